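"""End-to-end orchestration: design -> scaling -> training -> GA -> surfaces.

The pipeline reproduces the full modelling workflow on a design table with
observed activities: fit input/output scalers on the training rows, train
the perceptron (fixed hidden size or a sweep), score both partitions on the
scaled and natural scales, maximize the fitted surface with the genetic
algorithm, optionally export interaction surfaces, and emit a JSON-able
report whose headline is the predicted improvement over the best run that
was actually observed in the design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import ga as _ga
from . import scaling
from . import surfaces as _surfaces
from .design import DesignTable
from .ffnn import (
    NetworkTopology,
    SurrogateModel,
    TrainingConfig,
    TrainingResult,
    forward,
    select_hidden_size,
    train_lm,
)
from .metrics import MetricsReport, compute_metrics

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "improvement_percent", "fit_surrogate"]


def improvement_percent(best_new: float, best_baseline: float) -> float:
    """Percent change of a new optimum over a baseline: 100 (new - base) / base."""
    if best_baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (best_new - best_baseline) / best_baseline


@dataclass
class PipelineConfig:
    n_hidden: int = 10
    sweep: Sequence[int] | None = None  # e.g. range(3, 19); overrides n_hidden
    training: TrainingConfig = field(default_factory=TrainingConfig)
    ga: _ga.GAConfig = field(default_factory=_ga.GAConfig)
    top_k: int = 4
    surface_pairs: Sequence[tuple[str, str]] | None = None
    surface_resolution: int = 25
    outdir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class RunReport:
    topology: NetworkTopology
    train_metrics_natural: MetricsReport
    test_metrics_natural: MetricsReport | None
    train_metrics_scaled: MetricsReport
    test_metrics_scaled: MetricsReport | None
    best_design_activity: float
    best_design_run_id: int
    optimization: _ga.OptimizationResult
    improvement_percent: float
    sweep_table: object | None
    seed: int

    def to_dict(self, factor_names: Sequence[str] | None = None) -> dict:
        d = {
            "topology": {"n_in": self.topology.n_in, "n_hidden": self.topology.n_hidden, "n_out": 1},
            "train_metrics_natural": self.train_metrics_natural.to_dict(),
            "test_metrics_natural": None
            if self.test_metrics_natural is None
            else self.test_metrics_natural.to_dict(),
            "train_metrics_scaled": self.train_metrics_scaled.to_dict(),
            "test_metrics_scaled": None
            if self.test_metrics_scaled is None
            else self.test_metrics_scaled.to_dict(),
            "best_design_activity": self.best_design_activity,
            "best_design_run_id": self.best_design_run_id,
            "optimization": self.optimization.to_dict(factor_names),
            "improvement_percent": self.improvement_percent,
            "seed": self.seed,
        }
        if self.sweep_table is not None:
            d["sweep"] = self.sweep_table.to_dict(orient="records")
        return d


def _subseeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def fit_surrogate(
    table: DesignTable,
    n_hidden: int = 10,
    sweep: Sequence[int] | None = None,
    training: TrainingConfig = TrainingConfig(),
) -> tuple[SurrogateModel, TrainingResult, object | None]:
    """Scale a design table and train the perceptron on its training rows.

    Scalers are fitted on the training partition only and applied to the
    test rows, so the held-out error is honest.  Returns the bundled model,
    the training result and (if a sweep was requested) the sweep table.
    """
    train = table.subset("train")
    test = table.subset("test")
    if len(train) == 0:
        raise ValueError("design table has no training rows")
    y_train = train.observed
    if np.any(~np.isfinite(y_train)):
        raise ValueError("training rows must all have observed activities")

    x_scaler = scaling.fit_scaler(train.natural_matrix)
    y_scaler = scaling.fit_scaler(y_train)
    Xtr = scaling.transform(x_scaler, train.natural_matrix)
    ytr = scaling.transform(y_scaler, y_train)

    sweep_table = None
    if sweep is not None:
        if len(test) == 0:
            raise ValueError("hidden-size sweep needs a test partition")
        Xte = scaling.transform(x_scaler, test.natural_matrix)
        yte = scaling.transform(y_scaler, test.observed)
        topo, sweep_table, result = select_hidden_size(Xtr, ytr, Xte, yte, sweep, training)
    else:
        topo = NetworkTopology(n_in=len(table.factors), n_hidden=n_hidden)
        result = train_lm(topo, Xtr, ytr, training)
    model = SurrogateModel(topo, result.params, x_scaler, y_scaler)
    return model, result, sweep_table


def run_pipeline(table: DesignTable, config: PipelineConfig = PipelineConfig()) -> RunReport:
    """Execute all stages on a design table with observations; see module docstring."""
    train_seed, ga_seed = _subseeds(config.seed, 2)
    training = TrainingConfig(**{**config.training.__dict__, "seed": train_seed})
    model, result, sweep_table = fit_surrogate(table, config.n_hidden, config.sweep, training)
    train = table.subset("train")
    test = table.subset("test")
    logger.info(
        "trained %d-%d-1 network on %d rows: SSE=%.3e",
        model.topology.n_in, model.topology.n_hidden, len(train), result.final_sse,
    )

    def both_scales(part: DesignTable) -> tuple[MetricsReport, MetricsReport]:
        Xs = scaling.transform(model.x_scaler, part.natural_matrix)
        ys = scaling.transform(model.y_scaler, part.observed)
        pred_s = np.asarray(forward(model.params, Xs))
        pred_n = np.asarray(model.predict_natural(part.natural_matrix))
        return compute_metrics(pred_n, part.observed), compute_metrics(pred_s, ys)

    train_nat, train_sc = both_scales(train)
    test_nat = test_sc = None
    if len(test) > 0:
        test_nat, test_sc = both_scales(test)

    ga_config = _ga.GAConfig(
        **{**config.ga.__dict__, "seed": ga_seed, "top_k": config.top_k}
    )
    opt = _ga.evolve(model, table.factors, ga_config)
    logger.info("GA best predicted activity %.3f U/mL after %d evaluations",
                opt.best_predicted_activity, opt.n_evaluations)

    observed = table.observed
    best_idx = int(np.nanargmax(observed))
    best_design = float(observed[best_idx])
    report = RunReport(
        topology=model.topology,
        train_metrics_natural=train_nat,
        test_metrics_natural=test_nat,
        train_metrics_scaled=train_sc,
        test_metrics_scaled=test_sc,
        best_design_activity=best_design,
        best_design_run_id=table.runs[best_idx].run_id,
        optimization=opt,
        improvement_percent=improvement_percent(opt.best_predicted_activity, best_design),
        sweep_table=sweep_table,
        seed=config.seed,
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.save_json(outdir / "model.json")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(table.factor_names), fh, indent=2)
        pairs = config.surface_pairs
        if pairs is None:
            names = set(table.factor_names)
            pairs = [p for p in _surfaces.DEFAULT_PAIRS if set(p) <= names]
        for fi, fj in pairs:
            grid = _surfaces.surface_grid(model, table, fi, fj, config.surface_resolution)
            grid.to_long_frame().to_csv(outdir / f"surface_{fi}_x_{fj}.csv", index=False)
    return report
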