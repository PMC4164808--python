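"""Synthetic response surfaces and the packaged 50-run fermentation fixture.

The generator emulates the statistical structure the analysis assumes: a
smooth response over the six factors with a single interior maximum
(concave quadratic in coded units, optionally with bilinear interaction
terms) observed with additive homoscedastic Gaussian noise at the design
points.  It lets the training, model-selection and optimization stages be
exercised with a known ground truth.

``table2_fixture`` returns the packaged 50-run central composite design of
the alpha-galactosidase fermentation study (observed and model-predicted
activities, 40 train / 10 test rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import design as _design
from .design import DesignError, DesignTable, FactorSpec, default_factors

__all__ = [
    "SyntheticSurfaceSpec",
    "make_quadratic_truth",
    "simulate_design_observations",
    "table2_fixture",
    "table2_frame",
]


@dataclass(frozen=True)
class SyntheticSurfaceSpec:
    """Ground truth for a simulated fermentation response.

    ``optimum_coded`` is the true argmax in coded units, ``peak_activity``
    the response there (U/mL), ``curvature`` the per-factor quadratic
    coefficients (all strictly negative so the maximum is unique and
    interior), ``interaction_coeffs`` an optional symmetric matrix of
    bilinear terms, and ``noise_sd`` the observation noise (U/mL).
    """

    factors: tuple[FactorSpec, ...] = field(default_factory=default_factors)
    optimum_coded: tuple[float, ...] = (0.0,) * 6
    peak_activity: float = 7.5
    curvature: tuple[float, ...] = (-0.5,) * 6
    interaction_coeffs: tuple[tuple[float, ...], ...] | None = None
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.factors)
        if len(self.optimum_coded) != k or len(self.curvature) != k:
            raise DesignError("optimum_coded and curvature need one entry per factor")
        if any(c >= 0 for c in self.curvature):
            raise DesignError("all curvature coefficients must be negative")
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise DesignError("noise_sd must be finite and non-negative")


def make_quadratic_truth(spec: SyntheticSurfaceSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return f(coded) -> activity with f(optimum_coded) == peak_activity exactly.

    f(x) = peak + Σ_i c_i (x_i − o_i)² + Σ_{i<j} B_ij (x_i − o_i)(x_j − o_j)
    """
    opt = np.asarray(spec.optimum_coded, dtype=float)
    curv = np.asarray(spec.curvature, dtype=float)
    B = None if spec.interaction_coeffs is None else np.asarray(spec.interaction_coeffs, float)

    def f(coded) -> np.ndarray | float:
        x = np.asarray(coded, dtype=float)
        single = x.ndim == 1
        d = (x[None, :] if single else x) - opt
        val = spec.peak_activity + d**2 @ curv
        if B is not None:
            val = val + 0.5 * np.einsum("ni,ij,nj->n", d, B, d) - 0.5 * (d**2 @ np.diag(B))
        return float(val[0]) if single else val

    return f


def simulate_design_observations(spec: SyntheticSurfaceSpec, table: DesignTable) -> DesignTable:
    """Fill a design's observed activities with truth + Gaussian noise (seeded).

    Negative draws are floored at zero (an activity cannot be negative) with
    a warning, since heavy flooring means the noise model is inconsistent
    with the chosen surface.
    """
    truth = make_quadratic_truth(spec)
    rng = np.random.default_rng(spec.seed)
    y = np.asarray(truth(table.coded_matrix), dtype=float)
    y = y + rng.normal(0.0, spec.noise_sd, size=y.shape) if spec.noise_sd > 0 else y
    if np.any(y < 0):
        warnings.warn("negative simulated activities floored at 0", stacklevel=2)
        y = np.clip(y, 0.0, None)
    runs = tuple(replace(r, observed_activity=float(v)) for r, v in zip(table.runs, y))
    return replace(table, runs=runs)


def table2_frame() -> pd.DataFrame:
    """The packaged 50-run design table as a DataFrame (printed precision)."""
    path = resources.files("fermopt").joinpath("data/table2.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def table2_fixture() -> DesignTable:
    """The 50-run fermentation CCD with observed/predicted activities.

    Rows carry the published train/test partition (40/10); predicted
    activities are kept as an auxiliary column for metric cross-checks.
    """
    df = table2_frame()
    factors = default_factors()
    return _design.table_from_natural(
        factors,
        alpha=2.0,
        natural=df[[f.csv_column for f in factors]].to_numpy(dtype=float),
        observed=df[_design.ACTIVITY_COLUMN].to_numpy(dtype=float),
        predicted=df[_design.PREDICTED_COLUMN].to_numpy(dtype=float),
        partitions=df["partition"].tolist(),
        run_ids=df["run_id"].tolist(),
    )
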