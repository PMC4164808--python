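"""Central composite designs (CCD) for multi-factor fermentation screens.

A CCD combines a (possibly fractional) two-level factorial core, axial
("star") points at coded distance ``±alpha`` on each factor axis, and
replicated center points.  Factor settings are handled on two scales:

* *coded* units — dimensionless, centered at 0, factorial points at ±1,
  axial points at ±alpha;
* *natural* units — °C, rpm, g/100 mL, …

The convention used throughout is that a factor's ``low``/``high`` bounds
are its **axial** levels, so for a factor with bounds (L, H)::

    center            = (L + H) / 2
    natural(coded c)  = center + c * (H - L) / (2 * alpha)

which places the factorial levels at center ± (H − L)/(2·alpha).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "FactorSpec",
    "DesignRun",
    "DesignTable",
    "default_factors",
    "build_ccd",
    "code_levels",
    "decode_levels",
    "split_design",
    "table_from_natural",
    "TABLE2_TEST_IDS",
]

#: run ids held out for testing in the packaged 50-run fermentation fixture
TABLE2_TEST_IDS: tuple[int, ...] = (4, 13, 16, 23, 29, 32, 36, 41, 46, 49)

ROLE_FACTORIAL = "factorial"
ROLE_AXIAL = "axial"
ROLE_CENTER = "center"

# canonical CSV column per factor name (fallback: the bare factor name)
_CSV_COLUMNS = {
    "temperature": "temperature_C",
    "pH": "pH",
    "agitation": "agitation_rpm",
    "tryptone": "tryptone_g_per_100mL",
    "raffinose": "raffinose_g_per_100mL",
    "K2HPO4": "k2hpo4_g_per_100mL",
}
ACTIVITY_COLUMN = "activity_U_per_mL"
PREDICTED_COLUMN = "predicted_U_per_mL"


class DesignError(ValueError):
    """Invalid design configuration or malformed factor settings."""


@dataclass(frozen=True)
class FactorSpec:
    """One controllable fermentation factor.

    ``low`` and ``high`` are the axial (outermost) levels in natural units.
    """

    name: str
    units: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise DesignError(f"factor {self.name!r}: bounds must be finite")
        if not self.low < self.high:
            raise DesignError(f"factor {self.name!r}: low must be < high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def step(self, alpha: float) -> float:
        """Natural-unit change per coded unit for axial distance ``alpha``."""
        return (self.high - self.low) / (2.0 * alpha)

    def factorial_levels(self, alpha: float) -> tuple[float, float]:
        s = self.step(alpha)
        return (self.center - s, self.center + s)

    @property
    def csv_column(self) -> str:
        return _CSV_COLUMNS.get(self.name, self.name)


@dataclass(frozen=True)
class DesignRun:
    run_id: int
    coded: tuple[float, ...]
    natural: tuple[float, ...]
    role: str
    partition: str = "train"
    observed_activity: float | None = None
    predicted_activity: float | None = None


@dataclass(frozen=True)
class DesignTable:
    """An ordered collection of CCD runs over a fixed set of factors."""

    factors: tuple[FactorSpec, ...]
    runs: tuple[DesignRun, ...]
    alpha: float

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise DesignError("run ids must be unique")

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor_index(self, name: str) -> int:
        try:
            return self.factor_names.index(name)
        except ValueError:
            raise DesignError(f"unknown factor {name!r}") from None

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([r.coded for r in self.runs], dtype=float)

    @property
    def natural_matrix(self) -> np.ndarray:
        return np.array([r.natural for r in self.runs], dtype=float)

    @property
    def observed(self) -> np.ndarray:
        """Observed activities (NaN where absent)."""
        return np.array(
            [math.nan if r.observed_activity is None else r.observed_activity for r in self.runs],
            dtype=float,
        )

    def subset(self, partition: str) -> "DesignTable":
        runs = tuple(r for r in self.runs if r.partition == partition)
        return replace(self, runs=runs)

    def partition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.runs:
            counts[r.partition] = counts.get(r.partition, 0) + 1
        return counts

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.runs:
            counts[r.role] = counts.get(r.role, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {"run_id": [r.run_id for r in self.runs]}
        for i, f in enumerate(self.factors):
            cols[f.csv_column] = [r.natural[i] for r in self.runs]
        cols[ACTIVITY_COLUMN] = [r.observed_activity for r in self.runs]
        if any(r.predicted_activity is not None for r in self.runs):
            cols[PREDICTED_COLUMN] = [r.predicted_activity for r in self.runs]
        cols["partition"] = [r.partition for r in self.runs]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_factors() -> tuple[FactorSpec, ...]:
    """The six-factor fermentation screen for alpha-galactosidase production.

    Bounds are the axial levels of the 50-run design: temperature 32–40 °C,
    pH 6–8, agitation 150–190 rpm, tryptone 0–2, raffinose 1.5–3.5 and
    K2HPO4 0.5–1.5 g/100 mL.
    """
    return (
        FactorSpec("temperature", "degC", 32.0, 40.0),
        FactorSpec("pH", "", 6.0, 8.0),
        FactorSpec("agitation", "rpm", 150.0, 190.0),
        FactorSpec("tryptone", "g/100mL", 0.0, 2.0),
        FactorSpec("raffinose", "g/100mL", 1.5, 3.5),
        FactorSpec("K2HPO4", "g/100mL", 0.5, 1.5),
    )


def _factorial_core(k: int, core: str) -> np.ndarray:
    """Coded ±1 sign matrix of the factorial core.

    Rows are in standard order with the first factor varying slowest and the
    last *base* factor fastest.  The half fraction uses the defining relation
    I = AB…K (last column = product of the others), the highest-resolution
    choice; for six factors this is the resolution-VI 2^(6−1) fraction and it
    reproduces the packaged fixture's factorial block row for row.
    """
    if core == "full":
        base = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
        return base
    if core == "half_fraction":
        if k < 3:
            raise DesignError("half_fraction requires at least 3 factors")
        base = np.array(list(itertools.product((-1.0, 1.0), repeat=k - 1)))
        gen = np.prod(base, axis=1, keepdims=True)
        return np.hstack([base, gen])
    raise DesignError(f"unknown core {core!r} (expected 'full' or 'half_fraction')")


def build_ccd(
    factors: Sequence[FactorSpec],
    core: str = "half_fraction",
    alpha: float = 2.0,
    n_center: int = 6,
    seed: int | None = None,
    shuffle: bool = False,
) -> DesignTable:
    """Construct a central composite design.

    Runs are ordered factorial block (standard order), then axial pairs in
    factor order (low before high), then center replicates; ``shuffle=True``
    randomizes the run order (seeded) without changing run ids' contents.
    """
    k = len(factors)
    if not 2 <= k <= 12:
        raise DesignError("number of factors must be between 2 and 12")
    if not (math.isfinite(alpha) and alpha > 0):
        raise DesignError("alpha must be positive and finite")
    if n_center < 0:
        raise DesignError("n_center must be >= 0")

    blocks: list[tuple[np.ndarray, str]] = [(_factorial_core(k, core), ROLE_FACTORIAL)]
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    blocks.append((axial, ROLE_AXIAL))
    if n_center:
        blocks.append((np.zeros((n_center, k)), ROLE_CENTER))

    centers = np.array([f.center for f in factors])
    steps = np.array([f.step(alpha) for f in factors])

    runs: list[DesignRun] = []
    rid = 1
    for coded_block, role in blocks:
        for coded in coded_block:
            natural = centers + coded * steps
            runs.append(
                DesignRun(rid, tuple(coded.tolist()), tuple(natural.tolist()), role)
            )
            rid += 1
    if shuffle:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(runs))
        runs = [replace(runs[j], run_id=i + 1) for i, j in enumerate(order)]
    return DesignTable(tuple(factors), tuple(runs), float(alpha))


def code_levels(table: DesignTable, natural: Sequence[float]) -> np.ndarray:
    """Natural-unit settings -> coded levels (inverse of :func:`decode_levels`)."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape[-1] != len(table.factors):
        raise DesignError("expected one natural value per factor")
    centers = np.array([f.center for f in table.factors])
    steps = np.array([f.step(table.alpha) for f in table.factors])
    return (natural - centers) / steps


def decode_levels(table: DesignTable, coded: Sequence[float]) -> np.ndarray:
    """Coded levels -> natural-unit settings."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(table.factors):
        raise DesignError("expected one coded value per factor")
    centers = np.array([f.center for f in table.factors])
    steps = np.array([f.step(table.alpha) for f in table.factors])
    return centers + coded * steps


def split_design(table: DesignTable, test_ids: Iterable[int]) -> DesignTable:
    """Assign train/test partitions: runs in ``test_ids`` become the test set."""
    test_ids = list(test_ids)
    if len(set(test_ids)) != len(test_ids):
        raise DesignError("duplicate run ids in test_ids")
    known = {r.run_id for r in table.runs}
    unknown = set(test_ids) - known
    if unknown:
        raise DesignError(f"unknown run ids in test_ids: {sorted(unknown)}")
    test = set(test_ids)
    runs = tuple(
        replace(r, partition="test" if r.run_id in test else "train") for r in table.runs
    )
    return replace(table, runs=runs)


def _classify_role(coded: np.ndarray, alpha: float, tol: float = 1e-9) -> str:
    if np.all(np.abs(coded) <= tol):
        return ROLE_CENTER
    if np.all(np.abs(np.abs(coded) - 1.0) <= tol):
        return ROLE_FACTORIAL
    nonzero = np.abs(coded) > tol
    if nonzero.sum() == 1 and abs(abs(coded[nonzero][0]) - alpha) <= tol:
        return ROLE_AXIAL
    raise DesignError(f"coded point {coded} is not a CCD factorial/axial/center point")


def table_from_natural(
    factors: Sequence[FactorSpec],
    alpha: float,
    natural: np.ndarray,
    observed: Sequence[float] | None = None,
    predicted: Sequence[float] | None = None,
    partitions: Sequence[str] | None = None,
    run_ids: Sequence[int] | None = None,
) -> DesignTable:
    """Build a DesignTable from natural-unit settings, inferring coded levels and roles."""
    natural = np.asarray(natural, dtype=float)
    n = natural.shape[0]
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step(alpha) for f in factors])
    coded = (natural - centers) / steps
    runs = []
    for i in range(n):
        runs.append(
            DesignRun(
                run_id=int(run_ids[i]) if run_ids is not None else i + 1,
                coded=tuple(coded[i].tolist()),
                natural=tuple(natural[i].tolist()),
                role=_classify_role(coded[i], alpha),
                partition=partitions[i] if partitions is not None else "train",
                observed_activity=None if observed is None else float(observed[i]),
                predicted_activity=None if predicted is None else float(predicted[i]),
            )
        )
    return DesignTable(tuple(factors), tuple(runs), float(alpha))


def read_design_csv(path, factors: Sequence[FactorSpec], alpha: float = 2.0) -> DesignTable:
    """Read a design CSV (canonical columns, '.' decimal, UTF-8) into a DesignTable."""
    df = pd.read_csv(path)
    natural = df[[f.csv_column for f in factors]].to_numpy(dtype=float)
    observed = df[ACTIVITY_COLUMN].to_numpy(dtype=float) if ACTIVITY_COLUMN in df else None
    predicted = df[PREDICTED_COLUMN].to_numpy(dtype=float) if PREDICTED_COLUMN in df else None
    partitions = df["partition"].tolist() if "partition" in df else None
    run_ids = df["run_id"].tolist() if "run_id" in df else None
    return table_from_natural(factors, alpha, natural, observed, predicted, partitions, run_ids)
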