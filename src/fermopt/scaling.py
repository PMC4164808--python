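"""Min-max normalization of network inputs and outputs to [-1, +1].

The affine map per variable is ``y = 2 (x - min) / (max - min) - 1``, so the
fitted minimum maps to -1 and the fitted maximum to +1.  Values outside the
fitted range extrapolate linearly (logged at debug level), which matters when
an optimizer proposes settings beyond the training runs' span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["DegenerateScaleError", "ScalerParams", "fit_scaler", "transform", "inverse_transform"]


class DegenerateScaleError(ValueError):
    """A column has no spread, so the min-max map is undefined."""


@dataclass(frozen=True)
class ScalerParams:
    """Per-variable minima and maxima defining the [-1, 1] affine map."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_vars(self) -> int:
        return self.mins.shape[0]

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(np.asarray(d["mins"], dtype=float), np.asarray(d["maxs"], dtype=float))


def _as_2d(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[:, None], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError("expected a vector or a 2-D matrix")


def fit_scaler(columns) -> ScalerParams:
    """Fit column-wise min/max.  ``columns`` is (n, p) or a length-n vector."""
    arr, _ = _as_2d(columns)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in scaler input")
    mins = arr.min(axis=0)
    maxs = arr.max(axis=0)
    flat = maxs - mins <= 0
    if np.any(flat):
        raise DegenerateScaleError(f"constant column(s) at index {np.where(flat)[0].tolist()}")
    return ScalerParams(mins, maxs)


def transform(params: ScalerParams, x) -> np.ndarray:
    """Map natural values into [-1, 1] per variable (linear extrapolation outside)."""
    arr, was_1d = _as_2d(x)
    if arr.shape[1] != params.n_vars:
        raise ValueError(f"expected {params.n_vars} variables, got {arr.shape[1]}")
    y = 2.0 * (arr - params.mins) / (params.maxs - params.mins) - 1.0
    if np.any((y < -1.0 - 1e-12) | (y > 1.0 + 1e-12)):
        logger.debug("transform: values outside the fitted range were extrapolated")
    return y[:, 0] if was_1d else y


def inverse_transform(params: ScalerParams, y) -> np.ndarray:
    """Exact inverse of :func:`transform`."""
    arr, was_1d = _as_2d(y)
    if arr.shape[1] != params.n_vars:
        raise ValueError(f"expected {params.n_vars} variables, got {arr.shape[1]}")
    x = params.mins + (arr + 1.0) * (params.maxs - params.mins) / 2.0
    return x[:, 0] if was_1d else x
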