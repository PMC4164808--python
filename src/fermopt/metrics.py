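"""Error metrics for judging surrogate-model predictions.

For predictions ``y_p`` against experimental values ``y_e`` over ``n`` runs:

    MSE  = (1/n) Σ (y_p − y_e)²          RMSE = sqrt(MSE)
    MAE  = (1/n) Σ |y_p − y_e|           MAPE = (1/n) Σ |y_p − y_e| / y_e

MAPE is kept as a fraction (no ×100) and is undefined when any experimental
value is zero.  Two flavours of R² are reported: the squared Pearson
correlation between predictions and observations (the headline number, the
one a calibration scatter plot shows) and the residual-based
1 − SSE/SST (can be negative for a bad model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    n: int
    mse: float
    rmse: float
    mae: float
    mape: float | None  # None when some observed value is zero
    r_squared: float  # squared Pearson correlation
    r_squared_resid: float  # 1 - SSE/SST

    @property
    def mape_defined(self) -> bool:
        return self.mape is not None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "mape": self.mape,
            "r_squared": self.r_squared,
            "r_squared_resid": self.r_squared_resid,
        }


def compute_metrics(y_pred, y_exp) -> MetricsReport:
    """Compute the full metric suite for a prediction/observation pairing."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_exp = np.asarray(y_exp, dtype=float)
    if y_pred.shape != y_exp.shape or y_pred.ndim != 1:
        raise ValueError("y_pred and y_exp must be 1-D vectors of equal length")
    n = y_pred.shape[0]
    if n == 0:
        raise ValueError("empty vectors")

    err = y_pred - y_exp
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)
    mae = float(np.mean(np.abs(err)))
    mape = None if np.any(y_exp == 0) else float(np.mean(np.abs(err) / y_exp))

    sst = float(np.sum((y_exp - y_exp.mean()) ** 2))
    r_resid = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else math.nan
    if n < 2 or np.std(y_pred) == 0 or np.std(y_exp) == 0:
        r_sq = math.nan
    else:
        r = float(np.corrcoef(y_pred, y_exp)[0, 1])
        r_sq = r * r
    return MetricsReport(n, mse, rmse, mae, mape, r_sq, r_resid)
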