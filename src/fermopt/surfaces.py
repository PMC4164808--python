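"""Pairwise interaction response surfaces of the trained surrogate.

A surface slices the fitted six-dimensional response: two factors sweep
their full [low, high] ranges on an equally spaced grid while the remaining
four are pinned at their center-point settings (the response-surface
convention for interaction plots).  Values are reported in natural units
(U/mL) after inverse scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignError, DesignTable
from .ffnn import SurrogateModel

__all__ = ["SurfaceGrid", "surface_grid", "DEFAULT_PAIRS", "plot_surface"]

#: the six factor pairs conventionally plotted for this fermentation screen
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("tryptone", "temperature"),
    ("K2HPO4", "pH"),
    ("tryptone", "agitation"),
    ("raffinose", "agitation"),
    ("K2HPO4", "raffinose"),
    ("raffinose", "tryptone"),
)


@dataclass
class SurfaceGrid:
    factor_i: str
    factor_j: str
    axis_i: np.ndarray  # natural units
    axis_j: np.ndarray
    z: np.ndarray  # (len(axis_i), len(axis_j)) predicted activity, U/mL
    fixed_values: dict[str, float]  # the held-constant factors

    def to_long_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(np.arange(self.axis_i.size), np.arange(self.axis_j.size), indexing="ij")
        return pd.DataFrame(
            {
                f"{self.factor_i}_value": self.axis_i[ii.ravel()],
                f"{self.factor_j}_value": self.axis_j[jj.ravel()],
                "activity": self.z.ravel(),
            }
        )


def surface_grid(
    model: SurrogateModel,
    table: DesignTable,
    factor_i: str,
    factor_j: str,
    resolution: int = 25,
) -> SurfaceGrid:
    """Evaluate the model over a 2-D grid of two factors, others at center."""
    if factor_i == factor_j:
        raise DesignError("factor_i and factor_j must differ")
    if resolution < 2:
        raise DesignError("resolution must be >= 2")
    i = table.factor_index(factor_i)
    j = table.factor_index(factor_j)
    fi, fj = table.factors[i], table.factors[j]
    axis_i = np.linspace(fi.low, fi.high, resolution)
    axis_j = np.linspace(fj.low, fj.high, resolution)
    centers = np.array([f.center for f in table.factors])

    X = np.tile(centers, (resolution * resolution, 1))
    ii, jj = np.meshgrid(axis_i, axis_j, indexing="ij")
    X[:, i] = ii.ravel()
    X[:, j] = jj.ravel()
    z = np.asarray(model.predict_natural(X)).reshape(resolution, resolution)
    fixed = {
        f.name: float(c) for f, c in zip(table.factors, centers) if f.name not in (factor_i, factor_j)
    }
    return SurfaceGrid(factor_i, factor_j, axis_i, axis_j, z, fixed)


def plot_surface(grid: SurfaceGrid, path, kind: str = "contour") -> None:
    """Render a filled-contour (or 3-D) plot of one interaction surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if kind == "contour":
        fig, ax = plt.subplots(figsize=(5, 4))
        cs = ax.contourf(grid.axis_j, grid.axis_i, grid.z, levels=20, cmap="viridis")
        fig.colorbar(cs, ax=ax, label="activity (U/mL)")
        ax.set_xlabel(grid.factor_j)
        ax.set_ylabel(grid.factor_i)
    else:
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(projection="3d")
        J, I = np.meshgrid(grid.axis_j, grid.axis_i)
        ax.plot_surface(J, I, grid.z, cmap="viridis")
        ax.set_xlabel(grid.factor_j)
        ax.set_ylabel(grid.factor_i)
        ax.set_zlabel("activity (U/mL)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
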