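"""Regular prediction grids and per-cell summary maps.

Predictions are made at cell centres: centre(i, j) = origin + (i + ½,
j + ½) · cell_size.  Maps store a posterior mean and sd per cell for a
named quantity (log-odds, probability, or a covariate value), with an
optional mask for cells where a required input is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PredictionGrid", "GridMap"]


@dataclass(frozen=True)
class PredictionGrid:
    """Regular square-celled grid: origin, cell size, cell counts."""

    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 0.04
    n_x: int = 25
    n_y: int = 25

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")

    @classmethod
    def unit_square(cls, n: int) -> "PredictionGrid":
        return cls(origin=(0.0, 0.0), cell_size=1.0 / n, n_x=n, n_y=n)

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    def cell_centres(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates, x fastest."""
        xs = self.origin[0] + (np.arange(self.n_x) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(self.n_y) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "cell_size": self.cell_size,
            "n_x": self.n_x,
            "n_y": self.n_y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionGrid":
        return cls(
            origin=tuple(d["origin"]),
            cell_size=float(d["cell_size"]),
            n_x=int(d["n_x"]),
            n_y=int(d["n_y"]),
        )


@dataclass
class GridMap:
    """Per-cell posterior mean and sd of a named quantity on a grid."""

    grid: PredictionGrid
    mean: np.ndarray
    sd: np.ndarray
    quantity: str = "value"
    mask: np.ndarray | None = None  # True = cell masked (no prediction)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if len(self.mean) != self.grid.n_cells or len(self.sd) != self.grid.n_cells:
            raise ValueError("mean/sd length must equal grid cell count")
        valid = self.mask is None or ~self.mask
        if np.any(self.sd[valid] < 0):
            raise ValueError("negative sd in grid map")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()

    @property
    def n_masked(self) -> int:
        return 0 if self.mask is None else int(self.mask.sum())

    def to_frame(self) -> pd.DataFrame:
        centres = self.grid.cell_centres()
        mean = self.mean.copy()
        sd = self.sd.copy()
        if self.mask is not None:
            mean[self.mask] = np.nan
            sd[self.mask] = np.nan
        return pd.DataFrame(
            {"cell_x": centres[:, 0], "cell_y": centres[:, 1], "mean": mean, "sd": sd}
        )
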