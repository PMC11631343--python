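"""U-matrix and P-matrix height fields over the neuron grid, plus diagnostics.

The U-matrix assigns each neuron the mean data-space distance between its
weight vector and those of its Moore-neighbourhood neurons; ridges of large
U-heights mark voids between data clouds.  The P-matrix counts the data
points inside a hypersphere of radius ``r`` around each weight vector and is
a density field over the map.  ``radius_diagnostics`` flags a radius as too
small (many empty hyperspheres) or too large (high density coinciding with
large U-heights — the crosstalk phenomenon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .datasets import DataTable
from .esom import EsomModel

__all__ = ["HeightMatrix", "umatrix", "pmatrix", "radius_diagnostics", "RadiusVerdict"]

# Moore neighbourhood: the 8 distinct neighbours of a grid cell.
_MOORE_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class HeightMatrix:
    """Per-neuron scalar field on the grid; ``kind`` is "U" or "P"."""

    heights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if self.kind not in ("U", "P"):
            raise ValueError("kind must be 'U' or 'P'")


def umatrix(model: EsomModel) -> HeightMatrix:
    """U-heights: mean weight-space distance to the 8 Moore neighbours.

    On a toroid the neighbourhood wraps; on a planar grid border neurons
    average over their existing neighbours only.
    """
    W = model.weight_grid()
    lines, columns, _ = W.shape
    total = np.zeros((lines, columns))
    count = np.zeros((lines, columns))
    for dr, dc in _MOORE_OFFSETS:
        shifted = np.roll(np.roll(W, -dr, axis=0), -dc, axis=1)
        dist = np.linalg.norm(W - shifted, axis=2)
        if model.grid.toroid:
            valid = np.ones((lines, columns), dtype=bool)
        else:
            valid = np.zeros((lines, columns), dtype=bool)
            rs = slice(max(0, -dr), lines - max(0, dr))
            cs = slice(max(0, -dc), columns - max(0, dc))
            valid[rs, cs] = True
        total += np.where(valid, dist, 0.0)
        count += valid
    return HeightMatrix(total / np.maximum(count, 1), "U")


def pmatrix(model: EsomModel, data: DataTable, radius: float) -> HeightMatrix:
    """P-heights: number of data points in the closed ball of ``radius`` per neuron."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if data.d != model.d:
        raise ValueError("data and model dimensionality differ")
    dist = cdist(model.weights, data.values)
    counts = (dist <= radius).sum(axis=1)
    return HeightMatrix(
        counts.reshape(model.grid.lines, model.grid.columns).astype(float), "P"
    )


@dataclass
class RadiusVerdict:
    """Diagnostic verdict on a density radius, with the metrics behind it."""

    verdict: str  # too_small | plausible | too_large
    zero_fraction: float
    dense_rank_correlation: float
    thresholds: dict = field(default_factory=dict)


def radius_diagnostics(
    u: HeightMatrix,
    p: HeightMatrix,
    z_max: float = 0.5,
    rho_max: float = 0.5,
) -> RadiusVerdict:
    """Classify a density radius as too_small / plausible / too_large.

    Too small: more than ``z_max`` of the P-heights are zero (empty
    hyperspheres everywhere).  Too large: among the densest quartile of
    neurons the Spearman correlation between U- and P-heights exceeds
    ``rho_max`` — large distances coinciding with large densities indicate
    that the hyperspheres reach across cloud boundaries.
    """
    if u.heights.shape != p.heights.shape:
        raise ValueError("U and P grids have different shapes")
    uh = u.heights.ravel()
    ph = p.heights.ravel()
    zero_fraction = float((ph == 0).mean())
    dense = ph >= np.quantile(ph, 0.75)
    if dense.sum() >= 3 and np.ptp(ph[dense]) > 0 and np.ptp(uh[dense]) > 0:
        rho = float(spearmanr(uh[dense], ph[dense]).statistic)
    else:
        rho = 0.0
    if zero_fraction > z_max:
        verdict = "too_small"
    elif rho > rho_max:
        verdict = "too_large"
    else:
        verdict = "plausible"
    return RadiusVerdict(verdict, zero_fraction, rho, {"z_max": z_max, "rho_max": rho_max})
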