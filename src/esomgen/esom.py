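"""Toroidal emergent self-organizing map: grid geometry, training, projection.

An emergent SOM (ESOM) uses a large neuron grid (thousands of neurons) to
build a topology-preserving projection of high-dimensional data rather than
to cluster it.  Training is the classic online rule: for every presented
case the best-matching unit (BMU) and, attenuated by a Gaussian kernel in
grid distance, its neighbours are drawn toward the case.  Both the learning
rate and the neighbourhood radius decay linearly over epochs.  On a toroid
grid all distances wrap, which removes border effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import DataTable

__all__ = [
    "GridSpec",
    "EsomModel",
    "BmuProjection",
    "grid_distance",
    "init_weights",
    "train_esom",
    "project",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GridSpec:
    """Neuron grid geometry: ``lines`` rows x ``columns`` cols, optionally toroidal.

    The default 50 x 80 = 4000 neurons is an effective starting point for
    emergent maps; at least ~600 neurons are needed before a SOM stops
    behaving like k-means, and edge ratios of 1.2-1.6 work best.
    """

    lines: int = 50
    columns: int = 80
    toroid: bool = True

    def __post_init__(self) -> None:
        if self.lines < 1 or self.columns < 1:
            raise ValueError("grid must have positive dimensions")

    @property
    def m(self) -> int:
        return self.lines * self.columns

    def positions(self) -> np.ndarray:
        """All (row, col) positions in row-major order, shape (m, 2)."""
        rows, cols = np.meshgrid(
            np.arange(self.lines), np.arange(self.columns), indexing="ij"
        )
        return np.column_stack([rows.ravel(), cols.ravel()])


@dataclass
class EsomModel:
    """A trained (or initialized) ESOM: grid + one weight vector per neuron.

    ``weights`` has shape (m, d) in row-major grid order.
    """

    grid: GridSpec
    weights: np.ndarray
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.grid.m:
            raise ValueError("weights must have one row per neuron")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def d(self) -> int:
        return self.weights.shape[1]

    def weight_grid(self) -> np.ndarray:
        """Weights reshaped to (lines, columns, d)."""
        return self.weights.reshape(self.grid.lines, self.grid.columns, -1)


@dataclass
class BmuProjection:
    """Best-matching-unit assignment of each data row to a neuron."""

    neuron_index: np.ndarray
    grid_position: np.ndarray

    def __post_init__(self) -> None:
        self.neuron_index = np.asarray(self.neuron_index, dtype=int)
        self.grid_position = np.asarray(self.grid_position, dtype=int)


def _axis_delta(a: np.ndarray, b: np.ndarray, extent: int, toroid: bool) -> np.ndarray:
    delta = np.abs(a - b)
    if toroid:
        delta = np.minimum(delta, extent - delta)
    return delta


def grid_distance(a, b, grid: GridSpec) -> float:
    """Euclidean distance between two grid positions, wrapping on a toroid."""
    a = np.asarray(a)
    b = np.asarray(b)
    for pos in (a, b):
        if not (0 <= pos[0] < grid.lines and 0 <= pos[1] < grid.columns):
            raise ValueError(f"grid position {tuple(pos)} outside {grid.lines}x{grid.columns}")
    dr = _axis_delta(a[0], b[0], grid.lines, grid.toroid)
    dc = _axis_delta(a[1], b[1], grid.columns, grid.toroid)
    return float(np.hypot(dr, dc))


def init_weights(data: DataTable, grid: GridSpec, seed: int = 0) -> EsomModel:
    """Initialize weights uniformly within the per-variable data ranges."""
    if data.n < 1:
        raise ValueError("cannot initialize from an empty table")
    rng = np.random.default_rng(seed)
    lo = data.values.min(axis=0)
    hi = data.values.max(axis=0)
    weights = rng.uniform(0.0, 1.0, size=(grid.m, data.d)) * (hi - lo) + lo
    return EsomModel(grid, weights, {"initialized_seed": seed})


def _squared_grid_distances(grid: GridSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Per-axis squared wrap deltas: (lines x lines, columns x columns)."""
    def axis(extent: int) -> np.ndarray:
        idx = np.arange(extent)
        delta = np.abs(idx[:, None] - idx[None, :])
        if grid.toroid:
            delta = np.minimum(delta, extent - delta)
        return delta.astype(float) ** 2

    return axis(grid.lines), axis(grid.columns)


def train_esom(
    data: DataTable,
    grid: GridSpec | None = None,
    epochs: int = 25,
    radius_start: float | None = None,
    radius_end: float = 1.0,
    rate_start: float = 0.5,
    rate_end: float = 0.05,
    seed: int = 0,
    initial_weights: np.ndarray | None = None,
) -> EsomModel:
    """Online ESOM training with a Gaussian neighbourhood and linear cooling.

    Per presented case the update is ``w <- w + alpha(t) * h(g, rho(t)) * (x - w)``
    where ``g`` is the grid distance from the BMU and
    ``h(g, rho) = exp(-g^2 / (2 rho^2))``.  Learning rate and neighbourhood
    radius are interpolated linearly across epochs; the case order is
    reshuffled every epoch from the given seed.  The default starting radius
    is half the smaller grid extent.
    """
    if grid is None:
        grid = GridSpec()
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if radius_start is None:
        radius_start = min(grid.lines, grid.columns) / 2.0
    if not radius_start >= radius_end >= 0:
        raise ValueError("require radius_start >= radius_end >= 0")
    if not (0 < rate_start <= 1 and 0 < rate_end <= 1):
        raise ValueError("learning rates must lie in (0, 1]")
    if not np.all(np.isfinite(data.values)):
        raise ValueError("data must be finite")

    rng = np.random.default_rng(seed)
    if initial_weights is not None:
        weights = np.array(initial_weights, dtype=float)
        rng.integers(2**31)  # keep the seed stream aligned with default init
        if weights.shape != (grid.m, data.d):
            raise ValueError("initial_weights must have shape (m, d)")
    else:
        weights = init_weights(data, grid, seed=int(rng.integers(2**31))).weights
    row_d2, col_d2 = _squared_grid_distances(grid)
    X = data.values
    n = data.n

    frac = np.linspace(0.0, 1.0, epochs) if epochs > 1 else np.array([0.0])
    for epoch in range(epochs):
        alpha = rate_start + frac[epoch] * (rate_end - rate_start)
        rho = radius_start + frac[epoch] * (radius_end - radius_start)
        rho = max(rho, 1e-9)
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            diff = weights - x
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            br, bc = divmod(bmu, grid.columns)
            g2 = row_d2[br][:, None] + col_d2[bc][None, :]
            h = np.exp(-g2.ravel() / (2.0 * rho * rho))
            weights += (alpha * h)[:, None] * (x - weights)
        if not np.all(np.isfinite(weights)):
            raise FloatingPointError(f"non-finite weights after epoch {epoch}")

    meta = {
        "epochs": epochs,
        "radius_start": radius_start,
        "radius_end": radius_end,
        "rate_start": rate_start,
        "rate_end": rate_end,
        "seed": seed,
    }
    return EsomModel(grid, weights, meta)


def project(data: DataTable, model: EsomModel) -> BmuProjection:
    """Assign every data row to its best-matching unit (nearest weight vector).

    Ties are broken toward the lowest neuron index (argmin convention).
    """
    if data.d != model.d:
        raise ValueError(
            f"data dimensionality {data.d} does not match model dimensionality {model.d}"
        )
    dist = cdist(data.values, model.weights)
    idx = dist.argmin(axis=1)
    pos = np.column_stack(divmod(idx, model.grid.columns))
    return BmuProjection(idx, pos)


def quantization_error(data: DataTable, model: EsomModel) -> float:
    """Mean Euclidean distance from each case to its BMU weight vector."""
    dist = cdist(data.values, model.weights)
    return float(dist.min(axis=1).mean())


def save_model(model: EsomModel, directory: str | Path) -> None:
    """Persist a model as a directory: weights CSV + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "weights.csv", model.weights, delimiter=",")
    meta = {
        "lines": model.grid.lines,
        "columns": model.grid.columns,
        "toroid": model.grid.toroid,
        "train_meta": model.train_meta,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> EsomModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    grid = GridSpec(meta["lines"], meta["columns"], meta["toroid"])
    weights = np.loadtxt(directory / "weights.csv", delimiter=",", ndmin=2)
    return EsomModel(grid, weights, meta.get("train_meta", {}))
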