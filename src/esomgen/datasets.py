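"""Tabular containers, CSV I/O, and built-in synthetic benchmark generators.

The two built-in generators reproduce canonical FCPS benchmark geometries:

* ``make_hepta`` — seven spherical clouds in 3-D, one small dense cloud at
  the origin (radius 0.1, 32 points) and six clouds of radius 1 (30 points
  each) centred at +/-3 on the coordinate axes; n = 212 in total.
* ``make_chainlink`` — two interlinked rings in 3-D, each class sampled
  uniformly from a torus with minor radius 0.1 and major radius 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataTable",
    "HeptaSpec",
    "make_hepta",
    "make_chainlink",
    "read_table",
    "write_table",
    "read_lrn",
    "read_cls",
]

LABEL_COLUMN = "Cls"


@dataclass
class DataTable:
    """An n x d numeric matrix with optional integer class labels.

    The universal input/output of the pipeline.  ``values`` must be finite;
    ``labels``, when present, has exactly one entry per row.
    """

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    variable_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if d < 1:
            raise ValueError("values must have at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError(
                    f"labels must have exactly {n} entries, got {self.labels.shape}"
                )
        if self.variable_names is not None:
            self.variable_names = list(self.variable_names)
            if len(self.variable_names) != d:
                raise ValueError("variable_names length must equal the number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def column_names(self) -> list[str]:
        if self.variable_names is not None:
            return list(self.variable_names)
        return [f"Var{i + 1}" for i in range(self.d)]


@dataclass
class HeptaSpec:
    """Recipe for the seven-cloud Hepta benchmark.

    Defaults: origin cloud of 32 points within radius 0.1, six clouds of 30
    points within radius 1 centred at +/-3 on each axis.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.0, 0.0],
                [3.0, 0.0, 0.0],
                [-3.0, 0.0, 0.0],
                [0.0, 3.0, 0.0],
                [0.0, -3.0, 0.0],
                [0.0, 0.0, 3.0],
                [0.0, 0.0, -3.0],
            ]
        )
    )
    radii: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    )
    counts: np.ndarray = field(
        default_factory=lambda: np.array([32, 30, 30, 30, 30, 30, 30])
    )

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.counts = np.atleast_1d(np.asarray(self.counts, dtype=int))
        k = self.centers.shape[0]
        if self.radii.shape != (k,) or self.counts.shape != (k,):
            raise ValueError("centers, radii and counts must agree in length")
        if np.any(self.counts <= 0):
            raise ValueError("all class counts must be positive")
        if np.any(self.radii < 0):
            raise ValueError("all radii must be non-negative")


def _uniform_ball(count: int, dim: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample in a ``dim``-ball: isotropic direction, radius ~ r*U^(1/dim)."""
    direction = rng.standard_normal((count, dim))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    direction /= norms
    radii = radius * rng.uniform(0.0, 1.0, size=(count, 1)) ** (1.0 / dim)
    return direction * radii


def make_hepta(spec: HeptaSpec | None = None, seed: int = 0) -> DataTable:
    """Draw the Hepta benchmark: clouds of points uniform in balls around the centers.

    Class labels are 1-based and follow the row order of ``spec.centers``.
    Deterministic for a given seed; class sizes depend only on the spec.
    """
    if spec is None:
        spec = HeptaSpec()
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, (center, radius, count) in enumerate(
        zip(spec.centers, spec.radii, spec.counts), start=1
    ):
        blocks.append(center + _uniform_ball(int(count), spec.centers.shape[1], float(radius), rng))
        labels.append(np.full(int(count), k))
    return DataTable(np.vstack(blocks), np.concatenate(labels))


def _torus_points(
    count: int, minor_radius: float, major_radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a torus lying in the xy-plane, centred at the origin.

    Rejection on the major angle corrects for the larger volume element on the
    outer side of the tube (negligible for thin tori, exact nonetheless).
    """
    out = np.empty((count, 3))
    filled = 0
    while filled < count:
        m = max(count - filled, 64)
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        theta = rng.uniform(0.0, 2.0 * np.pi, m)
        s = minor_radius * np.sqrt(rng.uniform(0.0, 1.0, m))
        accept = rng.uniform(0.0, 1.0, m) < (major_radius + s * np.cos(theta)) / (
            major_radius + minor_radius
        )
        phi, theta, s = phi[accept], theta[accept], s[accept]
        ring = major_radius + s * np.cos(theta)
        pts = np.column_stack([ring * np.cos(phi), ring * np.sin(phi), s * np.sin(theta)])
        take = min(len(pts), count - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out


def make_chainlink(
    n_total: int = 1000,
    minor_radius: float = 0.1,
    major_radius: float = 1.0,
    seed: int = 0,
) -> DataTable:
    """Draw the Chainlink benchmark: two orthogonally interlinked tori.

    Ring 1 lies in the xy-plane centred at the origin; ring 2 in the xz-plane
    centred at ``(major_radius, 0, 0)`` so each ring passes through the
    other's hole.  Classes are labelled 1 and 2 with ``n_total/2`` points each.
    """
    if n_total < 2 or n_total % 2 != 0:
        raise ValueError("n_total must be even and >= 2")
    if not 0 < minor_radius < major_radius:
        raise ValueError("require 0 < minor_radius < major_radius")
    rng = np.random.default_rng(seed)
    half = n_total // 2
    ring1 = _torus_points(half, minor_radius, major_radius, rng)
    ring2 = _torus_points(half, minor_radius, major_radius, rng)
    # rotate ring 2 into the xz-plane and shift it onto ring 1's circumference
    ring2 = ring2[:, [0, 2, 1]] + np.array([major_radius, 0.0, 0.0])
    values = np.vstack([ring1, ring2])
    labels = np.concatenate([np.full(half, 1), np.full(half, 2)])
    return DataTable(values, labels)


def read_table(path: str | Path, label_column: Optional[str] = None) -> DataTable:
    """Read a CSV table (header row mandatory) into a :class:`DataTable`.

    ``label_column``, when given, is extracted as integer class labels and
    excluded from the numeric matrix.  Non-numeric or missing cells raise a
    ``ValueError`` naming the offending column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise ValueError(f"{path}: label column {label_column!r} not found")
        labels = frame.pop(label_column).to_numpy()
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"{path}: non-numeric or missing value in column {col!r}, row {row}")
        frame[col] = numeric
    return DataTable(frame.to_numpy(dtype=float), labels, list(frame.columns))


def write_table(table: DataTable, path: str | Path) -> None:
    """Write a :class:`DataTable` as CSV; labels become a final ``Cls`` column."""
    frame = pd.DataFrame(table.values, columns=table.column_names())
    if table.labels is not None:
        frame[LABEL_COLUMN] = table.labels
    frame.to_csv(path, index=False)


def read_lrn(path: str | Path) -> DataTable:
    """Read a Databionics ``*.lrn`` file (tab-separated, ``%``-prefixed header).

    Column-type row codes: 9 = row key (dropped), 1 = data column.
    """
    path = Path(path)
    header_rows: list[str] = []
    data_rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("%"):
                header_rows.append(line[1:].strip())
            else:
                data_rows.append(line.split("\t"))
    if not data_rows:
        raise ValueError(f"{path}: no data rows")
    col_types = None
    names = None
    for row in header_rows:
        fields = row.split("\t")
        if all(f.strip().lstrip("-").isdigit() for f in fields) and len(fields) > 1:
            col_types = [int(f) for f in fields]
        elif len(fields) > 1:
            names = [f.strip() for f in fields]
    matrix = np.array(data_rows, dtype=float)
    if col_types is not None and len(col_types) == matrix.shape[1]:
        keep = [i for i, t in enumerate(col_types) if t != 9]
        matrix = matrix[:, keep]
        if names is not None and len(names) == len(col_types):
            names = [names[i] for i in keep]
    if names is not None and len(names) != matrix.shape[1]:
        names = None
    return DataTable(matrix, None, names)


def read_cls(path: str | Path) -> np.ndarray:
    """Read a Databionics ``*.cls`` file: whitespace-separated index/class pairs."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            fields = line.split()
            pairs.append((int(fields[0]), int(fields[1])))
    if not pairs:
        raise ValueError(f"{path}: no class assignments")
    pairs.sort()
    return np.array([cls for _, cls in pairs], dtype=int)
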