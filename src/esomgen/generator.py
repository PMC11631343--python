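"""Structure-preserving point generation by banded hypersphere sampling.

Around each original case ("seed") the algorithm places ``gen_per_data``
new points at isotropic random directions, with distances drawn from three
uniform bands expressed in units of the neighbourhood scale ``c``:

* band A (default 80% of points): lengths in (0, 0.72]*c — distances whose
  neighbourhood probability exceeds ~0.95;
* band B (15%): lengths in (0.72, 1.22]*c — probabilities between ~0.10
  and ~0.95;
* band C (remainder): lengths in (1.22, 2.0]*c — the sparse far tail.

The scale is ``c = 0.4 * r`` where ``r`` is the density radius, which keeps
generated points away from neighbouring clouds (halfway between clouds
would be factor 0.5).  The band limits are the inversion of the sigmoid
neighbourhood probability ``p(d) = 1 / (1 + exp(10 (d/c - 1)))``, which
equals 0.5 at d = c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .datasets import DataTable

__all__ = [
    "GenerationConfig",
    "GeneratedSet",
    "neighborhood_probability",
    "sample_directions",
    "sample_lengths",
    "generate_data",
    "augment_to_size",
]


@dataclass(frozen=True)
class GenerationConfig:
    """Tunables of the generator; defaults follow the reference constants."""

    gen_per_data: int = 10
    c_factor: float = 0.4
    band_limits: tuple[float, float] = (0.72, 1.22)
    band_fractions: tuple[float, float] = (0.80, 0.15)
    max_distance: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gen_per_data < 1:
            raise ValueError("gen_per_data must be >= 1")
        a, b = self.band_limits
        if not 0 < a < b < self.max_distance:
            raise ValueError("require 0 < band_limits[0] < band_limits[1] < max_distance")
        fa, fb = self.band_fractions
        if not (0 < fa < 1 and 0 < fb < 1 and fa + fb < 1):
            raise ValueError("band fractions must lie in (0,1) and sum to < 1")


@dataclass
class GeneratedSet:
    """Original rows plus generated rows, with per-row provenance.

    ``seed_index[i]`` is the row of ``original`` that seeded generated row
    ``i``; generated rows inherit their seed's class label.
    """

    original: DataTable
    generated: DataTable
    seed_index: np.ndarray

    def __post_init__(self) -> None:
        self.seed_index = np.asarray(self.seed_index, dtype=int)
        if self.generated.n != self.seed_index.size:
            raise ValueError("one seed index per generated row required")

    def pooled(self) -> DataTable:
        """Originals followed by generated rows as one table."""
        labels = None
        if self.original.labels is not None and self.generated.labels is not None:
            labels = np.concatenate([self.original.labels, self.generated.labels])
        return DataTable(
            np.vstack([self.original.values, self.generated.values]),
            labels,
            self.original.variable_names,
        )

    @property
    def origin_flag(self) -> np.ndarray:
        """Per pooled row: "original" or "generated"."""
        return np.array(
            ["original"] * self.original.n + ["generated"] * self.generated.n
        )


def neighborhood_probability(d, c: float):
    """Probability that a point at distance ``d`` is in the seed's neighbourhood.

    ``p = 1 / (1 + exp(10 (d/c - 1)))``: strictly decreasing in ``d``, equal
    to 0.5 at ``d = c`` (the Bayes boundary between "neighbour" and
    "not a neighbour").
    """
    if c <= 0:
        raise ValueError("scale c must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(10.0 * (d / c - 1.0)))
    return float(p) if p.ndim == 0 else p


def sample_directions(count: int, dim: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Isotropic unit vectors: Gaussian components normalized to length 1."""
    if count < 1 or dim < 1:
        raise ValueError("count and dim must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.standard_normal((count, dim))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def band_counts(count: int, fractions: tuple[float, float]) -> tuple[int, int, int]:
    """Band occupancies: round(count*f_a), round(count*f_b), remainder."""
    n_a = round(count * fractions[0])
    n_b = round(count * fractions[1])
    n_c = count - n_a - n_b
    if n_c < 0:
        n_b += n_c
        n_c = 0
    return n_a, n_b, n_c


def sample_lengths(
    count: int,
    c: float,
    config: Optional[GenerationConfig] = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-ordered jitter lengths: A then B then C, each uniform, scaled by ``c``.

    Band counts are exact (rounding rule above), not multinomial, and the
    lengths stay in band-block order so callers can rely on it.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if c <= 0:
        raise ValueError("scale c must be positive")
    if config is None:
        config = GenerationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_a, n_b, n_c = band_counts(count, config.band_fractions)
    lim_a, lim_b = config.band_limits
    lengths = np.concatenate(
        [
            rng.uniform(0.0, lim_a, n_a),
            rng.uniform(lim_a, lim_b, n_b),
            rng.uniform(lim_b, config.max_distance, n_c),
        ]
    )
    return lengths * c


def _generate_rows(
    seeds: np.ndarray,
    c: float,
    config: GenerationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Seed rows + direction * banded length, in the given row order."""
    count, dim = seeds.shape
    directions = sample_directions(count, dim, rng)
    lengths = sample_lengths(count, c, config, rng)
    return seeds + directions * lengths[:, None]


def generate_data(
    data: DataTable,
    density_radius: float,
    config: Optional[GenerationConfig] = None,
) -> GeneratedSet:
    """Generate ``gen_per_data`` new points per original case.

    The generated block repeats the originals in whole copies (all seeds for
    copy 1, then copy 2, ...) and the banded lengths are assigned to rows in
    that order, so band counts over the whole set are exact.  Labels are
    inherited from the seed; unlabeled input is treated as a single class.
    """
    if config is None:
        config = GenerationConfig()
    if density_radius <= 0:
        raise ValueError("density_radius must be positive")
    labels = data.labels
    if labels is None:
        labels = np.ones(data.n, dtype=int)
    if labels.shape[0] != data.n:
        raise ValueError("Unequal number of cases and class labels.")
    c = config.c_factor * density_radius
    rng = np.random.default_rng(config.seed)
    seed_index = np.tile(np.arange(data.n), config.gen_per_data)
    generated_values = _generate_rows(data.values[seed_index], c, config, rng)
    generated = DataTable(generated_values, labels[seed_index], data.variable_names)
    original = DataTable(data.values, labels, data.variable_names)
    return GeneratedSet(original, generated, seed_index)


def augment_to_size(
    data: DataTable,
    density_radius: float,
    targets: Mapping[int, int],
    config: Optional[GenerationConfig] = None,
) -> GeneratedSet:
    """Enlarge each class to a target size by per-class generation.

    For every class the deficit ``target - current`` is filled by cycling the
    class's seeds in original row order, each producing one generated point
    via the same banded mechanism.  Classes already at target receive no
    additions.  Typical use: balance all groups to the largest group's size.
    """
    if config is None:
        config = GenerationConfig()
    if density_radius <= 0:
        raise ValueError("density_radius must be positive")
    if data.labels is None:
        raise ValueError("augment_to_size requires class labels")
    c = config.c_factor * density_radius
    rng = np.random.default_rng(config.seed)
    blocks, block_labels, block_seeds = [], [], []
    for cls in sorted(targets):
        members = np.nonzero(data.labels == cls)[0]
        current = members.size
        target = int(targets[cls])
        if target < current:
            raise ValueError(
                f"target {target} for class {cls} is below its current size {current}"
            )
        deficit = target - current
        if deficit == 0:
            continue
        seed_rows = members[np.arange(deficit) % current]
        blocks.append(_generate_rows(data.values[seed_rows], c, config, rng))
        block_labels.append(np.full(deficit, cls))
        block_seeds.append(seed_rows)
    if blocks:
        generated = DataTable(
            np.vstack(blocks), np.concatenate(block_labels), data.variable_names
        )
        seed_index = np.concatenate(block_seeds)
    else:
        # no deficits anywhere: an empty generated block
        generated = DataTable(
            np.empty((0, data.d)), np.empty(0, dtype=int), data.variable_names
        )
        seed_index = np.empty(0, dtype=int)
    return GeneratedSet(data, generated, seed_index)
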