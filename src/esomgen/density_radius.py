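"""Density-radius estimation from Gabriel-graph distances between BMUs.

For structured data the distances along Gabriel-graph edges between the
distinct best-matching-unit weight vectors ("abstract U-matrix heights")
are bimodal: a small mode of within-cloud distances and a large mode of
between-cloud distances.  A two-component univariate Gaussian mixture is
fitted by EM, and the Bayes decision boundary ``t_AU`` between the two
modes yields the density radius ``r = 0.8 * t_AU`` used for P-matrix
density estimation and, scaled further by 0.4, for data generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .datasets import DataTable
from .esom import BmuProjection, EsomModel, project

__all__ = [
    "AuHeightSample",
    "MixtureFit",
    "RadiusEstimate",
    "UnimodalSampleError",
    "gabriel_graph",
    "au_heights",
    "fit_bimodal_gmm",
    "bayes_boundary",
    "estimate_density_radius",
    "save_radius",
    "load_radius",
]

RADIUS_FACTOR = 0.8  # r = 0.8 * t_AU


class UnimodalSampleError(ValueError):
    """Raised when the distance sample carries no two-mode structure."""


@dataclass
class AuHeightSample:
    """Euclidean lengths of Gabriel-graph edges between distinct BMU weights."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size == 0:
            raise ValueError("distance sample must be nonempty")
        if not np.all(np.isfinite(self.distances)) or np.any(self.distances <= 0):
            raise ValueError("distances must be finite and positive")


@dataclass
class MixtureFit:
    """A 2-component univariate Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    loglik_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("standard deviations must be positive")


@dataclass
class RadiusEstimate:
    """Density radius with full provenance of its derivation."""

    t_au: float
    radius: float
    fit: MixtureFit
    sample: AuHeightSample


def gabriel_graph(points: np.ndarray) -> np.ndarray:
    """Edges of the Gabriel graph over a point set.

    Edge (a, b) is present iff the closed ball with diameter ab contains no
    third point, equivalently iff no p satisfies
    ``d(a,p)^2 + d(b,p)^2 <= d(a,b)^2``.  Returns an (n_edges, 2) array of
    index pairs with a < b.  The Gabriel graph is a subgraph of the Delaunay
    triangulation.
    """
    points = np.asarray(points, dtype=float)
    m = points.shape[0]
    if m < 2:
        raise ValueError("need at least two points")
    sq = np.einsum("ij,ij->i", points, points)
    d2 = sq[:, None] + sq[None, :] - 2.0 * points @ points.T
    np.maximum(d2, 0.0, out=d2)
    edges = []
    for a in range(m - 1):
        # min over candidate blockers p of d(a,p)^2 + d(b,p)^2, excluding a and b
        s = d2[a][None, :] + d2[a + 1 :, :]  # rows: b = a+1..m-1
        s[:, a] = np.inf
        s[np.arange(s.shape[0]), np.arange(a + 1, m)] = np.inf
        blocked = s.min(axis=1) <= d2[a, a + 1 :]
        for b in np.nonzero(~blocked)[0]:
            edges.append((a, a + 1 + b))
    return np.array(edges, dtype=int).reshape(-1, 2)


def au_heights(projection: BmuProjection, model: EsomModel) -> AuHeightSample:
    """AU-heights: Gabriel edge lengths over the distinct BMU weight vectors.

    Duplicate BMUs (several cases sharing a neuron) are collapsed first so
    zero-length edges cannot corrupt the small-distance mode.
    """
    distinct = np.unique(projection.neuron_index)
    if distinct.size < 2:
        raise ValueError("only one distinct BMU: no structure to measure")
    bmu_weights = model.weights[distinct]
    # collapse numerically identical weight vectors as well
    bmu_weights = np.unique(bmu_weights, axis=0)
    if bmu_weights.shape[0] < 2:
        raise ValueError("only one distinct BMU weight vector: no structure to measure")
    edges = gabriel_graph(bmu_weights)
    lengths = np.linalg.norm(bmu_weights[edges[:, 0]] - bmu_weights[edges[:, 1]], axis=1)
    return AuHeightSample(lengths)


def _em_once(
    x: np.ndarray,
    means0: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> MixtureFit:
    n = x.size
    means = means0.astype(float).copy()
    resp_hard = x[:, None] - means[None, :]
    assign = np.abs(resp_hard).argmin(axis=1)
    weights = np.array([max((assign == k).mean(), 1e-3) for k in range(2)])
    weights /= weights.sum()
    var = np.empty(2)
    for k in range(2):
        members = x[assign == k]
        var[k] = members.var() if members.size > 1 else x.var()
    var = np.maximum(var, var_floor)

    loglik_trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step in log space for numerical safety
        logp = np.log(weights)[None, :] + norm.logpdf(
            x[:, None], means[None, :], np.sqrt(var)[None, :]
        )
        mx = logp.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
        loglik = float(lse.sum())
        loglik_trace.append(loglik)
        resp = np.exp(logp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if loglik - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = loglik

    order = np.argsort(means)
    return MixtureFit(
        weights[order],
        means[order],
        np.sqrt(var[order]),
        loglik_trace[-1],
        converged,
        np.asarray(loglik_trace),
    )


def fit_bimodal_gmm(
    sample: AuHeightSample | np.ndarray,
    restarts: int = 10,
    tol: float = 1e-9,
    seed: int = 0,
    max_iter: int = 500,
    var_floor: float = 1e-12,
) -> MixtureFit:
    """Best-of-restarts EM fit of a 2-component univariate Gaussian mixture.

    The first restart is initialized at the lower/upper quartiles of the
    sample (a 1-D analogue of k-means seeding); further restarts perturb
    random pairs of sample points.  The per-iteration log-likelihood is
    non-decreasing (EM guarantee) and recorded in ``loglik_trace``.
    Accepts an :class:`AuHeightSample` or any 1-D numeric array.
    """
    x = sample.distances if isinstance(sample, AuHeightSample) else np.asarray(sample, float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise ValueError("sample must be a finite 1-D array")
    if x.size < 4:
        raise ValueError("need at least 4 distances to fit a two-component mixture")
    if np.ptp(x) == 0:
        raise UnimodalSampleError("all distances identical: sample is unimodal")
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for restart in range(restarts):
        if restart == 0:
            means0 = np.quantile(x, [0.25, 0.75])
        else:
            means0 = np.sort(rng.choice(x, size=2, replace=False))
        if means0[0] == means0[1]:
            means0 = means0 + np.array([-1e-6, 1e-6]) * max(np.ptp(x), 1.0)
        fit = _em_once(x, means0, tol, max_iter, var_floor)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    if np.isclose(best.means[0], best.means[1], rtol=1e-6, atol=1e-12):
        raise UnimodalSampleError("mixture collapsed to a single mode")
    return best


def bayes_boundary(fit: MixtureFit) -> float:
    """Smallest point between the component means where the posterior flips.

    Solves ``w1 N(t; mu1, s1) = w2 N(t; mu2, s2)`` by bracketing the root of
    the log-posterior difference on (mu1, mu2) to relative tolerance 1e-8.
    """
    mu1, mu2 = fit.means
    if np.isclose(mu1, mu2):
        raise ValueError("component means are not distinct")

    def logdiff(t: float) -> float:
        return (
            np.log(fit.weights[0]) + norm.logpdf(t, mu1, fit.sds[0])
            - np.log(fit.weights[1]) - norm.logpdf(t, mu2, fit.sds[1])
        )

    eps = 1e-12 * (mu2 - mu1)
    ts = np.linspace(mu1 + eps, mu2 - eps, 512)
    vals = np.array([logdiff(t) for t in ts])
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if sign_change.size == 0:
        raise ValueError(
            "no posterior crossing between the means; fit diagnostics: "
            f"weights={fit.weights.tolist()}, means={fit.means.tolist()}, "
            f"sds={fit.sds.tolist()}"
        )
    i = sign_change[0]
    t = brentq(logdiff, ts[i], ts[i + 1], rtol=1e-8)
    return float(t)


def estimate_density_radius(
    data: DataTable,
    model: EsomModel,
    restarts: int = 10,
    tol: float = 1e-9,
    seed: int = 0,
) -> RadiusEstimate:
    """Full radius estimation: project -> AU-heights -> EM mixture -> Bayes boundary.

    Returns ``radius = 0.8 * t_AU``.  Raises :class:`UnimodalSampleError`
    (recommending a manually chosen radius) when the AU-height sample does
    not separate into two modes.
    """
    projection = project(data, model)
    sample = au_heights(projection, model)
    fit = fit_bimodal_gmm(sample, restarts=restarts, tol=tol, seed=seed)
    t_au = bayes_boundary(fit)
    return RadiusEstimate(t_au, RADIUS_FACTOR * t_au, fit, sample)


def save_radius(estimate: RadiusEstimate, path: str | Path) -> None:
    """Serialize a radius estimate as key-value text for CLI hand-off."""
    lines = [
        f"radius: {estimate.radius!r}",
        f"t_au: {estimate.t_au!r}",
        f"weights: {estimate.fit.weights.tolist()!r}",
        f"means: {estimate.fit.means.tolist()!r}",
        f"sds: {estimate.fit.sds.tolist()!r}",
        f"loglik: {estimate.fit.loglik!r}",
        f"converged: {estimate.fit.converged!r}",
        f"n_distances: {estimate.sample.distances.size!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_radius(path: str | Path) -> float:
    """Read back the ``radius`` field of a serialized estimate."""
    for line in Path(path).read_text().splitlines():
        if line.startswith("radius:"):
            return float(line.split(":", 1)[1])
    raise ValueError(f"{path}: no 'radius' field")
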