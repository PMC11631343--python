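"""Discriminator-based validation of generated data.

The battery asks two questions of a pooled original + generated dataset:

1. *Can a classifier tell generated from original points?*  If the
   generator preserves structure, a tuned random forest and a support
   vector machine should perform no better than guessing (balanced
   accuracy ~0.5).
2. *Can a classifier still learn the original classes?*  If so, the
   augmentation has not destroyed class structure (balanced accuracy ~1 on
   well-separated data), ruling out the trivial explanation that the
   classifiers simply do not work on these data.

Protocol: a distribution-matched, class-proportional 20% holdout is set
aside once; each of 100 Monte-Carlo cross-validation runs trains on a
random two-thirds of the remaining pool and validates on a random 80%
subsample of the holdout.  Hyperparameters are tuned once per task on the
pool.  Everything is repeated with independently permuted predictor columns
as an overfitting control, and every variable is compared between original
and generated rows with a two-sided Wilcoxon-Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import ks_2samp, mannwhitneyu
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .generator import GeneratedSet

__all__ = [
    "SplitPlan",
    "TaskResult",
    "EvalReport",
    "balanced_accuracy",
    "distribution_matched_holdout",
    "discriminator_experiment",
    "class_assignment_experiment",
    "variable_tests",
]


@dataclass
class SplitPlan:
    """A class-proportional holdout split with its distribution-match score."""

    holdout_indices: np.ndarray
    pool_indices: np.ndarray
    candidate_scores: np.ndarray

    @property
    def score(self) -> float:
        """Max-over-variables KS statistic of the selected holdout vs the full data."""
        return float(self.candidate_scores.min())


@dataclass
class TaskResult:
    """Balanced-accuracy summary of one task x classifier x control cell."""

    median: float
    lo: float
    hi: float
    values: np.ndarray

    def interval_covers(self, level: float = 0.5) -> bool:
        return self.lo <= level <= self.hi


@dataclass
class EvalReport:
    """Results keyed ``{classifier}`` and ``{classifier}_permuted``."""

    task: str
    results: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> TaskResult:
        return self.results[key]


def balanced_accuracy(truth: Sequence, predicted: Sequence) -> float:
    """Unweighted mean of per-class recall over classes present in the truth."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction must have equal length")
    return float(balanced_accuracy_score(truth, predicted))


def _stratified_indices(
    labels: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Class-proportional sample of ~frac of the rows (>= 1 per class)."""
    chosen = []
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        take = max(1, int(round(members.size * frac)))
        chosen.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def distribution_matched_holdout(
    values: np.ndarray,
    labels: np.ndarray,
    frac: float = 0.2,
    candidates: int = 1000,
    seed: int = 0,
) -> SplitPlan:
    """Select the class-proportional holdout that best matches the full data.

    Each of ``candidates`` random splits is scored by the maximum over
    variables of the two-sample Kolmogorov-Smirnov statistic between the
    holdout and the full dataset; the minimizer is returned.
    """
    if candidates < 1:
        raise ValueError("candidates must be >= 1")
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    scores = np.empty(candidates)
    best_idx: np.ndarray | None = None
    for i in range(candidates):
        holdout = _stratified_indices(labels, frac, rng)
        score = max(
            ks_2samp(values[holdout, j], values[:, j]).statistic
            for j in range(values.shape[1])
        )
        scores[i] = score
        if best_idx is None or score < scores[:i].min(initial=np.inf):
            best_idx = holdout
    assert best_idx is not None
    pool = np.setdiff1d(np.arange(values.shape[0]), best_idx)
    return SplitPlan(best_idx, pool, scores)


def _default_grids(d: int) -> dict:
    return {
        "rf": (
            RandomForestClassifier(random_state=0),
            {
                "n_estimators": [500],
                "max_features": sorted({max(1, int(np.sqrt(d))), max(1, d // 3)}),
            },
        ),
        "svm": (
            SVC(random_state=0),
            {
                "kernel": ["linear", "rbf"],
                "C": [0.1, 1.0, 10.0],
                "gamma": [1.0 / d, "scale"],
            },
        ),
    }


def _tune(name: str, X: np.ndarray, y: np.ndarray, seed: int):
    estimator, grid = _default_grids(X.shape[1])[name]
    n_grid = int(np.prod([len(v) for v in grid.values()]))
    if n_grid == 1:
        return clone(estimator).set_params(**{k: v[0] for k, v in grid.items()})
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(estimator, grid, scoring="balanced_accuracy", cv=cv, n_jobs=1)
    search.fit(X, y)
    return clone(search.best_estimator_)


def _permute_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute every predictor column, destroying joint structure."""
    out = X.copy()
    for j in range(out.shape[1]):
        out[:, j] = rng.permutation(out[:, j])
    return out


def _mccv(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int,
    seed: int,
    classifiers: Iterable[str],
    include_permuted: bool,
    holdout_candidates: int,
) -> dict:
    rng = np.random.default_rng(seed)
    results: dict[str, TaskResult] = {}
    variants = [("", X)]
    if include_permuted:
        variants.append(("_permuted", _permute_columns(X, rng)))
    for suffix, Xv in variants:
        plan = distribution_matched_holdout(
            Xv, y, frac=0.2, candidates=holdout_candidates, seed=int(rng.integers(2**31))
        )
        pool, holdout = plan.pool_indices, plan.holdout_indices
        for name in classifiers:
            model = _tune(name, Xv[pool], y[pool], seed=int(rng.integers(2**31)))
            accs = np.empty(n_runs)
            for run in range(n_runs):
                train = _stratified_indices(y[pool], 2.0 / 3.0, rng)
                train = pool[train]
                val = rng.choice(holdout, size=max(1, int(round(0.8 * holdout.size))), replace=False)
                assert np.intersect1d(train, val).size == 0
                fitted = clone(model)
                if hasattr(fitted, "random_state"):
                    fitted.set_params(random_state=int(rng.integers(2**31)))
                fitted.fit(Xv[train], y[train])
                accs[run] = balanced_accuracy(y[val], fitted.predict(Xv[val]))
            results[name + suffix] = TaskResult(
                float(np.median(accs)),
                float(np.percentile(accs, 2.5)),
                float(np.percentile(accs, 97.5)),
                accs,
            )
    return results


def discriminator_experiment(
    genset: GeneratedSet,
    n_runs: int = 100,
    seed: int = 0,
    classifiers: Iterable[str] = ("rf", "svm"),
    include_permuted: bool = True,
    holdout_candidates: int = 1000,
) -> EvalReport:
    """Train classifiers to detect which pooled rows were generated.

    For a faithful generator the median balanced accuracy sits near the 0.5
    guessing level and the 2.5th-97.5th percentile interval of the 100 runs
    covers 0.5, matching the permuted-predictor control.
    """
    if genset.generated.n == 0:
        raise ValueError("generated set is empty: both origins required")
    X = np.vstack([genset.original.values, genset.generated.values])
    y = np.array([0] * genset.original.n + [1] * genset.generated.n)
    report = EvalReport("generated_vs_original")
    report.results = _mccv(
        X, y, n_runs, seed, classifiers, include_permuted, holdout_candidates
    )
    return report


def class_assignment_experiment(
    genset: GeneratedSet,
    n_runs: int = 100,
    seed: int = 0,
    classifiers: Iterable[str] = ("rf", "svm"),
    include_permuted: bool = True,
    holdout_candidates: int = 1000,
) -> EvalReport:
    """Train classifiers to recover the original class labels on pooled data.

    Succeeding here (while the discriminator task fails) shows the
    augmentation preserved class structure and that the pipeline itself is
    sound.
    """
    if genset.original.labels is None:
        raise ValueError("class assignment requires labeled data")
    pooled = genset.pooled()
    if pooled.labels is None or np.unique(pooled.labels).size < 2:
        raise ValueError("class assignment requires >= 2 classes")
    report = EvalReport("class_assignment")
    report.results = _mccv(
        pooled.values,
        pooled.labels,
        n_runs,
        seed,
        classifiers,
        include_permuted,
        holdout_candidates,
    )
    return report


def variable_tests(genset: GeneratedSet) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per variable, original vs generated.

    No multiplicity adjustment is applied.  A variable with zero variance in
    both groups and identical values gets p = 1 by convention.
    """
    if genset.generated.n == 0:
        raise ValueError("generated set is empty: both origins required")
    orig = genset.original.values
    gen = genset.generated.values
    pvals = np.empty(orig.shape[1])
    for j in range(orig.shape[1]):
        a, b = orig[:, j], gen[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            pvals[j] = 1.0
            continue
        pvals[j] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    return pvals
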