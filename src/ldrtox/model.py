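"""Nested wrapper feature selection for toxicity prediction.

Architecture: an outer sequential backward selection (SBS) loop removes, at
each step, the feature whose exclusion yields the highest validation AUC; an
inner shuffle-and-split (S&S) loop scores every candidate subset as the mean
test-set AUC of an RBF-kernel SVM over many random stratified train/test
partitions of the cohort. Selection stops at the one-in-ten level
(floor(n_patients / 10) retained features). Hyperparameters are tuned by
particle swarm optimization over C in [0, 100] and gamma in [1e-5, 100];
feature importance is reported as the mean AUC of the final model refit with
each selected feature removed (lower AUC after removal = more important).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit, ShuffleSplit
from sklearn.svm import SVC

__all__ = [
    "HyperParams",
    "SplitScheme",
    "SplitPerformance",
    "SBSTrace",
    "shuffle_split_auc",
    "sbs_select",
    "pso_tune",
    "importance_by_removal",
]

C_BOUNDS = (0.0, 100.0)
GAMMA_BOUNDS = (1e-5, 100.0)
FPR_GRID = np.arange(0.0, 1.01, 0.01)

#: SVC needs C strictly positive; the lower box edge is clamped here
_C_FLOOR = 1e-3


@dataclass(frozen=True)
class HyperParams:
    """RBF-SVM hyperparameters, constrained to the search box."""

    C: float = 10.0
    gamma: float = 0.05

    def __post_init__(self) -> None:
        if not C_BOUNDS[0] <= self.C <= C_BOUNDS[1]:
            raise ValueError(f"C={self.C} outside {C_BOUNDS}")
        if not GAMMA_BOUNDS[0] <= self.gamma <= GAMMA_BOUNDS[1]:
            raise ValueError(f"gamma={self.gamma} outside {GAMMA_BOUNDS}")


@dataclass
class SplitScheme:
    """Repeated random train/test partitioning of the whole cohort."""

    n_repeats: int = 1000
    test_fraction: float = 0.2
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("need at least one split")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test fraction must lie in (0, 1)")

    def splits(self, y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Materialized (train, test) index pairs; stratification keeps both
        classes on each side."""
        cls = (StratifiedShuffleSplit if self.stratified else ShuffleSplit)(
            n_splits=self.n_repeats,
            test_size=self.test_fraction,
            random_state=self.master_seed % (2**31),
        )
        out = []
        for tr, te in cls.split(np.zeros((len(y), 1)), y):
            if self.stratified or (len(set(y[tr])) == 2 and len(set(y[te])) == 2):
                out.append((tr, te))
        if not out:
            raise ValueError("no valid splits with both classes present")
        return out


@dataclass
class SplitPerformance:
    """Mean S&S performance of one feature subset."""

    mean_auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    per_split_auc: np.ndarray
    fpr_grid: np.ndarray | None = None
    mean_tpr: np.ndarray | None = None


@dataclass
class SBSTrace:
    """Record of one sequential-backward-selection run."""

    iterations: list[tuple[str, float]]  # (removed feature, mean AUC after removal)
    final_features: list[str]
    final_performance: SplitPerformance
    stop_level: int


def _evaluate(
    X: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    hyper: HyperParams,
    compute_roc: bool = False,
) -> SplitPerformance:
    aucs = np.empty(len(splits))
    acc = np.empty(len(splits))
    sens = np.empty(len(splits))
    spec = np.empty(len(splits))
    tprs = np.empty((len(splits), len(FPR_GRID))) if compute_roc else None
    clf = SVC(C=max(hyper.C, _C_FLOOR), gamma=hyper.gamma, kernel="rbf")
    for i, (tr, te) in enumerate(splits):
        clf.fit(X[tr], y[tr])
        score = clf.decision_function(X[te])
        yt = y[te]
        aucs[i] = roc_auc_score(yt, score)
        pred = (score > 0).astype(int)
        acc[i] = float(np.mean(pred == yt))
        pos, neg = yt == 1, yt == 0
        sens[i] = float(np.mean(pred[pos] == 1)) if pos.any() else np.nan
        spec[i] = float(np.mean(pred[neg] == 0)) if neg.any() else np.nan
        if compute_roc:
            fpr, tpr, _ = roc_curve(yt, score)
            tprs[i] = np.interp(FPR_GRID, fpr, tpr)
    perf = SplitPerformance(
        mean_auc=float(aucs.mean()),
        accuracy=float(np.nanmean(acc)),
        sensitivity=float(np.nanmean(sens)),
        specificity=float(np.nanmean(spec)),
        per_split_auc=aucs,
    )
    if compute_roc:
        mean_tpr = tprs.mean(axis=0)
        mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
        perf.fpr_grid = FPR_GRID.copy()
        perf.mean_tpr = mean_tpr
    return perf


def _evaluate_precomputed(
    K: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    C: float,
) -> float:
    """Mean test AUC with a precomputed kernel matrix (SBS fast path)."""
    clf = SVC(C=max(C, _C_FLOOR), kernel="precomputed")
    total = 0.0
    for tr, te in splits:
        clf.fit(K[np.ix_(tr, tr)], y[tr])
        score = clf.decision_function(K[np.ix_(te, tr)])
        total += roc_auc_score(y[te], score)
    return total / len(splits)


def _feature_sq_dist(x: np.ndarray) -> np.ndarray:
    d = x[:, None] - x[None, :]
    return d * d


def _as_matrix(features: pd.DataFrame, subset: list[str]) -> np.ndarray:
    if not subset:
        raise ValueError("feature subset must be non-empty")
    return features.loc[:, list(subset)].to_numpy(dtype=float)


def shuffle_split_auc(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_subset: list[str] | None = None,
    hyper: HyperParams = HyperParams(),
    scheme: SplitScheme = SplitScheme(),
    compute_roc: bool = True,
) -> SplitPerformance:
    """Mean S&S performance (AUC, accuracy, sensitivity, specificity and the
    vertically averaged ROC) of an RBF-SVM on the given feature subset."""
    y = np.asarray(labels, dtype=int)
    if len(set(y)) != 2:
        raise ValueError("labels must contain both classes")
    subset = list(features.columns) if feature_subset is None else list(feature_subset)
    X = _as_matrix(features, subset)
    return _evaluate(X, y, scheme.splits(y), hyper, compute_roc=compute_roc)


def sbs_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    scheme: SplitScheme = SplitScheme(),
    hyper: HyperParams = HyperParams(),
    stop_level: int | None = None,
    selection_scheme: SplitScheme | None = None,
) -> SBSTrace:
    """Sequential backward selection down to the one-in-ten stop level.

    At each iteration every leave-one-feature-out subset is scored by mean
    S&S AUC; the removal with the highest score (tie: lowest column index)
    is applied. ``selection_scheme`` may use fewer repeats for the per-step
    scoring than the final performance estimate uses.
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if stop_level is None:
        stop_level = n // 10
    if stop_level < 1:
        raise ValueError("one-in-ten stop level below 1; cohort too small")

    current = list(features.columns)
    if len(current) <= stop_level:
        warnings.warn(
            "feature count already at or below the stop level; nothing to remove",
            stacklevel=2,
        )
    sel = selection_scheme or scheme
    sel_splits = sel.splits(y)
    iterations: list[tuple[str, float]] = []
    # leave-one-feature-out RBF kernels share all but one feature's squared
    # distances, so each candidate kernel is the full-set distance matrix
    # minus one per-feature term — exact, and far cheaper than refitting
    # from raw features
    sq_dist = {
        name: _feature_sq_dist(features[name].to_numpy(dtype=float))
        for name in current
    }
    while len(current) > stop_level:
        d_full = np.sum([sq_dist[name] for name in current], axis=0)
        best_auc, best_idx = -np.inf, -1
        for i, name in enumerate(current):
            K = np.exp(-hyper.gamma * (d_full - sq_dist[name]))
            auc = _evaluate_precomputed(K, y, sel_splits, hyper.C)
            if auc > best_auc + 1e-12:
                best_auc, best_idx = auc, i
        removed = current.pop(best_idx)
        iterations.append((removed, float(best_auc)))

    final_perf = _evaluate(
        _as_matrix(features, current), y, scheme.splits(y), hyper, compute_roc=True
    )
    return SBSTrace(
        iterations=iterations,
        final_features=current,
        final_performance=final_perf,
        stop_level=stop_level,
    )


def pso_tune(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_subset: list[str] | None = None,
    scheme: SplitScheme = SplitScheme(),
    n_particles: int = 10,
    n_iters: int = 10,
    seed: int = 0,
    inertia: float = 0.72,
    c_cognitive: float = 1.49,
    c_social: float = 1.49,
) -> HyperParams:
    """Global-best particle swarm search for (C, gamma).

    C moves linearly in [0, 100]; gamma moves in log10 space over
    [1e-5, 100]. The objective is the mean S&S AUC of the subset.
    """
    y = np.asarray(labels, dtype=int)
    subset = list(features.columns) if feature_subset is None else list(feature_subset)
    X = _as_matrix(features, subset)
    splits = scheme.splits(y)

    rng = np.random.default_rng(seed)
    lo = np.array([C_BOUNDS[0], math.log10(GAMMA_BOUNDS[0])])
    hi = np.array([C_BOUNDS[1], math.log10(GAMMA_BOUNDS[1])])
    pos = rng.uniform(lo, hi, size=(n_particles, 2))
    vel = rng.uniform(-(hi - lo), hi - lo, size=(n_particles, 2)) * 0.1
    vmax = 0.5 * (hi - lo)

    def objective(p: np.ndarray) -> float:
        hp = HyperParams(C=float(p[0]), gamma=float(10 ** p[1]))
        return _evaluate(X, y, splits, hp).mean_auc

    pbest = pos.copy()
    pbest_val = np.array([objective(p) for p in pos])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    for _ in range(n_iters):
        r1 = rng.random((n_particles, 2))
        r2 = rng.random((n_particles, 2))
        vel = (
            inertia * vel
            + c_cognitive * r1 * (pbest - pos)
            + c_social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(n_particles):
            val = objective(pos[i])
            if val > pbest_val[i]:
                pbest[i], pbest_val[i] = pos[i].copy(), val
                if val > gbest_val:
                    gbest, gbest_val = pos[i].copy(), val
    return HyperParams(C=float(gbest[0]), gamma=float(10 ** gbest[1]))


def importance_by_removal(
    final_set: list[str],
    features: pd.DataFrame,
    labels: np.ndarray,
    scheme: SplitScheme = SplitScheme(),
    hyper: HyperParams = HyperParams(),
) -> pd.DataFrame:
    """Mean S&S AUC of the final model refit without each selected feature.

    Rows are sorted ascending by that AUC, i.e. most important first: a
    larger drop after removal means the feature mattered more.
    """
    y = np.asarray(labels, dtype=int)
    splits = SplitScheme(
        n_repeats=scheme.n_repeats,
        test_fraction=scheme.test_fraction,
        stratified=scheme.stratified,
        master_seed=scheme.master_seed,
    ).splits(y)
    rows = []
    for name in final_set:
        remaining = [f for f in final_set if f != name]
        if not remaining:
            rows.append((name, np.nan))
            continue
        perf = _evaluate(_as_matrix(features, remaining), y, splits, hyper)
        rows.append((name, perf.mean_auc))
    report = pd.DataFrame(rows, columns=["feature", "mean_auc_after_removal"])
    return report.sort_values(
        "mean_auc_after_removal", kind="stable", na_position="last"
    ).reset_index(drop=True)
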