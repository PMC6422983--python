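"""Feature ranking (RReliefF) and coverage-class prediction (RBF-SVM).

The question asked here: given per-amplicon descriptors (GC content and
the cfDNA fragmentation features), can we predict which amplicons will end
up in the worst tertile of coverage depth (lowest third) or coverage
uniformity (highest CV third)? Features are ranked with the regression
variant of Relief (RReliefF), which scores a feature by how well its local
differences track target differences among nearest neighbors; classes are
then predicted with an RBF-kernel SVM under stratified 3-fold
cross-validation, and feature sets are compared by paired out-of-fold
AUROC differences across seeded replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats import equal_frequency_discretize

__all__ = [
    "ClassifierReport",
    "FeatureSetComparison",
    "rrelieff_rank",
    "define_target_classes",
    "train_eval_svm_rbf",
    "compare_feature_sets",
    "FEATURE_SET_PRESETS",
]

# Shipped feature-set presets: depth prediction pairs GC with the boundary
# depth change; uniformity prediction pairs GC with the spanning-fragment
# count and the depth shape.
FEATURE_SET_PRESETS = {
    "gc_only": ("gc",),
    "depth_combined": ("gc", "feature_c"),
    "uniformity_combined": ("gc", "feature_a", "feature_d"),
}


@dataclass(frozen=True)
class ClassifierReport:
    auroc: float
    auroc_ci_low: float
    auroc_ci_high: float
    precision: float
    feature_set: str
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.auroc_ci_low <= self.auroc <= self.auroc_ci_high):
            raise ValueError("AUROC must lie within its confidence interval")


@dataclass(frozen=True)
class FeatureSetComparison:
    mean_delta_auroc: float
    fraction_positive: float
    deltas: np.ndarray
    auroc_first: np.ndarray
    auroc_second: np.ndarray


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def rrelieff_rank(
    features,
    target,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """RReliefF weights for a continuous target.

    Implements the regression Relief estimator of how well feature
    differences predict target differences among near neighbors. Features
    are min-max scaled internally; neighbor distance is Manhattan in the
    scaled space; the ``k_neighbors`` nearest neighbors of each of
    ``n_iterations`` sampled instances (default: all, in random order)
    contribute with equal weight. The returned weight per feature is

        W[f] = P(diff f | diff target) - P(diff f | same target)

    in its accumulated-probability form: ``N_dC&dF / N_dC -
    (N_dF - N_dC&dF) / (N - N_dC)``. Constant features receive weight 0
    with a warning. Output is a frame with columns ``weight`` and ``rank``
    (1 = most informative), indexed by feature name.
    """
    X, names = _as_matrix(features)
    y = np.asarray(target, dtype=float)
    n, n_feat = X.shape
    if y.shape != (n,):
        raise ValueError("target length does not match features")
    if n < k_neighbors + 1:
        raise ValueError(f"need n >= k_neighbors + 1, have n={n}, k={k_neighbors}")
    y_range = np.ptp(y)
    if y_range == 0:
        raise ValueError("target is constant; relevance undefined")

    spans = np.ptp(X, axis=0)
    constant = spans == 0
    if constant.any():
        warnings.warn(
            f"constant feature(s) {[names[i] for i in np.flatnonzero(constant)]} "
            "receive weight 0"
        )
    safe = np.where(constant, 1.0, spans)
    Xs = (X - X.min(axis=0)) / safe
    Xs[:, constant] = 0.0
    t = (y - y.min()) / y_range

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    m = n if n_iterations is None else min(n_iterations, n)
    picks = order[:m]

    n_dc = 0.0
    n_df = np.zeros(n_feat)
    n_dcdf = np.zeros(n_feat)
    total = 0.0
    w_neighbor = 1.0 / k_neighbors
    for i in picks:
        dist = np.abs(Xs - Xs[i]).sum(axis=1)
        dist[i] = np.inf
        nbrs = np.argpartition(dist, k_neighbors)[:k_neighbors]
        t_diff = np.abs(t[nbrs] - t[i])
        f_diff = np.abs(Xs[nbrs] - Xs[i])
        n_dc += float(t_diff.sum()) * w_neighbor
        n_df += f_diff.sum(axis=0) * w_neighbor
        n_dcdf += (t_diff[:, None] * f_diff).sum(axis=0) * w_neighbor
        total += 1.0
    if n_dc == 0 or total - n_dc == 0:
        raise ValueError("degenerate target differences; cannot form weights")
    weights = n_dcdf / n_dc - (n_df - n_dcdf) / (total - n_dc)
    weights[constant] = 0.0
    out = pd.DataFrame({"weight": weights}, index=pd.Index(names, name="feature"))
    out["rank"] = out["weight"].rank(ascending=False, method="min").astype(int)
    return out.sort_values("rank")


def define_target_classes(values, mode: str) -> np.ndarray:
    """Binary classes from tertiles of a continuous target.

    ``mode='depth'`` labels the lowest tertile positive (amplicons at risk
    of under-coverage); ``mode='uniformity'`` labels the highest tertile
    positive (amplicons with the most variable coverage).
    """
    if mode not in ("depth", "uniformity"):
        raise ValueError(f"mode must be 'depth' or 'uniformity', got {mode!r}")
    groups = equal_frequency_discretize(np.asarray(values, dtype=float), 3)
    positive = 0 if mode == "depth" else 2
    return (groups == positive).astype(int)


def train_eval_svm_rbf(
    features,
    labels,
    folds: int = 3,
    C: float = 1.0,
    gamma="scale",
    n_bootstrap: int = 1000,
    seed: int = 0,
    feature_set: str = "unnamed",
    ci_method: str = "bootstrap",
    n_repeats: int = 20,
) -> ClassifierReport:
    """RBF-SVM class prediction under stratified k-fold cross-validation.

    Features are standardized with training-fold statistics only; decision
    scores of the held-out folds are pooled and scored by AUROC (rank
    statistic). Precision is taken at the SVM's natural decision threshold
    of 0. The 95% CI is a percentile bootstrap over amplicons of the pooled
    out-of-fold scores (``ci_method='bootstrap'``, default) or the
    percentile spread of AUROCs over ``n_repeats`` re-foldings
    (``ci_method='cv_repeats'``).
    """
    X, _ = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")

    def pooled_scores(fold_seed: int) -> np.ndarray:
        scores = np.empty(len(y))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        for train, test in skf.split(X, y):
            if np.unique(y[train]).size < 2:
                raise ValueError("single-class training fold")
            scaler = StandardScaler().fit(X[train])
            clf = SVC(kernel="rbf", C=C, gamma=gamma).fit(scaler.transform(X[train]), y[train])
            scores[test] = clf.decision_function(scaler.transform(X[test]))
        return scores

    scores = pooled_scores(seed)
    auroc = float(roc_auc_score(y, scores))
    precision = float(precision_score(y, (scores > 0).astype(int), zero_division=0))

    rng = np.random.default_rng(seed)
    if ci_method == "bootstrap":
        stats = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(y), len(y))
            if np.unique(y[idx]).size < 2:
                continue
            stats.append(roc_auc_score(y[idx], scores[idx]))
        lo, hi = np.percentile(stats, [2.5, 97.5])
    elif ci_method == "cv_repeats":
        stats = [
            roc_auc_score(y, pooled_scores(int(rng.integers(0, 2**31 - 1))))
            for _ in range(n_repeats)
        ]
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = min(float(lo), auroc), max(float(hi), auroc)
    return ClassifierReport(auroc, lo, hi, precision, feature_set, folds, seed)


def compare_feature_sets(
    features_first,
    features_second,
    labels,
    replicates: int = 20,
    seed: int = 0,
    folds: int = 3,
    **svm_kwargs,
) -> FeatureSetComparison:
    """Paired AUROC comparison of two feature sets on the same amplicons.

    For each replicate both sets are evaluated with identical fold
    assignments (the fold seed is shared), so the AUROC difference
    ``second - first`` is a paired measurement. Reports the mean
    difference and the fraction of replicates where the second set wins.
    """
    X1, _ = _as_matrix(features_first)
    X2, _ = _as_matrix(features_second)
    if X1.shape[0] != X2.shape[0]:
        raise ValueError("feature sets must describe the same amplicons")
    a1, a2 = np.empty(replicates), np.empty(replicates)
    for r in range(replicates):
        fold_seed = seed + r
        a1[r] = train_eval_svm_rbf(
            X1, labels, folds=folds, seed=fold_seed, n_bootstrap=20,
            feature_set="first", **svm_kwargs,
        ).auroc
        a2[r] = train_eval_svm_rbf(
            X2, labels, folds=folds, seed=fold_seed, n_bootstrap=20,
            feature_set="second", **svm_kwargs,
        ).auroc
    deltas = a2 - a1
    return FeatureSetComparison(
        mean_delta_auroc=float(deltas.mean()),
        fraction_positive=float((deltas > 0).mean()),
        deltas=deltas,
        auroc_first=a1,
        auroc_second=a2,
    )
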