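"""Lesion classification: k-NN with LOOCV, ROC analysis, exhaustive
feature-subset search and rank-sum significance.

Scores are the malignant-neighbour fraction of a k-NN classifier (k=4 by
default) evaluated by leave-one-out cross-validation in a standardized
Euclidean space, where the standardization statistics come from the
training fold only. ROC curves and the area under them are computed from
all score thresholds; the operating point maximizes Youden's J.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .features import PARAMETERS, feature_columns

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "ClassifierReport",
    "SearchResult",
    "ComparisonResult",
    "knn_loocv_scores",
    "roc_auc",
    "operating_point",
    "rank_sum_test",
    "significance_class",
    "exhaustive_search",
    "compare_groups",
]

MALIGNANT = "malignant"
BENIGN = "benign"


class RocCurve(NamedTuple):
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


class OperatingPoint(NamedTuple):
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float


@dataclass(frozen=True)
class ClassifierReport:
    features: tuple[str, ...]
    roi_group: str
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    p_value: float
    significance_class: str


@dataclass(frozen=True)
class SearchResult:
    roi_group: str
    reports: pd.DataFrame  # one row per subset, sorted by AUC desc
    best: ClassifierReport
    count: int


@dataclass(frozen=True)
class ComparisonResult:
    table: pd.DataFrame  # subset, auc_internal, auc_external, delta_auc
    n_internal_wins: int
    n_external_wins: int
    n_ties: int
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray


def _as_label_array(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        y = labels == MALIGNANT
    else:
        y = labels.astype(bool)
    return y


def _validate_xy(X: np.ndarray, y: np.ndarray, k: int) -> None:
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("feature matrix and labels disagree in length")
    if n < max(k + 1, 3):
        raise ValueError(f"need at least {max(k + 1, 3)} lesions for LOOCV with k={k}")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")


def knn_loocv_scores(features, labels, k: int = 4) -> np.ndarray:
    """Per-lesion malignancy scores from a leave-one-out k-NN.

    For each held-out lesion the remaining lesions form the training fold;
    every feature is standardized by the fold's mean and standard deviation
    (ddof=1), the ``k`` nearest training lesions by Euclidean distance in
    that space are found (neighbours tied with the k-th distance are all
    included) and the score is the malignant fraction among them. Features
    with zero training-fold standard deviation are dropped for that fold
    with a warning.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_label_array(labels)
    _validate_xy(X, y, k)
    n = len(y)
    scores = np.empty(n)
    warned = False
    for i in range(n):
        train = np.delete(np.arange(n), i)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        usable = sd > 0
        if not usable.all() and not warned:
            warnings.warn("feature with zero training-fold SD dropped", stacklevel=2)
            warned = True
        if not usable.any():
            scores[i] = y[train].mean()
            continue
        z_train = (X[train][:, usable] - mu[usable]) / sd[usable]
        z_test = (X[i, usable] - mu[usable]) / sd[usable]
        d = np.sqrt(((z_train - z_test) ** 2).sum(axis=1))
        kth = np.partition(d, k - 1)[k - 1]
        neighbours = d <= kth
        scores[i] = y[train][neighbours].mean()
    return scores


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over all score thresholds and the area under it.

    Integrating the curve with the trapezoidal rule gives the Mann-Whitney
    probability that a malignant score exceeds a benign one, with ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_label_array(labels)
    pos = int(y.sum())
    neg = int(len(y) - pos)
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    # last index of each tie group of the descending score sequence
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tps = np.cumsum(sorted_y)[distinct]
    fps = np.cumsum(~sorted_y)[distinct]
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(auc=auc, fpr=fpr, tpr=tpr, thresholds=thresholds)


def operating_point(scores, labels) -> OperatingPoint:
    """Sensitivity/specificity/accuracy at the Youden-optimal threshold.

    The threshold maximizes J = sensitivity + specificity - 1; ties are
    broken toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_label_array(labels)
    curve = roc_auc(scores, labels)
    if np.unique(scores).size == 1:
        warnings.warn("all scores equal: degenerate operating point", stacklevel=2)
    sens = curve.tpr
    spec = 1.0 - curve.fpr
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    idx = candidates[np.argmax(sens[candidates])]
    pos = int(y.sum())
    neg = len(y) - pos
    accuracy = (sens[idx] * pos + spec[idx] * neg) / len(y)
    return OperatingPoint(
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
        accuracy=float(accuracy),
        threshold=float(curve.thresholds[idx]),
    )


def significance_class(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "non-significant"


def rank_sum_test(benign_values, malignant_values) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum test between the two groups.

    Uses the exact null distribution when the pooled sample has at most 20
    values and no ties, and the tie-corrected normal approximation
    otherwise. Returns the p-value and its significance class.
    """
    benign = np.asarray(benign_values, dtype=float)
    malignant = np.asarray(malignant_values, dtype=float)
    if benign.size == 0 or malignant.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.r_[benign, malignant]
    if np.unique(pooled).size == 1:
        return 1.0, significance_class(1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(benign, malignant, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return p, significance_class(p)


# ---------------------------------------------------------------------------
# Exhaustive subset search


def _fold_standardized_sqdiffs(X: np.ndarray) -> np.ndarray:
    """Per-feature squared differences standardized by training-fold SDs.

    Returns ``D`` of shape (m, n, n) with
    ``D[f, i, j] = ((x[j, f] - x[i, f]) / s[i, f])**2`` where ``s[i, f]`` is
    the standard deviation (ddof=1) of feature ``f`` over the training fold
    that excludes lesion ``i``. Summing ``D`` over a feature subset gives
    the squared standardized Euclidean distances used by every LOOCV fold at
    once, which is what makes the exhaustive search tractable.
    """
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 lesions")
    s = X.sum(axis=0)
    ss = (X * X).sum(axis=0)
    mean_i = (s - X) / (n - 1)
    var_i = (ss - X * X - (n - 1) * mean_i**2) / (n - 2)
    var_i = np.maximum(var_i, 0.0)
    sd_i = np.sqrt(var_i)
    zero = sd_i == 0
    if zero.any():
        warnings.warn("feature with zero training-fold SD dropped for some folds", stacklevel=3)
        sd_i[zero] = np.inf  # feature contributes nothing for that fold
    diff = X[None, :, :] - X[:, None, :]  # (i, j, f)
    d = (diff / sd_i[:, None, :]) ** 2
    return np.moveaxis(d, 2, 0)


def _scores_from_sqdist(sqdist: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    d = sqdist.copy()
    np.fill_diagonal(d, np.inf)
    kth = np.partition(d, k - 1, axis=1)[:, k - 1]
    neighbours = d <= kth[:, None]
    return (neighbours @ y.astype(float)) / neighbours.sum(axis=1)


def _evaluate_subset(
    sqdist: np.ndarray, y: np.ndarray, k: int, compute_p: bool
) -> tuple[float, OperatingPoint, float, np.ndarray]:
    scores = _scores_from_sqdist(sqdist, y, k)
    curve = roc_auc(scores, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        op = operating_point(scores, y)
    if compute_p:
        p, _ = rank_sum_test(scores[~y], scores[y])
    else:
        p = float("nan")
    return curve.auc, op, p, scores


def exhaustive_search(
    table: pd.DataFrame,
    group: str,
    k: int = 4,
    *,
    max_size: int | None = None,
    compute_p: bool = True,
) -> SearchResult:
    """Evaluate every non-empty feature subset of an ROI group.

    ``group`` selects the columns: ``'internal'`` (``*_int``),
    ``'external'`` (``*_ext``) or ``'combined'`` (all 24). Only columns
    actually present in ``table`` are enumerated, so a pre-filtered table
    restricts the search. Each subset is scored by LOOCV k-NN and ROC/AUC;
    reports are sorted by AUC descending with lexicographic subset-name
    tie-break. ``max_size`` caps the subset cardinality (None enumerates all
    2^m - 1 subsets).
    """
    cols = [c for c in feature_columns(group) if c in table.columns]
    if not cols:
        raise ValueError(f"no feature columns for group {group!r} in table")
    y = _as_label_array(table["label"].to_numpy())
    X = table[cols].to_numpy(dtype=float)
    _validate_xy(X, y, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D = _fold_standardized_sqdiffs(X)
    m = len(cols)
    top = m if max_size is None else min(max_size, m)
    records = []
    for size in range(1, top + 1):
        for combo in itertools.combinations(range(m), size):
            sqdist = D[combo[0]].copy() if size == 1 else D[list(combo)].sum(axis=0)
            auc, op, p, _ = _evaluate_subset(sqdist, y, k, compute_p)
            records.append(
                (
                    "+".join(cols[c] for c in combo),
                    size,
                    auc,
                    op.sensitivity,
                    op.specificity,
                    op.accuracy,
                    p,
                    significance_class(p) if compute_p else "",
                )
            )
    reports = pd.DataFrame(
        records,
        columns=[
            "subset",
            "n_features",
            "auc",
            "sensitivity",
            "specificity",
            "accuracy",
            "p_value",
            "significance",
        ],
    )
    reports = reports.sort_values(
        ["auc", "subset"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    best_row = reports.iloc[0]
    best = ClassifierReport(
        features=tuple(best_row["subset"].split("+")),
        roi_group=group,
        auc=float(best_row["auc"]),
        sensitivity=float(best_row["sensitivity"]),
        specificity=float(best_row["specificity"]),
        accuracy=float(best_row["accuracy"]),
        p_value=float(best_row["p_value"]),
        significance_class=str(best_row["significance"]),
    )
    return SearchResult(roi_group=group, reports=reports, best=best, count=len(reports))


def _base_subset(subset: str) -> str:
    return "+".join(name.rsplit("_", 1)[0] for name in subset.split("+"))


def compare_groups(internal: SearchResult, external: SearchResult) -> ComparisonResult:
    """Pair internal and external searches subset-by-subset and difference
    their AUCs (external minus internal)."""
    int_rep = internal.reports.assign(base=internal.reports["subset"].map(_base_subset))
    ext_rep = external.reports.assign(base=external.reports["subset"].map(_base_subset))
    if internal.count != external.count or set(int_rep["base"]) != set(ext_rep["base"]):
        raise ValueError("internal and external searches enumerate different subsets")
    merged = int_rep[["base", "auc"]].merge(
        ext_rep[["base", "auc"]], on="base", suffixes=("_internal", "_external")
    )
    if len(merged) != internal.count:
        raise ValueError("subset enumeration mismatch between groups")
    merged["delta_auc"] = merged["auc_external"] - merged["auc_internal"]
    merged = merged.rename(columns={"base": "subset"}).sort_values("subset").reset_index(drop=True)
    delta = merged["delta_auc"].to_numpy()
    counts, edges = np.histogram(delta, bins=20)
    return ComparisonResult(
        table=merged,
        n_internal_wins=int((delta < 0).sum()),
        n_external_wins=int((delta > 0).sum()),
        n_ties=int((delta == 0).sum()),
        histogram_counts=counts,
        histogram_edges=edges,
    )
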