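"""Seven filter-based feature rankers used as comparators to MCFS.

chi-squared, information gain, gain ratio and symmetrical uncertainty operate
on a supervised discretization of each feature (Fayyad-Irani MDL by default,
the discretization Weka applies internally); correlation uses the raw values;
OneR scores a feature by the accuracy of its one-rule classifier; ReliefF
contrasts nearest hits and misses.  All entropies are in bits.  Rankings share
the tie-break used everywhere in the package: score descending, then feature
ID ascending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .io import CombinedMatrix
from .mcfs import FeatureRanking

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizedFeature",
    "discretize",
    "score_chi2",
    "score_infogain",
    "score_gainratio",
    "score_symuncert",
    "score_correlation",
    "score_oner",
    "score_relieff",
    "rank_all",
    "FILTER_METHODS",
]

FILTER_METHODS = (
    "ChiSquared",
    "Correlation",
    "GainRatio",
    "InfoGain",
    "OneR",
    "ReliefF",
    "SymmetricalUncert",
)


@dataclass
class DiscretizedFeature:
    """Per-sample bin assignment of one feature; bins are ordinal 0..B-1."""

    bins: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        if self.n_bins < 1:
            raise ValidationError(f"n_bins must be >= 1, got {self.n_bins}")
        if len(self.bins) and (self.bins.min() < 0 or self.bins.max() >= self.n_bins):
            raise ValidationError("bin indices out of range")


def _entropy_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _entropy_labels(y: np.ndarray) -> float:
    return _entropy_counts(np.unique(y, return_counts=True)[1])


def _mdl_cuts(xs: np.ndarray, ys: np.ndarray, lo: int, hi: int, cuts: list[float]) -> None:
    """Recursive Fayyad-Irani MDL partitioning of the sorted slice [lo, hi)."""
    n = hi - lo
    if n < 2:
        return
    seg_y = ys[lo:hi]
    ent_s = _entropy_labels(seg_y)
    if ent_s == 0.0:
        return
    # candidate cuts: boundaries between distinct adjacent values
    best_gain, best_i = -1.0, -1
    best_e1 = best_e2 = 0.0
    # incremental class counts left of the cut
    classes = np.unique(seg_y)
    code = {c: i for i, c in enumerate(classes)}
    left = np.zeros(len(classes))
    total = np.bincount([code[c] for c in seg_y], minlength=len(classes)).astype(float)
    for i in range(1, n):
        left[code[seg_y[i - 1]]] += 1
        if xs[lo + i] == xs[lo + i - 1]:
            continue
        right = total - left
        e1 = _entropy_counts(left)
        e2 = _entropy_counts(right)
        gain = ent_s - (i / n) * e1 - ((n - i) / n) * e2
        if gain > best_gain + 1e-12:
            best_gain, best_i, best_e1, best_e2 = gain, i, e1, e2
    if best_i < 0:
        return
    k = len(classes)
    k1 = len(np.unique(seg_y[:best_i]))
    k2 = len(np.unique(seg_y[best_i:]))
    delta = math.log2(3**k - 2) - (k * ent_s - k1 * best_e1 - k2 * best_e2)
    threshold = (math.log2(n - 1) + delta) / n
    if best_gain <= threshold:
        return
    cuts.append((xs[lo + best_i - 1] + xs[lo + best_i]) / 2.0)
    _mdl_cuts(xs, ys, lo, lo + best_i, cuts)
    _mdl_cuts(xs, ys, lo + best_i, hi, cuts)


def discretize(x, labels, method: str = "mdl") -> DiscretizedFeature:
    """Supervised discretization; ``mdl`` (Fayyad-Irani) accepts a binary
    split iff its information gain exceeds the MDL coding cost, recursively.
    A constant vector (or one with no accepted cut) maps to a single bin.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature values must be finite")
    if method != "mdl":
        raise ValidationError(f"unknown discretization method {method!r}")
    order = np.argsort(x, kind="mergesort")
    cuts: list[float] = []
    _mdl_cuts(x[order], labels[order], 0, len(x), cuts)
    cuts.sort()
    bins = np.searchsorted(cuts, x, side="right") if cuts else np.zeros(len(x), dtype=int)
    return DiscretizedFeature(bins, len(cuts) + 1)


def _contingency(f: DiscretizedFeature, labels: np.ndarray) -> np.ndarray:
    classes, y_idx = np.unique(labels, return_inverse=True)
    table = np.zeros((f.n_bins, len(classes)))
    np.add.at(table, (f.bins, y_idx), 1.0)
    return table


def score_chi2(f: DiscretizedFeature, labels) -> float:
    """Pearson chi-squared statistic of the bin x class contingency table."""
    table = _contingency(f, np.asarray(labels))
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = expected > 0
    return float((((table - expected) ** 2)[mask] / expected[mask]).sum())


def score_infogain(f: DiscretizedFeature, labels) -> float:
    """IG = H(C) - H(C|X) in bits (the mutual information of bins and class)."""
    labels = np.asarray(labels)
    table = _contingency(f, labels)
    n = table.sum()
    h_c = _entropy_counts(table.sum(axis=0))
    h_c_given_x = sum(
        (row.sum() / n) * _entropy_counts(row) for row in table if row.sum() > 0
    )
    return max(float(h_c - h_c_given_x), 0.0)


def score_gainratio(f: DiscretizedFeature, labels) -> float:
    """IG / H(X); 0 when H(X) = 0 (single bin)."""
    table = _contingency(f, np.asarray(labels))
    h_x = _entropy_counts(table.sum(axis=1))
    if h_x == 0.0:
        return 0.0
    return score_infogain(f, labels) / h_x


def score_symuncert(f: DiscretizedFeature, labels) -> float:
    """2 IG / (H(C) + H(X)); 0 when the denominator is 0."""
    table = _contingency(f, np.asarray(labels))
    h_x = _entropy_counts(table.sum(axis=1))
    h_c = _entropy_counts(table.sum(axis=0))
    if h_x + h_c == 0.0:
        return 0.0
    return 2.0 * score_infogain(f, labels) / (h_x + h_c)


def score_correlation(x, labels) -> float:
    """|Pearson r| between the raw feature and the 0/1 class; 0 if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def score_oner(f: DiscretizedFeature, labels, min_bucket: int = 6) -> float:
    """Accuracy of the one-rule classifier built on the feature's bins.

    Adjacent bins are merged left to right until every bucket holds at least
    ``min_bucket`` samples (a trailing small bucket merges backwards); the
    rule predicts the majority class per bucket.
    """
    labels = np.asarray(labels)
    table = _contingency(f, labels)
    buckets: list[np.ndarray] = []
    current = np.zeros(table.shape[1])
    for row in table:
        current = current + row
        if current.sum() >= min_bucket:
            buckets.append(current)
            current = np.zeros(table.shape[1])
    if current.sum() > 0:
        if buckets:
            buckets[-1] = buckets[-1] + current
        else:
            buckets.append(current)
    n = table.sum()
    correct = sum(b.max() for b in buckets)
    return float(correct / n)


def score_relieff(X, labels, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF weights for every feature (vector in [-1, 1]).

    Every sample is an anchor.  For each anchor, the k nearest hits (same
    class) and k nearest misses per other class are found under Manhattan
    distance on range-normalized features; per-feature differences (also
    range-normalized) decrease the weight for hits and increase it for
    misses, miss classes weighted by their prior odds.  A class smaller than
    k+1 contributes with its reduced neighbor count.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_ = hi - lo
    nz = rng_ > 0
    Xn = np.zeros_like(X)
    Xn[:, nz] = (X[:, nz] - lo[nz]) / rng_[nz]
    D = cdist(Xn, Xn, metric="cityblock")
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    members = {c: np.flatnonzero(y == c) for c in classes}
    weights = np.zeros(d)
    for i in range(n):
        ci = y[i]
        for c in classes:
            cand = members[c][members[c] != i]
            if len(cand) == 0:
                continue
            k_c = min(k_neighbors, len(cand))
            if k_c < k_neighbors:
                logger.debug("ReliefF: class %r smaller than k+1, using k=%d", c, k_c)
            # stable nearest-neighbor selection: distance, then sample index
            order = cand[np.lexsort((cand, D[i, cand]))][:k_c]
            diffsum = np.abs(Xn[i] - Xn[order]).sum(axis=0)
            if c == ci:
                weights -= diffsum / (n * k_c)
            else:
                weights += (priors[c] / (1.0 - priors[ci])) * diffsum / (n * k_c)
    return weights


def rank_all(
    data: CombinedMatrix,
    *,
    k_neighbors: int = 10,
    min_bucket: int = 6,
) -> dict[str, FeatureRanking]:
    """All seven filter rankings over the combined matrix.

    Discretization is computed once per feature and shared by the four
    entropy/chi-squared scorers and OneR.
    """
    y = data.labels
    ids = data.feature_ids
    d = data.n_features
    scores: dict[str, np.ndarray] = {m: np.zeros(d) for m in FILTER_METHODS}
    for j in range(d):
        x = data.values[:, j]
        disc = discretize(x, y)
        scores["ChiSquared"][j] = score_chi2(disc, y)
        scores["InfoGain"][j] = score_infogain(disc, y)
        scores["GainRatio"][j] = score_gainratio(disc, y)
        scores["SymmetricalUncert"][j] = score_symuncert(disc, y)
        scores["OneR"][j] = score_oner(disc, y, min_bucket=min_bucket)
        scores["Correlation"][j] = score_correlation(x, y)
    scores["ReliefF"] = score_relieff(data.values, y, k_neighbors=k_neighbors)
    return {m: FeatureRanking.from_scores(list(ids), s) for m, s in scores.items()}
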