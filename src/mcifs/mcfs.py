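"""Monte-Carlo feature selection (MCFS).

The method ranks features of a wide two-class matrix by aggregating decision
trees built on many small random feature subspaces.  For ``s`` random draws of
``m`` features (m << d) it grows ``t`` trees, each on its own stratified
train/test split, and credits every feature ``g`` with a relative importance

    RI_g = sum over trees tau of
           wAcc(tau)^u * sum over nodes of tau splitting on g of
           IG(node) * (n_node / n_tree)^v

where ``wAcc`` is the tree's weighted (per-class mean recall) accuracy on its
held-out split, ``IG`` the information gain of the split node in bits,
``n_node`` the training samples reaching the node and ``n_tree`` the tree's
training-set size.  Features are ranked by RI descending; ties (notably the
shared RI of never-used features, 0) break lexicographically on feature ID so
output is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, ValidationError
from .io import CombinedMatrix, tissue_of

logger = logging.getLogger(__name__)

__all__ = [
    "MCFSConfig",
    "TreeRecord",
    "FeatureRanking",
    "weighted_accuracy",
    "grow_tree",
    "relative_importance",
    "run_mcfs",
]


@dataclass
class MCFSConfig:
    """Hyperparameters of the tree-ensemble importance run.

    ``m=None`` resolves to ceil(0.05 * d) (capped at d).  ``u`` and ``v``
    weight tree accuracy and node sample coverage respectively; both default
    to the neutral 1.
    """

    s: int = 1000
    t: int = 5
    m: int | None = None
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    seed: int = 0

    def validate(self) -> None:
        if self.s < 1 or self.t < 1:
            raise ConfigError(f"s and t must be >= 1, got s={self.s}, t={self.t}")
        if self.m is not None and self.m < 1:
            raise ConfigError(f"m must be >= 1, got {self.m}")
        if self.u < 0 or self.v < 0:
            raise ConfigError(f"u and v must be >= 0, got u={self.u}, v={self.v}")
        if not 0 < self.train_fraction < 1:
            raise ConfigError(f"train_fraction must be in (0,1), got {self.train_fraction}")

    def resolved_m(self, d: int) -> int:
        if self.m is not None:
            if self.m > d:
                raise ConfigError(f"m={self.m} exceeds feature count d={d}")
            return self.m
        return min(d, math.ceil(0.05 * d))


@dataclass
class TreeRecord:
    """Per-tree evidence entering the RI sum.

    ``nodes`` holds one tuple (feature_id, information gain in bits,
    samples reaching the node, training samples of the tree) per internal
    node; leaf-only trees have an empty list.
    """

    wacc: float
    nodes: list[tuple[str, float, int, int]] = field(default_factory=list)


def weighted_accuracy(cm) -> float:
    """Mean per-class recall of a confusion matrix.

    ``cm[i, j]`` counts samples of class i predicted as class j.  Classes with
    zero row total are excluded from the average (avoids 0/0 on tiny held-out
    splits); an all-zero matrix is an error.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError(f"confusion matrix must be square, got shape {cm.shape}")
    if np.any(cm < 0):
        raise ValidationError("confusion matrix counts must be non-negative")
    row_totals = cm.sum(axis=1)
    present = row_totals > 0
    if not present.any():
        raise ValidationError("confusion matrix has no samples")
    recalls = np.diag(cm)[present] / row_totals[present]
    return float(recalls.mean())


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test index split; every class keeps >=2 train
    samples (and >=1 test sample where the class allows it)."""
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        perm = rng.permutation(members)
        n_c = len(members)
        n_train = int(round(train_fraction * n_c))
        n_train = max(n_train, min(2, n_c))
        if n_c >= 3:
            n_train = min(n_train, n_c - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    *,
    train_fraction: float = 0.66,
    rng: np.random.Generator | None = None,
) -> TreeRecord:
    """Grow one CART tree on a stratified split of (X, y) and record it.

    The tree uses the information-gain (entropy, bits) split criterion, is
    grown to purity with minimum leaf size 2 and no pruning.  Degenerate
    inputs (constant features, pure labels) yield a leaf-only tree whose
    held-out accuracy is that of the majority-class prediction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train, test = _stratified_split(y, train_fraction, rng)
    tree_seed = int(rng.integers(2**31 - 1))
    clf = DecisionTreeClassifier(
        criterion="entropy", min_samples_leaf=2, random_state=tree_seed
    )
    clf.fit(X[train], y[train])

    t = clf.tree_
    n_tree = len(train)
    nodes: list[tuple[str, float, int, int]] = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        w = t.weighted_n_node_samples
        ig = t.impurity[node] - (
            w[left] / w[node] * t.impurity[left] + w[right] / w[node] * t.impurity[right]
        )
        nodes.append(
            (feature_ids[t.feature[node]], max(float(ig), 0.0), int(t.n_node_samples[node]), n_tree)
        )

    eval_idx = test if len(test) else train
    pred = clf.predict(X[eval_idx])
    classes = np.unique(y)
    cm = np.zeros((len(classes), len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for yt, yp in zip(y[eval_idx], pred):
        cm[pos[yt], pos[yp]] += 1
    return TreeRecord(wacc=weighted_accuracy(cm), nodes=nodes)


@dataclass
class FeatureRanking:
    """Features ordered by relative importance, descending.

    Ranks are 1-based and strictly increasing; ties in score are broken by
    feature ID so the order is total and deterministic.
    """

    feature_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.feature_ids) != len(self.scores):
            raise ValidationError("feature_ids and scores must have equal length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be non-increasing in rank order")
        self._rank = {f: i + 1 for i, f in enumerate(self.feature_ids)}
        if len(self._rank) != len(self.feature_ids):
            raise ValidationError("feature_ids must be unique")

    @classmethod
    def from_scores(
        cls,
        feature_ids: list[str],
        scores,
        tie_rng: np.random.Generator | None = None,
    ) -> "FeatureRanking":
        """Rank by score descending.

        Ties break lexicographically on feature ID by default; with
        ``tie_rng`` they break by a random permutation drawn from it instead,
        which keeps the output deterministic given the generator's seed while
        leaving tied features exchangeable (no alphabetic bias in the large
        zero-score block a subsampled ensemble produces).
        """
        scores = np.asarray(scores, dtype=float)
        if tie_rng is None:
            order = sorted(range(len(feature_ids)), key=lambda i: (-scores[i], feature_ids[i]))
        else:
            jitter = tie_rng.permutation(len(feature_ids))
            order = sorted(range(len(feature_ids)), key=lambda i: (-scores[i], jitter[i]))
        return cls([feature_ids[i] for i in order], scores[order])

    def __len__(self) -> int:
        return len(self.feature_ids)

    def rank_of(self, feature_id: str) -> int:
        return self._rank[feature_id]

    def score_of(self, feature_id: str) -> float:
        return float(self.scores[self._rank[feature_id] - 1])

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "feature_id": self.feature_ids,
                "tissue": [tissue_of(f) or "" for f in self.feature_ids],
                "ri": self.scores,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureRanking":
        df = pd.read_csv(path, sep="\t")
        return cls(df["feature_id"].tolist(), df["ri"].to_numpy(dtype=float))


def relative_importance(
    trees: list[TreeRecord],
    config: MCFSConfig | None = None,
    feature_ids: list[str] | None = None,
    tie_rng: np.random.Generator | None = None,
) -> FeatureRanking:
    """Aggregate per-tree node records into the RI ranking.

    Features never used in any node receive RI 0; if ``feature_ids`` is given
    they all appear in the output, otherwise only features seen in the trees.
    """
    if not trees:
        raise ValidationError("trees must be nonempty")
    config = config or MCFSConfig()
    ri: dict[str, float] = {f: 0.0 for f in (feature_ids or [])}
    for rec in trees:
        w = rec.wacc**config.u
        for fid, ig, n_node, n_tree in rec.nodes:
            ri[fid] = ri.get(fid, 0.0) + w * ig * (n_node / n_tree) ** config.v
    ids = list(ri.keys())
    return FeatureRanking.from_scores(ids, [ri[f] for f in ids], tie_rng=tie_rng)


def run_mcfs(data: CombinedMatrix, config: MCFSConfig | None = None) -> FeatureRanking:
    """Full MCFS run: s subspace draws x t trees, aggregated into one ranking.

    Deterministic given ``config.seed``; the subset draws and all per-tree
    splits flow from a single generator in a fixed order.
    """
    config = config or MCFSConfig()
    config.validate()
    d = data.n_features
    m = config.resolved_m(d)
    if len(np.unique(data.labels)) < 2:
        raise ValidationError("both classes must be present")
    rng = np.random.default_rng(config.seed)
    trees: list[TreeRecord] = []
    for i in range(config.s):
        subset = np.sort(rng.choice(d, size=m, replace=False))
        ids = [data.feature_ids[j] for j in subset]
        X_sub = data.values[:, subset]
        for _ in range(config.t):
            trees.append(
                grow_tree(
                    X_sub,
                    data.labels,
                    ids,
                    train_fraction=config.train_fraction,
                    rng=rng,
                )
            )
        if (i + 1) % 100 == 0:
            logger.debug("MCFS: %d/%d subsets done", i + 1, config.s)
    # ties (notably the shared RI of never-used features) break by a
    # seed-derived permutation: deterministic per seed, exchangeable across
    # seeds, so a signal-free feature's rank is uniform under the null
    tie_rng = np.random.default_rng(np.random.default_rng(config.seed ^ 0x5EED).integers(2**31))
    return relative_importance(trees, config, feature_ids=data.feature_ids, tie_rng=tie_rng)
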