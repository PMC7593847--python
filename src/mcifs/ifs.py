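"""Incremental feature selection (IFS) with leave-one-out cross-validation.

Given a full feature ranking, IFS evaluates the nested top-k feature sets
F_1 subset F_2 subset ... with a classifier whose accuracy is estimated by
LOOCV, producing a (k, accuracy) curve.  The final key-feature set is chosen
by a delta rule: the smallest k whose accuracy is within ``delta`` of the
curve's maximum, formalizing the usual complexity/performance trade-off
(e.g. preferring 26 features at 0.94 over 175 at 0.96 when delta=0.02).

The ranking is computed once on the full dataset and reused inside LOOCV.
This mirrors the reference protocol but induces feature-selection bias: the
held-out sample influenced the ranking.  Accuracies on the IFS curve are
therefore optimistic for generalization; an honest variant would re-rank
inside every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.dummy import DummyClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, ValidationError
from .io import CombinedMatrix, tissue_of
from .mcfs import FeatureRanking

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "IFSCurve",
    "KeyFeatureReport",
    "loocv_accuracy",
    "ifs_scan",
    "select_key_set",
    "summarize_key_features",
]

CLASSIFIER_NAMES = ("svm", "tree", "knn", "nbayes", "dummy")


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier plus its hyperparameters.

    Defaults mirror common R defaults: SVM with RBF kernel, cost 1,
    gamma = 1/(number of features), features standardized per training fold;
    1-nearest-neighbor; CART decision tree; Gaussian naive Bayes.  ``dummy``
    (majority class) is provided as a chance-level baseline.
    """

    name: str = "svm"
    kernel: str = "rbf"
    cost: float = 1.0
    gamma: float | str = "auto"  # "auto" = 1 / n_features
    k: int = 1

    def validate(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigError(f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}")
        if self.cost <= 0:
            raise ConfigError(f"cost must be positive, got {self.cost}")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")

    def build(self):
        """Fresh (unfitted) sklearn estimator for this spec."""
        self.validate()
        if self.name == "svm":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svm", SVC(kernel=self.kernel, C=self.cost, gamma=self.gamma)),
                ]
            )
        if self.name == "tree":
            return DecisionTreeClassifier(random_state=0)
        if self.name == "knn":
            return KNeighborsClassifier(n_neighbors=self.k)
        if self.name == "nbayes":
            return GaussianNB()
        return DummyClassifier(strategy="most_frequent")


def loocv_accuracy(X, y, clf: ClassifierSpec) -> float:
    """Leave-one-out cross-validated accuracy.

    Each sample is predicted by a model fitted on the other n-1; any
    standardization is fitted on those n-1 only (inside the pipeline).  If a
    training fold loses a class entirely, that fold predicts the remaining
    class and is counted normally.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValidationError(f"LOOCV needs n >= 3 samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    proto = clf.build()
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        classes = np.unique(y_train)
        if len(classes) < 2:
            logger.debug("LOOCV fold %d: training fold lost a class", i)
            pred = classes[0]
        else:
            model = clone(proto)
            model.fit(X[mask], y_train)
            pred = model.predict(X[i : i + 1])[0]
        correct += int(pred == y[i])
    return correct / n


@dataclass
class IFSCurve:
    """LOOCV accuracy of the nested top-k feature sets."""

    ks: np.ndarray
    accuracies: np.ndarray
    classifier: str

    def __post_init__(self) -> None:
        self.ks = np.asarray(self.ks, dtype=int)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.ks) != len(self.accuracies) or len(self.ks) == 0:
            raise ValidationError("curve must have matching, nonempty k/accuracy arrays")
        if np.any(np.diff(self.ks) <= 0):
            raise ValidationError("k values must be strictly increasing")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValidationError("accuracies must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "accuracy": self.accuracies})

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, classifier: str = "svm") -> "IFSCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df["k"].to_numpy(), df["accuracy"].to_numpy(), classifier)

    def plot(self, ax=None):
        """Accuracy vs number of top-ranked features."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ks, self.accuracies, marker=".", lw=1)
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("LOOCV accuracy")
        ax.set_title(f"IFS curve ({self.classifier})")
        ax.set_ylim(0, 1.02)
        return ax


def ifs_scan(
    data: CombinedMatrix,
    ranking: FeatureRanking,
    clf: ClassifierSpec | None = None,
    K: int = 500,
) -> IFSCurve:
    """Evaluate LOOCV accuracy of the top-k feature sets for k = 1..K."""
    clf = clf or ClassifierSpec()
    if K < 1:
        raise ConfigError(f"K must be >= 1, got {K}")
    if K > len(ranking):
        raise ConfigError(f"K={K} exceeds number of ranked features ({len(ranking)})")
    col = {f: j for j, f in enumerate(data.feature_ids)}
    try:
        order = [col[f] for f in ranking.top(K)]
    except KeyError as exc:
        raise ValidationError(f"ranked feature {exc} missing from data") from None
    X_ordered = data.values[:, order]
    accs = np.empty(K)
    for k in range(1, K + 1):
        accs[k - 1] = loocv_accuracy(X_ordered[:, :k], data.labels, clf)
        if k % 50 == 0:
            logger.debug("IFS: k=%d/%d done", k, K)
    return IFSCurve(np.arange(1, K + 1), accs, clf.name)


def select_key_set(curve: IFSCurve, delta: float = 0.02) -> tuple[int, int]:
    """(k_peak, k_final): smallest k at maximum accuracy, and the smallest k
    whose accuracy is within ``delta`` of that maximum."""
    if delta < 0:
        raise ConfigError(f"delta must be >= 0, got {delta}")
    accs = curve.accuracies
    best = accs.max()
    k_peak = int(curve.ks[int(np.argmax(accs))])  # argmax returns first = smallest k
    k_final = int(curve.ks[int(np.argmax(accs >= best - delta))])
    return k_peak, k_final


@dataclass
class KeyFeatureReport:
    """The selected key features with their tissue attribution."""

    table: pd.DataFrame  # columns: rank, feature_id, tissue, ri
    tissue_counts: dict[str, int]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_key_features(
    data: CombinedMatrix, ranking: FeatureRanking, k_final: int
) -> KeyFeatureReport:
    """Tabulate the top-``k_final`` features with per-tissue counts."""
    if not 1 <= k_final <= len(ranking):
        raise ConfigError(f"k_final must be in [1, {len(ranking)}], got {k_final}")
    feats = ranking.top(k_final)
    tissues = [tissue_of(f) or "" for f in feats]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, k_final + 1),
            "feature_id": feats,
            "tissue": tissues,
            "ri": [ranking.score_of(f) for f in feats],
        }
    )
    counts = {t: tissues.count(t) for t in ("tumor", "adjacent")}
    return KeyFeatureReport(table, counts)
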