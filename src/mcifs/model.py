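"""Model/results front-end over the functional pipeline.

Follows the fit/results convention of statistical modelling packages: a
:class:`MonteCarloFS` model is built from a patients-by-features matrix with
binary labels; ``fit()`` runs the Monte-Carlo tree ensemble and returns a
:class:`MonteCarloFSResults` carrying the relative-importance ranking, whose
``ifs()`` method performs the incremental feature selection and yields an
:class:`IFSResults` with the accuracy curve, the selected key-feature set and
a ``summary()`` table.

Example
-------
>>> from mcifs import synthetic, io, model
>>> t, a, ann, truth = synthetic.generate_cohort(synthetic.SyntheticSpec(d=100, seed=1))
>>> data = io.combine_tissues(t, a, ann)
>>> res = model.MonteCarloFS(data, model.MCFSConfig(s=50, t=5, seed=1)).fit()
>>> ifs_res = res.ifs(k_max=30)
>>> print(ifs_res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ifs import (
    ClassifierSpec,
    IFSCurve,
    KeyFeatureReport,
    ifs_scan,
    select_key_set,
    summarize_key_features,
)
from .io import CombinedMatrix
from .mcfs import FeatureRanking, MCFSConfig, run_mcfs

__all__ = ["MonteCarloFS", "MonteCarloFSResults", "IFSResults"]


class MonteCarloFS:
    """Monte-Carlo feature selection model over a combined cohort matrix."""

    def __init__(self, data: CombinedMatrix, config: MCFSConfig | None = None):
        self.data = data
        self.config = config or MCFSConfig()

    @classmethod
    def from_dataframe(
        cls,
        X: pd.DataFrame,
        labels,
        config: MCFSConfig | None = None,
    ) -> "MonteCarloFS":
        """Build from a patients-by-features DataFrame and a label vector."""
        data = CombinedMatrix(
            feature_ids=[str(c) for c in X.columns],
            patients=[str(i) for i in X.index],
            values=X.to_numpy(dtype=float),
            labels=np.asarray(labels, dtype=int),
        )
        return cls(data, config)

    def fit(self) -> "MonteCarloFSResults":
        ranking = run_mcfs(self.data, self.config)
        return MonteCarloFSResults(self, ranking)


@dataclass
class MonteCarloFSResults:
    """Fitted MCFS ranking plus entry points to downstream selection."""

    model: MonteCarloFS
    ranking: FeatureRanking

    @property
    def ri(self) -> pd.Series:
        """Relative importance per feature, rank order."""
        return pd.Series(self.ranking.scores, index=self.ranking.feature_ids, name="ri")

    def summary(self, top: int = 10) -> str:
        df = self.ranking.to_dataframe().head(top)
        lines = [
            "Monte-Carlo feature selection",
            f"  features: {len(self.ranking)}   patients: {self.model.data.n_patients}",
            f"  trees: s={self.model.config.s} x t={self.model.config.t}"
            f"   m={self.model.config.resolved_m(len(self.ranking))}"
            f"   u={self.model.config.u} v={self.model.config.v}",
            "",
            df.to_string(index=False),
        ]
        return "\n".join(lines)

    def ifs(
        self,
        classifier: ClassifierSpec | str = "svm",
        k_max: int = 500,
        delta: float = 0.02,
    ) -> "IFSResults":
        """Incremental feature selection along this ranking."""
        clf = ClassifierSpec(name=classifier) if isinstance(classifier, str) else classifier
        K = min(k_max, len(self.ranking))
        curve = ifs_scan(self.model.data, self.ranking, clf, K=K)
        k_peak, k_final = select_key_set(curve, delta)
        report = summarize_key_features(self.model.data, self.ranking, k_final)
        return IFSResults(self, curve, k_peak, k_final, report, delta)


@dataclass
class IFSResults:
    """Outcome of the incremental feature selection scan."""

    parent: MonteCarloFSResults
    curve: IFSCurve
    k_peak: int
    k_final: int
    key_features: KeyFeatureReport
    delta: float

    @property
    def peak_accuracy(self) -> float:
        return float(self.curve.accuracies.max())

    @property
    def final_accuracy(self) -> float:
        return float(self.curve.accuracies[self.k_final - 1])

    def summary(self) -> str:
        counts = self.key_features.tissue_counts
        lines = [
            f"Incremental feature selection ({self.curve.classifier}, LOOCV)",
            f"  peak accuracy {self.peak_accuracy:.3f} at k={self.k_peak}",
            f"  selected k={self.k_final} (accuracy {self.final_accuracy:.3f},"
            f" delta={self.delta})",
            f"  tissue split: {counts.get('tumor', 0)} tumor /"
            f" {counts.get('adjacent', 0)} adjacent",
            "",
            self.key_features.table.to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """IFS curve with the peak and selected k marked."""
        ax = self.curve.plot(ax=ax)
        ax.axvline(self.k_peak, color="gray", ls="--", lw=0.8)
        ax.axvline(self.k_final, color="red", ls="--", lw=0.8)
        return ax
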