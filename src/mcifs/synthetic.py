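"""Synthetic paired-tissue two-class expression cohorts with planted signal.

Emulates the statistical structure of a paired tumor/adjacent microarray
cohort: 50 patients (28 phenotype-positive, 22 negative by default), one
probe-by-sample log-expression matrix per tissue, and a small set of planted
probes whose class-conditional mean is shifted by ``effect * sigma`` in
phenotype-positive patients.  Planted probes within a tissue share an
equicorrelated Gaussian noise component (a shared latent factor), mimicking
co-regulated genes.  All randomness flows from a single integer seed, so a
given spec reproduces byte-identical cohorts.

The generator emits already-normalized values; the downstream pipeline
assumes normalized input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import ExpressionMatrix, SampleAnnotation, TISSUE_SEP

__all__ = ["SyntheticSpec", "TruthSet", "generate_cohort", "write_truth", "read_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-signal cohort.

    Defaults mirror the reference cohort design: 28 positive / 22 negative
    patients, a desk-scale 1,000 probes per tissue, and 15 tumor + 11 adjacent
    planted discriminative probes at a standardized shift of 2 residual SDs.
    """

    n_pos: int = 28
    n_neg: int = 22
    d: int = 1000
    planted_tumor: int = 15
    planted_adjacent: int = 11
    effect: float = 2.0
    sigma: float = 1.0
    block_rho: float = 0.3
    seed: int = 0

    # baseline log2-intensity model; arbitrary for rank-based stages
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0

    def validate(self) -> None:
        if self.n_pos < 2:
            raise ValidationError(f"n_pos must be >= 2, got {self.n_pos}")
        if self.n_neg < 2:
            raise ValidationError(f"n_neg must be >= 2, got {self.n_neg}")
        if self.d < 1:
            raise ValidationError(f"d must be >= 1, got {self.d}")
        if self.planted_tumor < 0 or self.planted_tumor > self.d:
            raise ValidationError(
                f"planted_tumor must be in [0, d={self.d}], got {self.planted_tumor}"
            )
        if self.planted_adjacent < 0 or self.planted_adjacent > self.d:
            raise ValidationError(
                f"planted_adjacent must be in [0, d={self.d}], got {self.planted_adjacent}"
            )
        if self.effect < 0:
            raise ValidationError(f"effect must be >= 0, got {self.effect}")
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if not 0 <= self.block_rho < 1:
            raise ValidationError(f"block_rho must be in [0, 1), got {self.block_rho}")


@dataclass(frozen=True)
class TruthSet:
    """Tissue-tagged IDs of the planted discriminative features."""

    feature_ids: tuple[str, ...]

    @property
    def tumor_ids(self) -> tuple[str, ...]:
        return tuple(f for f in self.feature_ids if f.startswith("tumor" + TISSUE_SEP))

    @property
    def adjacent_ids(self) -> tuple[str, ...]:
        return tuple(f for f in self.feature_ids if f.startswith("adjacent" + TISSUE_SEP))

    def __len__(self) -> int:
        return len(self.feature_ids)


def _tissue_block(
    rng: np.random.Generator, spec: SyntheticSpec, n_planted: int, pos_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One tissue's probes x samples values and the planted probe indices."""
    n = spec.n_pos + spec.n_neg
    planted = np.sort(rng.permutation(spec.d)[:n_planted])
    baseline = spec.baseline_mean + spec.baseline_sd * rng.standard_normal(spec.d)
    z_private = rng.standard_normal((spec.d, n))
    z_common = rng.standard_normal(n)
    noise = z_private.copy()
    if n_planted and spec.block_rho > 0:
        rho = spec.block_rho
        noise[planted] = math.sqrt(rho) * z_common + math.sqrt(1.0 - rho) * z_private[planted]
    values = baseline[:, None] + spec.sigma * noise
    if n_planted:
        values[np.ix_(planted, np.flatnonzero(pos_mask))] += spec.effect * spec.sigma
    return values, planted


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation, TruthSet]:
    """Generate (tumor, adjacent, annotation, truth) for a planted cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    width = max(3, len(str(n)))
    sample_ids = [f"patient_{i + 1:0{width}d}" for i in range(n)]
    labels = np.zeros(n, dtype=int)
    labels[: spec.n_pos] = 1
    pos_mask = labels == 1
    probe_ids = [f"probe_{i + 1:05d}" for i in range(spec.d)]

    tumor_vals, tumor_planted = _tissue_block(rng, spec, spec.planted_tumor, pos_mask)
    adj_vals, adj_planted = _tissue_block(rng, spec, spec.planted_adjacent, pos_mask)

    tumor = ExpressionMatrix(list(probe_ids), list(sample_ids), tumor_vals, "tumor")
    adjacent = ExpressionMatrix(list(probe_ids), list(sample_ids), adj_vals, "adjacent")
    ann = SampleAnnotation(dict(zip(sample_ids, labels.tolist())))
    truth = TruthSet(
        tuple(f"tumor{TISSUE_SEP}{probe_ids[i]}" for i in tumor_planted)
        + tuple(f"adjacent{TISSUE_SEP}{probe_ids[i]}" for i in adj_planted)
    )
    return tumor, adjacent, ann, truth


def write_truth(truth: TruthSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for fid in truth.feature_ids:
            fh.write(fid + "\n")


def read_truth(path) -> TruthSet:
    with open(path, "rt", encoding="utf-8") as fh:
        return TruthSet(tuple(line.strip() for line in fh if line.strip()))
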