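"""Expression-matrix containers and tab-delimited I/O.

A cohort is stored as two probe-by-sample matrices (tumor and adjacent tissue,
log-scale intensities) plus a sample annotation mapping each patient to the
binary phenotype (1 = perineural invasion).  :func:`combine_tissues` builds the
analysis-side patients-by-features matrix by concatenating, per patient, the
tumor feature block and the adjacent feature block; features carry a
``tumor:`` / ``adjacent:`` prefix so downstream reports can attribute a
selected feature to the tissue it came from.  This is the single place where
the orientation flips from probes x samples (storage) to patients x features
(analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

TISSUE_SEP = ":"
VALID_TISSUES = ("tumor", "adjacent")


def tissue_of(feature_id: str) -> str | None:
    """Tissue block a tagged feature ID belongs to, or None if untagged."""
    if TISSUE_SEP in feature_id:
        prefix = feature_id.split(TISSUE_SEP, 1)[0]
        if prefix in VALID_TISSUES:
            return prefix
    return None


@dataclass
class ExpressionMatrix:
    """One tissue's probes x samples log-expression table."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_probes, n_samples)
    tissue: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise ValidationError(f"tissue must be one of {VALID_TISSUES}, got {self.tissue!r}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("probe_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids must be unique")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must all be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Mapping sample_id -> phenotype (1 = perineural invasion, 0 = absent)."""

    phenotype: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = set(self.phenotype.values())
        if not vals <= {0, 1}:
            raise ValidationError(f"phenotypes must be 0/1, got {sorted(vals)}")
        if vals != {0, 1}:
            raise ValidationError("both phenotype classes must be present")

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.phenotype]
        if missing:
            raise ValidationError(f"annotation missing samples: {missing}")
        return np.array([self.phenotype[s] for s in sample_ids], dtype=int)


@dataclass
class CombinedMatrix:
    """Patients x features matrix after per-patient tissue concatenation.

    ``feature_ids`` are tissue-tagged (``tumor:<probe>``, ``adjacent:<probe>``)
    when produced by :func:`combine_tissues`; d is the total feature count and
    the length N of any full ranking over it.
    """

    feature_ids: list[str]
    patients: list[str]
    values: np.ndarray  # shape (n_patients, n_features)
    labels: np.ndarray  # phenotype per patient, 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("feature_ids must be unique")
        n, d = self.values.shape if self.values.ndim == 2 else (-1, -1)
        if (n, d) != (len(self.patients), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.patients)} patients, {len(self.feature_ids)} features)"
            )
        if self.labels.shape != (len(self.patients),):
            raise ValidationError("labels must have one entry per patient")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must all be finite")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def tissue_tags(self) -> list[str | None]:
        return [tissue_of(f) for f in self.feature_ids]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.feature_ids)


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_expression(path, tissue_label: str) -> ExpressionMatrix:
    """Parse a probe-by-sample TSV (header of sample IDs, first column probe ID).

    Raises :class:`ParseError` with the offending line number on duplicate
    probe IDs, non-numeric cells or ragged rows.
    """
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        sample_ids = cols[1:]
        if not sample_ids:
            raise ParseError(f"{path}: header has no sample columns (line 1)")
        n_cols = len(cols)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            probe = parts[0]
            if probe in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate probe ID {probe!r}")
            seen.add(probe)
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            probe_ids.append(probe)
    if not probe_ids:
        raise ParseError(f"{path}: no probe rows")
    return ExpressionMatrix(probe_ids, sample_ids, np.array(rows, dtype=float), tissue_label)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in zip(matrix.probe_ids, matrix.values):
            fh.write(probe + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_annotation(path) -> SampleAnnotation:
    phen: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()  # sample_id<TAB>phenotype
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                phen[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: phenotype must be 0/1, got {parts[1]!r}"
                ) from None
    return SampleAnnotation(phen)


def write_annotation(ann: SampleAnnotation, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tphenotype\n")
        for sid, ph in ann.phenotype.items():
            fh.write(f"{sid}\t{ph}\n")


def combine_tissues(
    tumor: ExpressionMatrix,
    adjacent: ExpressionMatrix,
    ann: SampleAnnotation,
    pairing: dict[str, str] | None = None,
) -> CombinedMatrix:
    """Concatenate tumor and adjacent feature blocks per patient.

    Patients are paired by identical sample ID in both matrices, or through an
    explicit ``pairing`` map (tumor sample ID -> adjacent sample ID).  One row
    per patient; columns are all tumor features followed by all adjacent
    features, tissue-tagged.
    """
    if tumor.tissue != "tumor" or adjacent.tissue != "adjacent":
        raise ValidationError("matrices must carry tissue labels 'tumor' and 'adjacent'")
    pairing = pairing or {s: s for s in tumor.sample_ids}
    adj_index = {s: j for j, s in enumerate(adjacent.sample_ids)}
    missing = [
        s for s in tumor.sample_ids if s not in pairing or pairing[s] not in adj_index
    ]
    extra = set(adjacent.sample_ids) - {pairing.get(s) for s in tumor.sample_ids}
    if missing or extra:
        raise ValidationError(
            f"unpaired patients: tumor samples without adjacent pair {sorted(missing)}, "
            f"adjacent samples without tumor pair {sorted(extra)}"
        )
    patients = list(tumor.sample_ids)
    adj_cols = [adj_index[pairing[s]] for s in patients]
    # tumor block: samples x probes; adjacent block re-ordered to patient order
    values = np.hstack([tumor.values.T, adjacent.values[:, adj_cols].T])
    feature_ids = [f"tumor{TISSUE_SEP}{p}" for p in tumor.probe_ids] + [
        f"adjacent{TISSUE_SEP}{p}" for p in adjacent.probe_ids
    ]
    labels = ann.labels_for(patients)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("both phenotype classes must be present among the patients")
    return CombinedMatrix(feature_ids, patients, values, labels)


def write_combined(data: CombinedMatrix, path) -> None:
    """Patients x features TSV with a leading phenotype column."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("patient_id\tphenotype\t" + "\t".join(data.feature_ids) + "\n")
        for pid, lab, row in zip(data.patients, data.labels, data.values):
            fh.write(f"{pid}\t{lab}\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_combined(path) -> CombinedMatrix:
    patients: list[str] = []
    labels: list[int] = []
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 3 or cols[0] != "patient_id" or cols[1] != "phenotype":
            raise ParseError(f"{path}: line 1: expected 'patient_id<TAB>phenotype<TAB>...'")
        feature_ids = cols[2:]
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(cols)} columns, got {len(parts)}"
                )
            patients.append(parts[0])
            try:
                labels.append(int(parts[1]))
                rows.append([float(v) for v in parts[2:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad cell ({exc})") from None
    return CombinedMatrix(feature_ids, patients, np.array(rows, dtype=float), np.array(labels))
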