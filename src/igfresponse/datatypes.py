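"""Core containers shared across the pipeline.

The pipeline operates on a gene x sample abundance table plus a per-sample
design table.  Both are thin, validated wrappers around pandas DataFrames so
that every stage can rely on unique identifiers, non-negative values, and a
closed vocabulary for the design factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAGNOSES = ("CTL", "ASD")
TREATMENTS = ("H2O", "acute", "chronic")

#: value kinds an abundance matrix can be tagged with
KINDS = ("counts", "tpm", "logtpm")


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass
class AbundanceMatrix:
    """Gene x sample non-negative abundance table.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id.
    kind : str
        One of ``counts``, ``tpm`` or ``logtpm`` — several operations are
        only defined for a particular kind and refuse the others.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown abundance kind {self.kind!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("abundance matrix contains non-finite values")
        if arr.size and arr.min() < 0:
            raise ValidationError("abundance matrix contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "AbundanceMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.gene_ids)
        if len(missing):
            raise ValidationError(f"genes absent from matrix: {sorted(missing)}")
        return AbundanceMatrix(self.values.loc[genes], self.kind)

    def subset_samples(self, samples) -> "AbundanceMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.sample_ids)
        if len(missing):
            raise ValidationError(f"samples absent from matrix: {sorted(missing)}")
        return AbundanceMatrix(self.values[samples], self.kind)


REQUIRED_METADATA_COLUMNS = ("sample_id", "patient_id", "diagnosis", "treatment", "replicate")


@dataclass
class SampleMetadata:
    """Per-sample design table: patient, diagnosis, treatment arm, replicate.

    Any additional columns are carried along as named covariates (e.g. the
    per-line mean spontaneous burst rate from multielectrode recordings).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dup}")
        bad = set(self.table["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise ValidationError(f"unknown diagnosis labels: {sorted(bad)}")
        bad = set(self.table["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValidationError(f"unknown treatment labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in REQUIRED_METADATA_COLUMNS]

    def aligned_to(self, matrix: AbundanceMatrix) -> "SampleMetadata":
        """Return metadata restricted to, and ordered as, the matrix samples."""
        check_samples_match(matrix, self)
        sub = self.table.set_index("sample_id").loc[matrix.sample_ids]
        sub.index.name = "sample_id"
        return SampleMetadata(sub.reset_index())

    def subset(self, mask) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[np.asarray(mask)].reset_index(drop=True))


def check_samples_match(matrix: AbundanceMatrix, metadata: SampleMetadata) -> None:
    """Every matrix sample must appear exactly once in the metadata."""
    meta_ids = set(metadata.sample_ids)
    missing = [s for s in matrix.sample_ids if s not in meta_ids]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing}")


@dataclass
class DEResult:
    """Per-gene differential expression result for one contrast.

    ``table`` has columns gene, logFC, logCPM, pvalue, fdr (indexed by gene);
    genes that failed the expression filter are absent rather than NA.
    """

    table: pd.DataFrame
    contrast: str
    test: str  # "exact" or "glm_lrt"

    def significant(self, fdr_cut: float = 0.05) -> pd.Index:
        ok = self.table["fdr"].notna() & (self.table["fdr"] < fdr_cut)
        return self.table.index[ok]


@dataclass
class SimulatedTruth:
    """Ground truth emitted by the synthetic-data generator."""

    gene_class: pd.Series  # per gene: null/shared/acute_only/chronic_only/baseline_de/baseline_de_recoverable
    gene_direction: pd.Series  # per gene: +1 / -1
    response_scale: pd.Series  # per patient r_p (CTL fixed at 1)
    responder_flag: pd.Series  # per patient: r_p > 0
    activity: pd.Series  # per patient covariate value
    gene_dispersion: pd.Series | None = None  # per gene NB dispersion used
    params: dict = field(default_factory=dict)
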