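"""Input readers, validation, normalization, sample QC and cell-type scores.

QC follows the study's two-pass sample exclusion: first drop samples whose
log detected-gene count falls below a threshold, then drop samples that are
outliers in (PC1, PC2) of the log-normalized expression, with distance from
the centroid more than k SDs above the mean distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import (
    AbundanceMatrix,
    SampleMetadata,
    ValidationError,
    check_samples_match,
)


def read_abundance(path, kind: str) -> AbundanceMatrix:
    """Read a genes-as-rows TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceMatrix(df, kind)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return SampleMetadata(df)


def log_normalize(tpm: AbundanceMatrix) -> AbundanceMatrix:
    """log2(TPM + 1) normalization; only defined for TPM-tagged matrices."""
    if tpm.kind != "tpm":
        raise ValidationError(f"log_normalize expects a TPM matrix, got {tpm.kind!r}")
    return AbundanceMatrix(np.log2(tpm.values + 1.0), "logtpm")


@dataclass
class QCReport:
    excluded_samples: list = field(default_factory=list)  # (sample_id, reason)
    detected_genes: dict = field(default_factory=dict)
    pca_coordinates: pd.DataFrame | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "excluded_samples": [list(x) for x in self.excluded_samples],
            "detected_genes": {k: int(v) for k, v in self.detected_genes.items()},
            "pca_coordinates": (
                None
                if self.pca_coordinates is None
                else {s: list(map(float, row)) for s, row in self.pca_coordinates.iterrows()}
            ),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def exclude_outliers(
    matrix: AbundanceMatrix,
    log_gene_count_threshold: float = 6.0,
    pca_sd_k: float = 3.0,
) -> tuple[AbundanceMatrix, QCReport]:
    """Two-pass sample exclusion: low detected-gene count, then PCA distance.

    The gene-count rule reads the threshold on the natural log of the number
    of genes detected (abundance > 0) in the sample; 6 corresponds to ~403
    genes.  The PCA rule removes samples whose (PC1, PC2) distance from the
    centroid lies more than ``pca_sd_k`` SDs above the mean of that distance.
    """
    if matrix.n_samples < 3:
        raise ValidationError("exclude_outliers needs at least 3 samples")
    report = QCReport()
    detected = (matrix.values > 0).sum(axis=0)
    report.detected_genes = detected.to_dict()
    with np.errstate(divide="ignore"):
        log_detected = np.log(detected.to_numpy().astype(float))
    low = matrix.sample_ids[log_detected < log_gene_count_threshold]
    for s in low:
        report.excluded_samples.append((s, "low_gene_count"))
    kept = matrix.subset_samples(matrix.sample_ids.difference(low, sort=False))
    if kept.n_samples == 0:
        raise ValidationError("all samples excluded by the gene-count rule")

    if kept.kind == "tpm":
        logvals = np.log2(kept.values + 1.0)
    elif kept.kind == "counts":
        # bring counts onto a comparable log scale (CPM-style per-sample scaling)
        cpm = kept.values / kept.values.sum(axis=0).replace(0, 1) * 1e6
        logvals = np.log2(cpm + 1.0)
    else:
        logvals = kept.values
    X = logvals.to_numpy().T  # samples x genes
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    report.pca_coordinates = pd.DataFrame(
        coords[:, :2], index=kept.sample_ids, columns=["PC1", "PC2"]
    )
    centroid = coords[:, :2].mean(axis=0)
    dist = np.sqrt(((coords[:, :2] - centroid) ** 2).sum(axis=1))
    sd = dist.std(ddof=1) if len(dist) > 1 else 0.0
    if sd > 0:
        far = kept.sample_ids[dist > dist.mean() + pca_sd_k * sd]
    else:  # identical samples: zero spread, nothing to exclude
        far = pd.Index([])
    for s in far:
        report.excluded_samples.append((s, "pca_outlier"))
    kept = kept.subset_samples(kept.sample_ids.difference(far, sort=False))
    if kept.n_samples == 0:
        raise ValidationError("all samples excluded by QC")
    return kept, report


def cell_type_scores(
    logtpm: AbundanceMatrix,
    metadata: SampleMetadata,
    marker_sets: dict,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample cell-type signature scores and their disease association.

    A set's score is the per-sample sum of per-gene z-scored log expression
    over the set's genes ("scaled expression"); the association p comes from
    the F-test of the linear model score ~ diagnosis.  Marker genes missing
    from the matrix are dropped with a warning; a zero-variance gene has
    z-score 0 by convention.
    """
    if logtpm.kind != "logtpm":
        raise ValidationError("cell_type_scores expects a log-normalized matrix")
    meta = metadata.aligned_to(logtpm)
    vals = logtpm.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    z = vals.sub(mean, axis=0).div(sd.replace(0, np.inf), axis=0)

    scores = {}
    pvals = {}
    from scipy import stats

    for name, genes in marker_sets.items():
        genes = pd.Index(pd.unique(pd.Series(list(genes))))
        present = genes.intersection(logtpm.gene_ids)
        if len(present) < len(genes):
            warnings.warn(
                f"marker set {name!r}: {len(genes) - len(present)} genes absent, dropped"
            )
        if len(present) == 0:
            raise ValidationError(f"marker set {name!r} has no genes in the matrix")
        s = z.loc[present].sum(axis=0)
        scores[name] = s
        groups = [
            s[meta.table.loc[meta.table["diagnosis"] == dx, "sample_id"]].to_numpy()
            for dx in ("CTL", "ASD")
        ]
        groups = [g for g in groups if len(g)]
        if len(groups) == 2 and all(len(g) > 1 for g in groups):
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
                pvals[name] = 1.0
            else:
                f = stats.f_oneway(*groups)
                pvals[name] = 1.0 if np.isnan(f.pvalue) else float(f.pvalue)
        else:
            pvals[name] = np.nan
    score_df = pd.DataFrame(scores)
    score_df.index.name = "sample_id"
    return score_df, pd.Series(pvals, name="diagnosis_p")
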