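"""Control-signature PC projection and responder stratification.

A PC space is learned from control samples (vehicle + acute treatment) on
the control acute DE signature genes; every sample — including disease
samples the space never saw — is then projected with the *control* centering
and scaling, making PC1 a transferable axis of control-like treatment
response.  Each patient's response is the shift of their mean PC1 score from
vehicle to treatment; a positive shift is a control-like response
(responder), a negative shift marks a non-responder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, SampleMetadata, ValidationError


@dataclass
class PCSpace:
    """Frozen reference PC basis: signature genes, control center/scale,
    orthonormal loadings, and the orientation making PC1 treatment-positive."""

    genes: pd.Index
    center: pd.Series
    scale: pd.Series
    loadings: pd.DataFrame  # genes x (PC1, PC2)
    explained_variance_ratio: np.ndarray = field(default=None)
    separation_F: float = np.nan
    separation_p: float = np.nan

    def transform(self, logtpm: AbundanceMatrix) -> pd.DataFrame:
        """Project samples with the space's own center/scale (affine)."""
        missing = self.genes.difference(logtpm.gene_ids)
        if len(missing):
            raise ValidationError(f"genes absent from input: {sorted(missing)}")
        X = logtpm.values.loc[self.genes]
        Z = X.sub(self.center, axis=0).div(self.scale, axis=0)
        scores = Z.to_numpy().T @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=logtpm.sample_ids, columns=self.loadings.columns)


def fit_pc_space(
    ctl_logtpm: AbundanceMatrix,
    metadata: SampleMetadata,
    signature_genes,
    scale: bool = True,
    treatment_test: str = "acute",
    treatment_ref: str = "H2O",
) -> PCSpace:
    """Fit the reference PC space on control samples over the signature genes.

    Genes are centered (and by default scaled) by control-sample statistics;
    zero-variance genes are dropped with a warning.  PC1's sign is oriented
    so treated controls score higher than vehicle controls, fixing the SVD
    sign ambiguity; the separation F-test of that contrast is recorded.
    """
    genes = pd.Index(signature_genes).intersection(ctl_logtpm.gene_ids)
    if len(genes) < 2:
        raise ValidationError("need at least 2 signature genes present in the matrix")
    sub = ctl_logtpm.values.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance signature genes dropped")
        genes = genes[(sd > 0).to_numpy()]
        if len(genes) < 2:
            raise ValidationError("fewer than 2 variable signature genes remain")
        sub = ctl_logtpm.values.loc[genes]
        sd = sub.std(axis=1, ddof=0)
    center = sub.mean(axis=1)
    scl = sd if scale else pd.Series(1.0, index=genes)
    Z = sub.sub(center, axis=0).div(scl, axis=0).to_numpy()
    u, s, vt = np.linalg.svd(Z.T, full_matrices=False)  # samples x genes
    n_comp = min(2, len(s))
    loadings = pd.DataFrame(
        vt[:n_comp].T, index=genes, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    if n_comp < 2:
        loadings["PC2"] = 0.0
    space = PCSpace(
        genes=pd.Index(genes),
        center=center,
        scale=scl,
        loadings=loadings,
        explained_variance_ratio=(s**2 / (s**2).sum())[:2],
    )
    scores = space.transform(AbundanceMatrix(ctl_logtpm.values, "logtpm"))
    meta = metadata.aligned_to(ctl_logtpm)
    trt = pd.Series(meta.table["treatment"].to_numpy(), index=meta.sample_ids)
    s_ref = scores.loc[trt.index[trt == treatment_ref], "PC1"]
    s_test = scores.loc[trt.index[trt == treatment_test], "PC1"]
    if len(s_ref) and len(s_test) and s_test.mean() < s_ref.mean():
        space.loadings["PC1"] *= -1.0
        s_ref, s_test = -s_ref, -s_test
    if len(s_ref) > 1 and len(s_test) > 1:
        f = stats.f_oneway(s_ref.to_numpy(), s_test.to_numpy())
        space.separation_F = float(f.statistic)
        space.separation_p = float(f.pvalue)
    return space


def project(logtpm: AbundanceMatrix, space: PCSpace) -> pd.DataFrame:
    """Per-sample PC scores in the reference space (see PCSpace.transform)."""
    return space.transform(logtpm)


@dataclass
class ProjectionResult:
    scores: pd.DataFrame  # per sample PC1/PC2
    patient_table: pd.DataFrame  # per patient arm means, delta, responder flag
    excluded_patients: list = field(default_factory=list)


def patient_shift(
    scores: pd.DataFrame,
    metadata: SampleMetadata,
    treatment_test: str = "acute",
    treatment_ref: str = "H2O",
) -> ProjectionResult:
    """Per-patient mean PC1 in each arm and the vehicle-to-treatment shift.

    responder = delta_pc1 > 0, strictly; patients missing either arm are
    flagged and excluded from the shift table rather than silently dropped.
    """
    meta = metadata.table.set_index("sample_id")
    meta = meta.loc[meta.index.intersection(scores.index)]
    joined = meta.join(scores, how="inner")
    rows = []
    excluded = []
    for patient, grp in joined.groupby("patient_id", sort=True):
        arms = set(grp["treatment"])
        if treatment_ref not in arms or treatment_test not in arms:
            excluded.append((patient, f"missing arm(s): "
                             f"{sorted({treatment_ref, treatment_test} - arms)}"))
            continue
        m_ref = grp.loc[grp["treatment"] == treatment_ref, "PC1"].mean()
        m_test = grp.loc[grp["treatment"] == treatment_test, "PC1"].mean()
        delta = m_test - m_ref
        rows.append(
            (patient, grp["diagnosis"].iloc[0], m_ref, m_test, delta, delta > 0)
        )
    table = pd.DataFrame(
        rows,
        columns=["patient_id", "diagnosis", "mean_pc1_ref", "mean_pc1_test",
                 "delta_pc1", "responder"],
    ).sort_values("delta_pc1", ascending=False).set_index("patient_id")
    return ProjectionResult(scores=scores, patient_table=table, excluded_patients=excluded)


@dataclass
class CovariateAssociation:
    covariate: str
    slope: float
    intercept: float
    F: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "slope": float(self.slope),
            "F": float(self.F),
            "p": float(self.p),
            "n": int(self.n),
        }


def covariate_association(x, y, name: str = "") -> CovariateAssociation:
    """OLS of the covariate on the response shift, F-test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError("need at least 3 paired finite values")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x")
    res = stats.linregress(x, y)
    # for simple regression the slope F-test is the square of the t-test
    df = len(x) - 2
    t2 = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
    p = float(stats.f.sf(t2, 1, df)) if np.isfinite(t2) else 0.0
    return CovariateAssociation(
        covariate=name, slope=float(res.slope), intercept=float(res.intercept),
        F=float(t2), p=p, n=len(x),
    )
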