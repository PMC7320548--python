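"""Treatment-recovery classification of baseline disease genes.

A gene differentially expressed between ASD and control at baseline is
"recovered" under a treatment arm when the treatment shifts its ASD
expression in the direction opposite the baseline difference AND the
treated-ASD vs control-baseline contrast is no longer significant.  A
looser sign-only rule (quadrant membership in the logFC-vs-logFC plane) is
also provided.  Genes normal at baseline that become significantly
different from the control state only after treatment are flagged
"IGF-1 altered".
"""

from __future__ import annotations

import pandas as pd

from .datatypes import AbundanceMatrix, DEResult, SampleMetadata, ValidationError
from . import diffexpr as de

COMBINED_CATEGORIES = (
    "recovered_both",
    "recovered_acute_only",
    "recovered_chronic_only",
    "not_recovered",
)


def baseline_de(
    counts: AbundanceMatrix,
    metadata: SampleMetadata,
    treatment: str = "H2O",
    **kwargs,
) -> DEResult:
    """Exact-test DE between diagnoses within the vehicle arm (ASD vs CTL)."""
    meta = metadata.aligned_to(counts)
    keep = (meta.table["treatment"] == treatment).to_numpy()
    if not keep.any():
        raise ValidationError(f"no samples in treatment arm {treatment!r}")
    sub = counts.subset_samples(meta.table.loc[keep, "sample_id"])
    msub = meta.subset(keep)
    for dx in ("CTL", "ASD"):
        if (msub.table["diagnosis"] == dx).sum() == 0:
            raise ValidationError(f"diagnosis {dx} absent from the {treatment} arm")
    return de.run_exact_contrast(sub, msub, "diagnosis", "ASD", "CTL", **kwargs)


def classify_recovery(
    baseline: DEResult,
    asd_acute: DEResult,
    asd_chronic: DEResult,
    post_vs_ctl_acute: DEResult,
    post_vs_ctl_chronic: DEResult,
    fdr_cut: float = 0.05,
    rule: str = "strict",
) -> pd.DataFrame:
    """Per-gene recovery calls over the shared feature space.

    Contrasts: ``baseline`` is ASD vs CTL in vehicle; ``asd_acute`` /
    ``asd_chronic`` are treatment vs vehicle within ASD; ``post_vs_ctl_*``
    compare treated ASD against vehicle controls.  Under the default
    "strict" rule an arm recovers a baseline-DE gene when the treatment
    shift opposes the baseline sign and the post-treatment-vs-control
    contrast is not significant; rule="sign" uses the sign condition alone.
    Every baseline-DE gene gets a combined category; ``igf1_altered_*``
    flags mark genes normal at baseline that differ from the control state
    only after treatment.
    """
    if rule not in ("strict", "sign"):
        raise ValidationError(f"unknown recovery rule {rule!r}")
    contrasts = {
        "baseline": baseline,
        "asd_acute": asd_acute,
        "asd_chronic": asd_chronic,
        "post_vs_ctl_acute": post_vs_ctl_acute,
        "post_vs_ctl_chronic": post_vs_ctl_chronic,
    }
    for name, c in contrasts.items():
        if c is None:
            raise ValidationError(f"missing contrast {name!r}")
    genes = baseline.table.index
    for name, c in contrasts.items():
        genes = genes.intersection(c.table.index)

    out = pd.DataFrame(index=genes)
    out["baseline_logfc"] = baseline.table.loc[genes, "logFC"]
    out["baseline_fdr"] = baseline.table.loc[genes, "fdr"]
    out["baseline_de"] = out["baseline_fdr"] < fdr_cut

    for arm, asd_res, post_res in (
        ("acute", asd_acute, post_vs_ctl_acute),
        ("chronic", asd_chronic, post_vs_ctl_chronic),
    ):
        tl = asd_res.table.loc[genes, "logFC"]
        out[f"treatment_logfc_{arm}"] = tl
        post_sig = post_res.table.loc[genes, "fdr"] < fdr_cut
        opposed = (tl * out["baseline_logfc"]) < 0
        if rule == "strict":
            rec = opposed & ~post_sig
        else:
            rec = opposed
        out[f"recovered_{arm}"] = out["baseline_de"] & rec
        out[f"igf1_altered_{arm}"] = (~out["baseline_de"]) & post_sig

    def combined(row) -> str:
        if not row["baseline_de"]:
            return ""
        a, c = row["recovered_acute"], row["recovered_chronic"]
        if a and c:
            return "recovered_both"
        if a:
            return "recovered_acute_only"
        if c:
            return "recovered_chronic_only"
        return "not_recovered"

    out["combined"] = out.apply(combined, axis=1)
    return out
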