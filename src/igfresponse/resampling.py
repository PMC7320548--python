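"""Permutation significance of response magnitude and classifier robustness.

The permutation test asks whether the *number* of genes passing the FDR
cutoff under the true treatment labels is larger than expected by chance:
treatment labels are reshuffled (within patient by default, so each
patient's arm multiset is preserved), the full DE machinery is re-run, and
the count of FDR-significant genes recorded per permutation.

The classifier check asks whether the *specific* signature genes carry
treatment information: a bagged random-forest on the signature's expression
with out-of-bag error, confusion matrix and OOB-vote AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score

from .datatypes import AbundanceMatrix, SampleMetadata, ValidationError
from . import diffexpr as de


@dataclass
class PermutationResult:
    observed_count: int
    null_counts: np.ndarray
    bootstrap_p: float  # (1 + #{null >= obs}) / (n_perm + 1)
    raw_fraction: float  # #{null >= obs} / n_perm, as the study reports
    n_perm: int
    seed: int
    contrast: str = ""

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "observed_count": int(self.observed_count),
            "null_counts": [int(x) for x in self.null_counts],
            "bootstrap_p": float(self.bootstrap_p),
            "raw_fraction": float(self.raw_fraction),
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
        }


def _permute_labels(
    meta: pd.DataFrame, scheme: str, rng: np.random.Generator
) -> np.ndarray:
    labels = meta["treatment"].to_numpy().copy()
    if scheme == "global":
        rng.shuffle(labels)
        return labels
    if scheme != "within_patient":
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    warned = False
    for patient, idx in meta.groupby("patient_id").groups.items():
        idx = np.asarray(list(idx))
        if len(np.unique(labels[idx])) < 2:
            if not warned:
                warnings.warn(
                    f"patient {patient} holds a single arm; its labels stay fixed"
                )
                warned = True
            continue
        labels[idx] = labels[idx][rng.permutation(len(idx))]
    return labels


def permutation_magnitude_test(
    counts: AbundanceMatrix,
    metadata: SampleMetadata,
    contrast: tuple,
    design: str = "additive",
    n_perm: int = 100,
    scheme: str = "within_patient",
    fdr_cut: float = 0.05,
    min_total: float = 6.0,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the DE-gene-count magnitude for one contrast.

    ``contrast`` is (reference, test) treatment labels, e.g. ("H2O", "acute").
    ``design`` selects the re-run DE test: "exact" (two-group conditional
    exact test), "additive" (GLM LRT, treatment + patient, the default) or
    "interaction" (GLM LRT, treatment + patient + treatment x patient with
    the treatment main effect tested).  Genes with total abundance below
    ``min_total`` across all samples are filtered once up front (the filter
    is label-free).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    ref, test = contrast
    meta = metadata.aligned_to(counts)
    keep = meta.table["treatment"].isin([ref, test]).to_numpy()
    sub = counts.subset_samples(meta.table.loc[keep, "sample_id"])
    meta_sub = meta.subset(keep)
    totals = sub.values.sum(axis=1)
    sub = AbundanceMatrix(sub.values.loc[totals >= min_total], sub.kind)

    norm = de.tmm_factors(sub)
    rng = np.random.default_rng(seed)

    def count_significant(treatment_labels: np.ndarray) -> int:
        m = meta_sub.table.copy()
        m["treatment"] = treatment_labels
        msub = SampleMetadata(m)
        if design == "exact":
            spec = de.DesignSpec(["treatment"], tested="treatment")
            disp = de.estimate_dispersions(sub, spec, norm, metadata=msub, trend=False)
            groups = pd.Series(treatment_labels, index=pd.Index(m["sample_id"]))
            groups = groups[list(sub.sample_ids)]
            res = de.exact_test(sub, groups, norm, disp, levels=(ref, test))
        elif design == "additive":
            spec = de.DesignSpec(["treatment", "patient_id"], tested="treatment")
            disp = de.estimate_dispersions(sub, spec, norm, metadata=msub, trend=False)
            res = de.glm_lrt(sub, spec, norm, disp, msub)
        elif design == "interaction":
            spec = de.DesignSpec(
                ["treatment", "patient_id", "treatment:patient_id"], tested="treatment"
            )
            disp = de.estimate_dispersions(sub, spec, norm, metadata=msub, trend=False)
            res = de.glm_lrt(sub, spec, norm, disp, msub)
        else:
            raise ValidationError(f"unknown permutation design {design!r}")
        return int(len(res.significant(fdr_cut)))

    observed = count_significant(meta_sub.table["treatment"].to_numpy())
    null_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null_counts[i] = count_significant(_permute_labels(meta_sub.table, scheme, rng))
    exceed = int((null_counts >= observed).sum())
    return PermutationResult(
        observed_count=observed,
        null_counts=null_counts,
        bootstrap_p=(1 + exceed) / (n_perm + 1),
        raw_fraction=exceed / n_perm,
        n_perm=n_perm,
        seed=seed,
        contrast=f"{test}_vs_{ref}",
    )


@dataclass
class ClassifierReport:
    oob_error: float  # percent
    confusion: pd.DataFrame
    auc: float
    n_trees: int
    seed: int
    classes: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "oob_error_percent": float(self.oob_error),
            "confusion_matrix": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.iterrows()
            },
            "auc": float(self.auc),
            "n_trees": int(self.n_trees),
            "seed": int(self.seed),
        }


def classify_treatment(
    signature_logtpm: AbundanceMatrix,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierReport:
    """Random-forest classification of treatment from signature expression.

    Samples are rows, signature genes are features.  Error, confusion matrix
    and AUC all come from out-of-bag predictions, so no sample is judged by
    trees that saw it.
    """
    labels = pd.Series(labels)
    y = labels.loc[list(signature_logtpm.sample_ids)].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {list(classes)}")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValidationError("need at least 2 samples per class")
    if signature_logtpm.n_genes < 1:
        raise ValidationError("need at least one feature gene")
    X = signature_logtpm.values.to_numpy().T

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=int(seed),
        bootstrap=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-sample OOB warnings
        rf.fit(X, y)
    votes = rf.oob_decision_function_
    # a sample never left out-of-bag (vanishingly rare at 500 trees) counts
    # as a tie split evenly between classes
    nan_rows = np.isnan(votes).any(axis=1)
    votes = np.where(nan_rows[:, None], 1.0 / votes.shape[1], votes)
    pred = rf.classes_[np.argmax(votes, axis=1)]
    err = float((pred != y).mean() * 100.0)
    conf = confusion_matrix(y, pred, labels=rf.classes_)
    conf_df = pd.DataFrame(conf, index=rf.classes_, columns=rf.classes_)
    auc = float(roc_auc_score((y == rf.classes_[1]).astype(int), votes[:, 1]))
    return ClassifierReport(
        oob_error=err,
        confusion=conf_df,
        auc=auc,
        n_trees=n_trees,
        seed=seed,
        classes=tuple(rf.classes_),
    )
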