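"""Synthetic cohort generator emulating the IGF-1 treatment study design.

The generator draws negative-binomial counts for a cohort of control and ASD
patients, each measured in replicate under three arms (vehicle water, acute
IGF-1, chronic IGF-1).  Planted structure, all exposed as ground truth:

* treatment-responsive gene classes (``shared``, ``acute_only``,
  ``chronic_only``) whose log2 treatment effect is scaled per patient by a
  response scale r_p — controls respond fully (r_p = 1) while ASD patients
  split into responders (r_p > 0) and non-responders (r_p < 0);
* baseline disease genes (``baseline_de``) shifted in ASD in every arm, a
  configurable fraction of which (``baseline_de_recoverable``) are pushed
  back toward the control level by treatment in ASD samples;
* a designated receptor gene whose post-treatment level is coupled to r_p,
  and a per-patient activity covariate generated from r_p — together they
  let downstream stages test responder/covariate associations against truth.

One RNG stream is consumed in a documented order (gene parameters -> classes
-> patient effects -> response scales -> library sizes -> counts -> activity)
so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleMetadata, SimulatedTruth, TREATMENTS

GENE_CLASSES = (
    "null",
    "shared",
    "acute_only",
    "chronic_only",
    "baseline_de",
    "baseline_de_recoverable",
)

# fraction of the full acute effect retained at the other timepoint: shared
# genes respond identically at both timepoints, while timepoint-specific
# genes retain a low-level 25% echo at the other arm.
_TREATMENT_INDICATOR = {
    "shared": {"acute": 1.0, "chronic": 1.0},
    "acute_only": {"acute": 1.0, "chronic": 0.25},
    "chronic_only": {"acute": 0.25, "chronic": 1.0},
}


class SimulationConfigError(ValueError):
    """Raised when a simulation parameter is out of its valid range."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design
    (7 control + 8 ASD patients, duplicates, three treatment arms)."""

    n_ctl_patients: int = 7
    n_asd_patients: int = 8
    n_replicates: int = 2
    treatments: tuple = TREATMENTS
    n_genes: int = 5000
    baseline_log_mean_range: tuple = (1.0, 8.0)  # log2 scale
    dispersion_mean: float = 0.15  # mean of gamma-distributed NB dispersion
    dispersion_shape: float = 2.0
    library_size_range: tuple = (800_000, 1_200_000)
    frac_shared: float = 0.04
    frac_acute_only: float = 0.03
    frac_chronic_only: float = 0.03
    frac_baseline_de: float = 0.06
    frac_recoverable: float = 0.5  # of the baseline-DE genes
    effect_logfc: float = 1.0
    baseline_logfc: float = 1.0
    patient_sd: float = 0.3
    responder_fraction: float = 5 / 8
    receptor_gene_index: int = 0
    activity_slope: float = 2.0
    activity_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_ctl_patients", "n_asd_patients", "n_replicates", "n_genes"):
            if int(getattr(self, name)) < 1:
                raise SimulationConfigError(f"{name} must be >= 1")
        for name in (
            "frac_shared",
            "frac_acute_only",
            "frac_chronic_only",
            "frac_baseline_de",
            "frac_recoverable",
            "responder_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        class_sum = (
            self.frac_shared + self.frac_acute_only + self.frac_chronic_only + self.frac_baseline_de
        )
        if class_sum > 1.0 + 1e-12:
            raise SimulationConfigError("gene-class fractions sum to more than 1")
        if self.dispersion_mean <= 0 or self.dispersion_shape <= 0:
            raise SimulationConfigError("dispersion_mean and dispersion_shape must be > 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise SimulationConfigError("library_size_range must be positive and ordered")
        if not 0 <= self.receptor_gene_index < self.n_genes:
            raise SimulationConfigError("receptor_gene_index out of range")
        if self.activity_noise_sd < 0 or self.patient_sd < 0:
            raise SimulationConfigError("patient_sd and activity_noise_sd must be >= 0")


@dataclass
class SimulatedDataset:
    counts: AbundanceMatrix
    tpm: AbundanceMatrix
    metadata: SampleMetadata
    truth: SimulatedTruth
    config: SimulationConfig = field(repr=False, default=None)


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Planted class per gene; counts are floor(fraction * n_genes) exactly."""
    n = cfg.n_genes
    counts = {
        "shared": math.floor(cfg.frac_shared * n),
        "acute_only": math.floor(cfg.frac_acute_only * n),
        "chronic_only": math.floor(cfg.frac_chronic_only * n),
    }
    n_baseline = math.floor(cfg.frac_baseline_de * n)
    n_recoverable = math.floor(cfg.frac_recoverable * n_baseline)
    counts["baseline_de_recoverable"] = n_recoverable
    counts["baseline_de"] = n_baseline - n_recoverable
    classes = np.array(["null"] * n, dtype=object)
    # the receptor gene stays class "null": its treatment coupling is modelled
    # separately so it never doubles as a planted DE gene
    candidates = np.array([i for i in range(n) if i != cfg.receptor_gene_index])
    rng.shuffle(candidates)
    pos = 0
    for label in ("shared", "acute_only", "chronic_only", "baseline_de_recoverable", "baseline_de"):
        k = counts[label]
        if k > len(candidates) - pos:
            raise SimulationConfigError("gene-class fractions exceed available genes")
        classes[candidates[pos : pos + k]] = label
        pos += k
    return pd.Series(classes)


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Draw one synthetic cohort.

    Returns counts, a TPM view (unit gene length, so TPM coincides with CPM),
    sample metadata with the activity covariate, and the ground truth.
    """
    cfg = config if config is not None else SimulationConfig()
    if overrides:
        cfg = dataclass_replace(cfg, **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")

    # 1. gene-level parameters
    lo, hi = cfg.baseline_log_mean_range
    baseline_log2 = rng.uniform(lo, hi, size=n)
    scale = cfg.dispersion_mean / cfg.dispersion_shape
    dispersion = rng.gamma(cfg.dispersion_shape, scale, size=n)
    dispersion = np.maximum(dispersion, 1e-6)

    # 2. classes and directions
    gene_class = _assign_classes(cfg, rng)
    gene_class.index = gene_ids
    direction = rng.choice([-1.0, 1.0], size=n)
    gene_direction = pd.Series(direction, index=gene_ids)

    # 3. patients and their random effects
    patients = [f"CTL{i + 1:02d}" for i in range(cfg.n_ctl_patients)] + [
        f"ASD{i + 1:02d}" for i in range(cfg.n_asd_patients)
    ]
    diagnosis = ["CTL"] * cfg.n_ctl_patients + ["ASD"] * cfg.n_asd_patients
    patient_effect = rng.normal(0.0, cfg.patient_sd, size=len(patients))

    # 4. response scales: controls respond fully; the configured fraction of
    # ASD patients are responders (positive but attenuated), the rest invert
    n_resp = int(round(cfg.responder_fraction * cfg.n_asd_patients))
    r_asd = np.empty(cfg.n_asd_patients)
    resp_idx = rng.permutation(cfg.n_asd_patients)
    r_asd[resp_idx[:n_resp]] = rng.uniform(0.3, 1.0, size=n_resp)
    r_asd[resp_idx[n_resp:]] = rng.uniform(-0.5, 0.0, size=cfg.n_asd_patients - n_resp)
    r_p = np.concatenate([np.ones(cfg.n_ctl_patients), r_asd])
    response_scale = pd.Series(r_p, index=pd.Index(patients, name="patient_id"))

    # sample grid: patient x treatment x replicate
    rows = []
    for p_i, (patient, dx) in enumerate(zip(patients, diagnosis)):
        for trt in cfg.treatments:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((f"{patient}_{trt}_r{rep}", patient, dx, trt, rep, p_i))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "diagnosis", "treatment", "replicate", "_pi"]
    )
    n_samples = len(samples)

    # 5. library sizes
    lib_sizes = rng.uniform(cfg.library_size_range[0], cfg.library_size_range[1], size=n_samples)

    # expected log2 abundance per gene x sample
    log2mu = np.tile(baseline_log2[:, None], (1, n_samples))
    is_asd = (samples["diagnosis"] == "ASD").to_numpy()
    treated = samples["treatment"].to_numpy()
    p_idx = samples["_pi"].to_numpy()
    log2mu += patient_effect[p_idx][None, :]

    base_mask = gene_class.isin(["baseline_de", "baseline_de_recoverable"]).to_numpy()
    log2mu[np.ix_(base_mask, is_asd)] += (
        direction[base_mask, None] * cfg.baseline_logfc
    )

    for label, ind in _TREATMENT_INDICATOR.items():
        gmask = (gene_class == label).to_numpy()
        if not gmask.any():
            continue
        for trt, frac in ind.items():
            smask = treated == trt
            if not smask.any():
                continue
            log2mu[np.ix_(gmask, smask)] += (
                direction[gmask, None] * cfg.effect_logfc * frac * r_p[p_idx[smask]][None, :]
            )

    # recoverable genes: treatment pushes the ASD level back toward control in
    # both arms (full shift, ASD samples only — see docs/methods.md)
    rec_mask = (gene_class == "baseline_de_recoverable").to_numpy()
    smask = is_asd & (treated != "H2O")
    if rec_mask.any() and smask.any():
        log2mu[np.ix_(rec_mask, smask)] -= direction[rec_mask, None] * cfg.baseline_logfc

    # receptor gene: acute-treatment mean multiplied by 2^(r_p * effect_logfc)
    acute_mask = treated == "acute"
    log2mu[cfg.receptor_gene_index, acute_mask] += (
        cfg.effect_logfc * r_p[p_idx[acute_mask]]
    )

    # convert relative abundances to expected counts at the sample library size
    rel = np.exp2(log2mu)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib_sizes[None, :]

    # 6. NB counts: Var = mu + phi * mu^2
    r = 1.0 / dispersion
    p_nb = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p_nb)

    # 7. activity covariate, one draw per patient
    activity = cfg.activity_slope * r_p + rng.normal(0.0, cfg.activity_noise_sd, size=len(r_p))
    activity = pd.Series(activity, index=response_scale.index)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"])
    col_sums = counts_df.sum(axis=0).to_numpy().astype(float)
    col_sums[col_sums == 0] = 1.0
    tpm_df = counts_df / col_sums * 1e6

    meta = samples.drop(columns=["_pi"]).copy()
    meta["activity"] = activity.loc[meta["patient_id"]].to_numpy()

    truth = SimulatedTruth(
        gene_class=gene_class,
        gene_direction=gene_direction,
        response_scale=response_scale,
        responder_flag=response_scale > 0,
        activity=activity,
        gene_dispersion=pd.Series(dispersion, index=gene_ids),
        params={"effect_logfc": cfg.effect_logfc, "baseline_logfc": cfg.baseline_logfc,
                "receptor_gene": gene_ids[cfg.receptor_gene_index], "seed": cfg.seed},
    )
    return SimulatedDataset(
        counts=AbundanceMatrix(counts_df, "counts"),
        tpm=AbundanceMatrix(tpm_df, "tpm"),
        metadata=SampleMetadata(meta),
        truth=truth,
        config=cfg,
    )


def dataclass_replace(cfg: SimulationConfig, **overrides) -> SimulationConfig:
    from dataclasses import replace

    return replace(cfg, **overrides)


def write_fixture(dataset: SimulatedDataset, directory) -> dict:
    """Write counts.tsv / tpm.tsv / metadata.tsv / truth.json.

    The tables round-trip losslessly through :mod:`igfresponse.io_qc` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "tpm": directory / "tpm.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    dataset.counts.values.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    dataset.tpm.values.to_csv(paths["tpm"], sep="\t", index_label="gene_id")
    dataset.metadata.table.to_csv(paths["metadata"], sep="\t", index=False)
    t = dataset.truth
    payload = {
        "gene_class": t.gene_class.to_dict(),
        "gene_direction": {k: int(v) for k, v in t.gene_direction.items()},
        "response_scale": t.response_scale.to_dict(),
        "responder_flag": {k: bool(v) for k, v in t.responder_flag.items()},
        "activity": t.activity.to_dict(),
        "gene_dispersion": {k: float(v) for k, v in t.gene_dispersion.items()},
        "params": t.params,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_truth(path) -> SimulatedTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimulatedTruth(
        gene_class=pd.Series(payload["gene_class"]),
        gene_direction=pd.Series(payload["gene_direction"]),
        response_scale=pd.Series(payload["response_scale"]),
        responder_flag=pd.Series(payload["responder_flag"]),
        activity=pd.Series(payload["activity"]),
        gene_dispersion=pd.Series(payload.get("gene_dispersion", {}), dtype=float),
        params=payload.get("params", {}),
    )
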