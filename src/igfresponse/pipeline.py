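"""End-to-end orchestration: QC -> DE -> signature stats -> resampling ->
co-expression -> projection -> recovery, with a JSON summary report.

Every stage is a pure function of (inputs, config, seed); running the same
config twice produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression as coex
from . import diffexpr as de
from . import io_qc, projection, recovery, resampling, signature_stats as sigstats
from .datatypes import AbundanceMatrix, SampleMetadata, ValidationError
from .simulate import SimulationConfig, SimulatedDataset, simulate_dataset

log = logging.getLogger("igfresponse")


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    tpm_path: str | None = None
    metadata_path: str | None = None
    simulate: dict | None = None  # SimulationConfig fields; used when paths absent
    fdr_cut: float = 0.05
    n_perm: int = 100
    permutation_scheme: str = "within_patient"
    permutation_design: str = "additive"
    min_module_size: int = 10
    scale_free_r2: float = 0.9
    cut_height: float = 0.99
    recovery_rule: str = "strict"
    projection_scale: bool = True
    receptor_gene: str | None = None
    n_trees: int = 500
    outdir: str = "igfresponse_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("counts_path", "tpm_path", "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValidationError(
                        f"{name} missing or does not exist (and no simulate block)"
                    )


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        ds = simulate_dataset(SimulationConfig(**sim_kwargs))
        receptor = ds.truth.params.get("receptor_gene")
        return ds.counts, ds.tpm, ds.metadata, ds, receptor
    counts = io_qc.read_abundance(cfg.counts_path, "counts")
    tpm = io_qc.read_abundance(cfg.tpm_path, "tpm")
    meta = io_qc.read_metadata(cfg.metadata_path)
    return counts, tpm, meta, None, cfg.receptor_gene


def _exact_between(
    counts: AbundanceMatrix, meta: SampleMetadata,
    mask_ref, mask_test, label: str,
) -> de.DEResult:
    """Exact test between two arbitrary sample groups given boolean masks."""
    keep = np.asarray(mask_ref) | np.asarray(mask_test)
    sub = counts.subset_samples(meta.table.loc[keep, "sample_id"])
    msub = meta.subset(keep)
    group = np.where(np.asarray(mask_test)[keep], "test", "ref")
    msub2 = msub.table.copy()
    filt = de.filter_expressed(sub)
    norm = de.tmm_factors(filt)
    design = de.DesignSpec(["treatment"], tested="treatment")
    # dispersion from a one-factor design on the two groups
    msub2["treatment"] = np.where(group == "test", "acute", "H2O")
    disp = de.estimate_dispersions(filt, design, norm, metadata=SampleMetadata(msub2))
    groups = pd.Series(group, index=pd.Index(msub.table["sample_id"]))[list(filt.sample_ids)]
    return de.exact_test(filt, groups, norm, disp, contrast=label, levels=("ref", "test"))


def _de_glm_contrast(counts, meta, diagnosis, arm, fdr_cut):
    """GLM LRT treatment-vs-vehicle within one diagnosis, patient-adjusted."""
    keep = (
        (meta.table["diagnosis"] == diagnosis)
        & meta.table["treatment"].isin(["H2O", arm])
    ).to_numpy()
    sub = counts.subset_samples(meta.table.loc[keep, "sample_id"])
    msub = meta.subset(keep)
    filt = de.filter_expressed(sub)
    norm = de.tmm_factors(filt)
    design = de.DesignSpec(["treatment", "patient_id"], tested="treatment")
    disp = de.estimate_dispersions(filt, design, norm, metadata=msub)
    return de.glm_lrt(filt, design, norm, disp, msub, contrast=f"{diagnosis}_{arm}_vs_H2O")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``<outdir>/report.json`` together with per-stage tables)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(asctime)s %(name)s %(message)s")
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        t0 = time.time()
        log.info("stage=%s start seed=%d", name, config.seed)
        return t0

    def done(name, t0, block):
        block["wall_time_s"] = round(time.time() - t0, 3)
        report["stages"][name] = block
        log.info("stage=%s done in %.2fs", name, block["wall_time_s"])

    # ---- inputs / simulation -------------------------------------------
    t0 = stage("inputs")
    counts, tpm, meta, sim, receptor_gene = _load_inputs(config)
    block = {
        "n_genes": int(counts.n_genes),
        "n_samples": int(counts.n_samples),
        "simulated": sim is not None,
    }
    if sim is not None:
        block["gene_class_counts"] = sim.truth.gene_class.value_counts().to_dict()
        block["n_responders_true"] = int(sim.truth.responder_flag.sum())
    done("inputs", t0, block)

    # ---- qc -------------------------------------------------------------
    t0 = stage("qc")
    tpm_kept, qcreport = io_qc.exclude_outliers(tpm)
    kept_ids = tpm_kept.sample_ids
    counts = counts.subset_samples(kept_ids)
    tpm = tpm_kept
    meta = meta.aligned_to(counts)
    logtpm = io_qc.log_normalize(tpm)
    qcreport.to_json(outdir / "qc_report.json")
    done("qc", t0, {
        "n_excluded": len(qcreport.excluded_samples),
        "excluded": [list(x) for x in qcreport.excluded_samples],
        "n_samples_kept": int(counts.n_samples),
    })

    # ---- differential expression ---------------------------------------
    t0 = stage("differential_expression")
    contrasts = {}
    for dx in ("CTL", "ASD"):
        for arm in ("acute", "chronic"):
            res = _de_glm_contrast(counts, meta, dx, arm, config.fdr_cut)
            contrasts[f"{dx.lower()}_{arm}"] = res
            res.table.to_csv(outdir / f"de_{dx.lower()}_{arm}.tsv", sep="\t")
    baseline = recovery.baseline_de(counts, meta)
    baseline.table.to_csv(outdir / "de_baseline.tsv", sep="\t")
    contrasts["baseline"] = baseline
    done("differential_expression", t0, {
        name: {"n_significant": int(len(res.significant(config.fdr_cut))),
               "n_tested": int(len(res.table))}
        for name, res in contrasts.items()
    })

    # ---- signature stats ------------------------------------------------
    t0 = stage("signature_stats")
    block = {}
    universe = int(counts.n_genes)
    for dx in ("ctl", "asd"):
        acute, chronic = contrasts[f"{dx}_acute"], contrasts[f"{dx}_chronic"]
        ov = sigstats.overlap_fisher(
            list(acute.significant(config.fdr_cut)),
            list(chronic.significant(config.fdr_cut)),
            universe,
        )
        groups = sigstats.temporal_grouping(
            de.DEResult(acute.table.loc[acute.table.index.intersection(chronic.table.index)],
                        acute.contrast, acute.test),
            de.DEResult(chronic.table.loc[chronic.table.index.intersection(acute.table.index)],
                        chronic.contrast, chronic.test),
            config.fdr_cut,
        )
        traj = {}
        for label in ("shared", "acute_only", "chronic_only"):
            genes = groups.genes(label)
            genes = genes[groups.direction.loc[genes] != "discordant"]
            if len(genes) == 0:
                continue
            tt = sigstats.trajectory_test(logtpm, meta, genes, group_label=label)
            traj[label] = {c: {"F": None if np.isnan(r["F"]) else float(r["F"]),
                               "p": float(r["p"])}
                           for c, r in tt.tests.iterrows()}
        block[dx] = {
            "overlap": ov.to_dict(),
            "temporal_group_sizes": groups.labels.value_counts().to_dict(),
            "trajectory": traj,
        }
    done("signature_stats", t0, block)

    # ---- resampling -----------------------------------------------------
    t0 = stage("resampling")
    block = {}
    rng = np.random.default_rng(config.seed)
    for dx in ("CTL", "ASD"):
        for arm in ("acute", "chronic"):
            keep = (meta.table["diagnosis"] == dx).to_numpy()
            sub = counts.subset_samples(meta.table.loc[keep, "sample_id"])
            msub = meta.subset(keep)
            perm = resampling.permutation_magnitude_test(
                sub, msub, ("H2O", arm),
                design=config.permutation_design,
                n_perm=config.n_perm,
                scheme=config.permutation_scheme,
                fdr_cut=config.fdr_cut,
                seed=int(rng.integers(2**31 - 1)),
            )
            key = f"{dx.lower()}_{arm}"
            entry = perm.to_dict()
            sig = contrasts[key].significant(config.fdr_cut)
            if len(sig) >= 1:
                lt_keep = msub.table["treatment"].isin(["H2O", arm]).to_numpy()
                ids = msub.table.loc[lt_keep, "sample_id"]
                feats = logtpm.subset_samples(ids).subset_genes(
                    pd.Index(sig).intersection(logtpm.gene_ids))
                labels = pd.Series(
                    msub.table.loc[lt_keep, "treatment"].to_numpy(), index=pd.Index(ids))
                rep = resampling.classify_treatment(
                    feats, labels, n_trees=config.n_trees,
                    seed=int(rng.integers(2**31 - 1)))
                entry["classifier"] = rep.to_dict()
            block[key] = entry
    done("resampling", t0, block)

    # ---- coexpression ---------------------------------------------------
    t0 = stage("coexpression")
    acute_union = pd.Index(contrasts["ctl_acute"].significant(config.fdr_cut)).union(
        contrasts["asd_acute"].significant(config.fdr_cut))
    block = {"n_input_genes": int(len(acute_union))}
    if len(acute_union) >= 3:
        wa = meta.table["treatment"].isin(["H2O", "acute"]).to_numpy()
        sub_lt = logtpm.subset_samples(meta.table.loc[wa, "sample_id"]).subset_genes(
            acute_union.intersection(logtpm.gene_ids))
        params = coex.pick_soft_power(
            sub_lt, r2_target=config.scale_free_r2, min_module_size=config.min_module_size)
        adj = coex.adjacency(sub_lt, params.soft_power)
        tom = coex.tom_similarity(adj)
        assign = coex.detect_modules(
            tom, min_module_size=config.min_module_size, cut_height=config.cut_height)
        eig = coex.module_eigengenes(sub_lt, assign)
        assign.labels.to_csv(outdir / "modules.tsv", sep="\t")
        eig.values.to_csv(outdir / "eigengenes.tsv", sep="\t")
        block.update({
            "soft_power": int(params.soft_power),
            "scale_free_r2": float(params.scale_free_r2),
            "module_sizes": assign.labels.value_counts().to_dict(),
        })
        if eig.values.shape[1]:
            itest = coex.eigengene_model(eig, meta.subset(wa))
            block["interaction_tests"] = {
                m: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for m, row in itest.table.iterrows()
            }
            block["interaction_significant"] = list(itest.interaction_significant())
    done("coexpression", t0, block)

    # ---- projection -----------------------------------------------------
    t0 = stage("projection")
    sig_genes = pd.Index(contrasts["ctl_acute"].significant(config.fdr_cut))
    block = {"n_signature_genes": int(len(sig_genes))}
    if len(sig_genes) >= 2:
        ctl_wa = (
            (meta.table["diagnosis"] == "CTL")
            & meta.table["treatment"].isin(["H2O", "acute"])
        ).to_numpy()
        ctl_lt = logtpm.subset_samples(meta.table.loc[ctl_wa, "sample_id"])
        space = projection.fit_pc_space(
            ctl_lt, meta.subset(ctl_wa), sig_genes, scale=config.projection_scale)
        wa = meta.table["treatment"].isin(["H2O", "acute"]).to_numpy()
        all_lt = logtpm.subset_samples(meta.table.loc[wa, "sample_id"])
        scores = projection.project(all_lt, space)
        shifts = projection.patient_shift(scores, meta.subset(wa))
        scores.to_csv(outdir / "pc_scores.tsv", sep="\t")
        shifts.patient_table.to_csv(outdir / "patient_shifts.tsv", sep="\t")
        block.update({
            "separation_p": float(space.separation_p),
            "patients": {
                p: {"diagnosis": r["diagnosis"], "delta_pc1": float(r["delta_pc1"]),
                    "responder": bool(r["responder"])}
                for p, r in shifts.patient_table.iterrows()
            },
            "n_responders": int(shifts.patient_table["responder"].sum()),
        })
        assoc = {}
        ptab = shifts.patient_table
        if "activity" in meta.table.columns:
            act = meta.table.groupby("patient_id")["activity"].first()
            common = ptab.index.intersection(act.index)
            if len(common) >= 3:
                a = projection.covariate_association(
                    ptab.loc[common, "delta_pc1"], act.loc[common], name="activity")
                assoc["activity"] = a.to_dict()
        if receptor_gene is not None and receptor_gene in logtpm.gene_ids:
            for arm, key in (("acute", "receptor_post_treatment"), ("H2O", "receptor_h2o")):
                sel = (meta.table["treatment"] == arm).to_numpy()
                expr = logtpm.subset_samples(meta.table.loc[sel, "sample_id"]).values.loc[
                    receptor_gene]
                lvl = pd.DataFrame({
                    "patient_id": meta.table.loc[sel, "patient_id"].to_numpy(),
                    "expr": expr.to_numpy(),
                }).groupby("patient_id")["expr"].mean()
                common = ptab.index.intersection(lvl.index)
                if len(common) >= 3:
                    a = projection.covariate_association(
                        ptab.loc[common, "delta_pc1"], lvl.loc[common], name=key)
                    assoc[key] = a.to_dict()
        block["covariate_associations"] = assoc
    done("projection", t0, block)

    # ---- recovery -------------------------------------------------------
    t0 = stage("recovery")
    asd = (meta.table["diagnosis"] == "ASD").to_numpy()
    dia = meta.table["diagnosis"].to_numpy()
    trt = meta.table["treatment"].to_numpy()
    asd_acute = _exact_between(
        counts, meta, asd & (trt == "H2O"), asd & (trt == "acute"), "asd_acute_vs_h2o")
    asd_chronic = _exact_between(
        counts, meta, asd & (trt == "H2O"), asd & (trt == "chronic"), "asd_chronic_vs_h2o")
    post_acute = _exact_between(
        counts, meta, (dia == "CTL") & (trt == "H2O"), asd & (trt == "acute"),
        "asd_acute_vs_ctl_h2o")
    post_chronic = _exact_between(
        counts, meta, (dia == "CTL") & (trt == "H2O"), asd & (trt == "chronic"),
        "asd_chronic_vs_ctl_h2o")
    calls = recovery.classify_recovery(
        contrasts["baseline"], asd_acute, asd_chronic, post_acute, post_chronic,
        fdr_cut=config.fdr_cut, rule=config.recovery_rule)
    calls.to_csv(outdir / "recovery_calls.tsv", sep="\t")
    base_calls = calls.loc[calls["baseline_de"]]
    done("recovery", t0, {
        "n_baseline_de": int(calls["baseline_de"].sum()),
        "combined_counts": base_calls["combined"].value_counts().to_dict(),
        "n_igf1_altered_acute": int(calls["igf1_altered_acute"].sum()),
        "n_igf1_altered_chronic": int(calls["igf1_altered_chronic"].sum()),
    })

    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def validate_report(report: dict) -> None:
    """Check the report against the bundled stage schema (required keys)."""
    schema = json.loads(
        resources.files("igfresponse").joinpath("report_schema.json").read_text())
    missing = [s for s in schema["required_stages"] if s not in report.get("stages", {})]
    if missing:
        raise ValidationError(f"report missing stages: {missing}")
    for name, keys in schema["stage_required_keys"].items():
        blk = report["stages"].get(name, {})
        lost = [k for k in keys if k not in blk]
        if lost:
            raise ValidationError(f"stage {name} missing keys: {lost}")
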