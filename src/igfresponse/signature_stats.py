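"""Gene-list overlap statistics, temporal grouping, trajectory tests, ORA.

The overlap statistic follows the conditional-exact convention: the odds
ratio is the conditional MLE under Fisher's noncentral hypergeometric
likelihood given the table margins, with the exact central 95% CI obtained
by inverting one-sided tests at 2.5% per side — the convention behind R's
``fisher.test`` printout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .datatypes import AbundanceMatrix, DEResult, SampleMetadata, ValidationError
from .diffexpr import adjust_fdr


@dataclass
class OverlapResult:
    both: int
    only_a: int
    only_b: int
    neither: int
    odds_ratio: float  # conditional MLE; may be inf
    ci95: tuple
    p_value: float

    def to_dict(self) -> dict:
        return {
            "both": self.both,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "neither": self.neither,
            "odds_ratio": float(self.odds_ratio),
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "p_value": float(self.p_value),
        }


def overlap_fisher(list_a, list_b, universe_n: int) -> OverlapResult:
    """Fisher exact overlap test of two gene lists within a universe.

    Returns the 2x2 table counts, the two-sided exact p, the conditional-MLE
    odds ratio and its exact central 95% CI.  A zero margin cell yields an
    infinite OR estimate.
    """
    a, b = set(list_a), set(list_b)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    union = both + only_a + only_b
    if union > universe_n:
        raise ValidationError(f"union of lists ({union}) exceeds universe ({universe_n})")
    neither = universe_n - union
    table = np.array([[both, only_a], [only_b, neither]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    return OverlapResult(
        both=both,
        only_a=only_a,
        only_b=only_b,
        neither=neither,
        odds_ratio=float(res.statistic),
        ci95=(float(ci.low), float(ci.high)),
        p_value=p,
    )


def chisq_categories(table) -> tuple:
    """Pearson chi-square of independence on an r x c count table.

    No continuity correction; requires positive marginal totals and positive
    expected counts.  Returns (X2, df, p).
    """
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero marginal row or column")
    chi2, p, df, expected = stats.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise ValidationError("zero expected counts")
    return float(chi2), int(df), float(p)


@dataclass
class TemporalGroups:
    labels: pd.Series  # shared / acute_only / chronic_only per gene
    direction: pd.Series  # up / down / discordant

    def genes(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def temporal_grouping(
    acute: DEResult, chronic: DEResult, fdr_cut: float = 0.05
) -> TemporalGroups:
    """Partition the union of acute- and chronic-significant genes.

    Shared genes take the acute direction; a shared gene whose two
    contrasts disagree in sign is flagged "discordant" (and excluded from
    trajectory aggregates downstream).
    """
    if not acute.table.index.equals(chronic.table.index):
        if set(acute.table.index) != set(chronic.table.index):
            raise ValidationError("acute and chronic results are on different feature sets")
        chronic = DEResult(
            chronic.table.loc[acute.table.index], chronic.contrast, chronic.test
        )
    a_sig = set(acute.significant(fdr_cut))
    c_sig = set(chronic.significant(fdr_cut))
    labels = {}
    direction = {}
    for g in a_sig | c_sig:
        in_a, in_c = g in a_sig, g in c_sig
        if in_a and in_c:
            labels[g] = "shared"
            sa = np.sign(acute.table.loc[g, "logFC"])
            sc = np.sign(chronic.table.loc[g, "logFC"])
            direction[g] = ("up" if sa > 0 else "down") if sa == sc else "discordant"
        elif in_a:
            labels[g] = "acute_only"
            direction[g] = "up" if acute.table.loc[g, "logFC"] > 0 else "down"
        else:
            labels[g] = "chronic_only"
            direction[g] = "up" if chronic.table.loc[g, "logFC"] > 0 else "down"
    idx = pd.Index(sorted(labels), name="gene_id")
    return TemporalGroups(
        labels=pd.Series([labels[g] for g in idx], index=idx, name="group"),
        direction=pd.Series([direction[g] for g in idx], index=idx, name="direction"),
    )


@dataclass
class TrajectoryTest:
    group: str
    direction: str
    scores: pd.Series  # per-sample aggregate
    tests: pd.DataFrame  # per contrast: F, p, flag
    degenerate: bool = False


def trajectory_test(
    logtpm: AbundanceMatrix,
    metadata: SampleMetadata,
    genes,
    contrasts=(("H2O", "acute"), ("H2O", "chronic")),
    group_label: str = "",
    direction_label: str = "",
) -> TrajectoryTest:
    """Aggregate-trajectory F-tests for one gene group.

    Each gene is z-scored across all samples; the per-sample aggregate is
    the mean z over the group.  Each contrast's F/p comes from a one-way
    treatment model restricted to the contrast's two arms.  A group whose
    aggregate is constant (all genes flat) is degenerate: p = 1, flagged.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValidationError("empty gene group")
    sub = logtpm.subset_genes(genes)
    meta = metadata.aligned_to(logtpm)
    vals = sub.values
    sd = vals.std(axis=1, ddof=0)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd.mask(sd == 0, np.inf), axis=0)
    agg = z.mean(axis=0)

    rows = []
    degenerate = float(agg.std(ddof=0)) == 0.0
    trt = pd.Series(meta.table["treatment"].to_numpy(), index=meta.sample_ids)
    for ref, test in contrasts:
        in_ref = agg[trt.index[trt == ref]]
        in_test = agg[trt.index[trt == test]]
        if len(in_ref) == 0 or len(in_test) == 0:
            raise ValidationError(f"contrast {test} vs {ref}: an arm has no samples")
        if degenerate or (in_ref.std(ddof=0) == 0 and in_test.std(ddof=0) == 0
                          and in_ref.mean() == in_test.mean()):
            rows.append((f"{test}_vs_{ref}", np.nan, 1.0, True))
            continue
        f = stats.f_oneway(in_ref.to_numpy(), in_test.to_numpy())
        pv = 1.0 if np.isnan(f.pvalue) else float(f.pvalue)
        rows.append((f"{test}_vs_{ref}", float(f.statistic), pv, bool(np.isnan(f.statistic))))
    tests = pd.DataFrame(rows, columns=["contrast", "F", "p", "degenerate"]).set_index("contrast")
    return TrajectoryTest(
        group=group_label,
        direction=direction_label,
        scores=agg,
        tests=tests,
        degenerate=degenerate,
    )


def enrichment_ora(hits, universe, gene_sets: dict) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``hits`` in each set.

    Sets are intersected with the universe first; p is the upper-tail
    hypergeometric probability of seeing at least the observed overlap;
    BH adjustment is across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    hits = set(hits) & universe
    N, n = len(universe), len(hits)
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & universe
        k = len(s & hits)
        K = len(s)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "pvalue"]).set_index("set")
    df["fdr"] = adjust_fdr(df["pvalue"].to_numpy())
    return df


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
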