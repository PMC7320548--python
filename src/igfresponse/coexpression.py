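"""Supervised co-expression network on DE genes.

Weighted-correlation network in the WGCNA style: an unsigned adjacency
|cor|^beta with beta chosen as the smallest power reaching a scale-free
topology fit R^2 above target; topological overlap similarity; modules from
average-linkage clustering of the TOM dissimilarity with a static tree cut;
module eigengenes (first PC of gene-standardized module expression); and a
per-module linear model eigengene ~ disease * treatment with F-tests,
flagging interaction-significant modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .datatypes import AbundanceMatrix, SampleMetadata, ValidationError

#: deterministic module labels by descending size, WGCNA color style
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)
UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    soft_power: int
    scale_free_r2: float
    r2_by_power: pd.Series = field(default=None)
    min_module_size: int = 10
    network_type: str = "unsigned"
    reached_target: bool = True


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) vs log10 k regression, truncated at 0."""
    k = k[k > 0]
    if len(k) < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / len(k)))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r**2 * (-np.sign(slope))
    return float(max(r2, 0.0))


def _drop_constant_genes(logtpm: AbundanceMatrix) -> AbundanceMatrix:
    sd = logtpm.values.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant genes dropped before correlation")
    return AbundanceMatrix(logtpm.values.loc[sd > 0], logtpm.kind)


def pick_soft_power(
    logtpm: AbundanceMatrix, r2_target: float = 0.9, max_power: int = 20,
    min_module_size: int = 10,
) -> NetworkParams:
    """Smallest soft-threshold power whose connectivity distribution reaches
    the scale-free fit target; falls back to the best power with a warning."""
    logtpm = _drop_constant_genes(logtpm)
    if logtpm.n_genes < 3 or logtpm.n_samples < 4:
        raise ValidationError("need at least 3 variable genes and 4 samples")
    corr = np.corrcoef(logtpm.values.to_numpy())
    acorr = np.abs(np.clip(corr, -1, 1))
    np.fill_diagonal(acorr, 0.0)
    r2s = {}
    for beta in range(1, max_power + 1):
        k = (acorr**beta).sum(axis=1)
        r2s[beta] = _scale_free_r2(k)
        # a non-positive target is vacuous: the minimal power satisfies it
        if r2s[beta] > r2_target or r2_target <= 0:
            return NetworkParams(
                soft_power=beta, scale_free_r2=r2s[beta],
                r2_by_power=pd.Series(r2s), min_module_size=min_module_size,
            )
    best = max(r2s, key=r2s.get)
    warnings.warn(
        f"no power reached scale-free R^2 > {r2_target}; using best power {best} "
        f"(R^2 = {r2s[best]:.3f})"
    )
    return NetworkParams(
        soft_power=best, scale_free_r2=r2s[best], r2_by_power=pd.Series(r2s),
        min_module_size=min_module_size, reached_target=False,
    )


def adjacency(logtpm: AbundanceMatrix, soft_power: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    logtpm = _drop_constant_genes(logtpm)
    corr = np.corrcoef(logtpm.values.to_numpy())
    a = np.abs(np.clip(corr, -1, 1)) ** soft_power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=logtpm.gene_ids, columns=logtpm.gene_ids)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap: shared neighbors plus the direct edge,
    normalized by the smaller connectivity."""
    A = np.asarray(adj, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency must be square and symmetric")
    if np.abs(np.diag(A)).max() > 1e-10:
        raise ValidationError("adjacency must have a zero diagonal")
    k = A.sum(axis=1)
    shared = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + A) / (kmin + 1.0 - A)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return pd.DataFrame(tom)


@dataclass
class ModuleAssignment:
    labels: pd.Series  # per-gene module color or "unassigned"

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.labels.value_counts()
        return sizes[sizes.index != UNASSIGNED].sort_values(ascending=False)

    def genes(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def detect_modules(
    tom: pd.DataFrame, min_module_size: int = 10, cut_height: float = 0.99
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters below ``min_module_size`` become "unassigned"; surviving
    modules get deterministic color labels by descending size.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    T = np.asarray(tom, dtype=float)
    if not np.allclose(T, T.T, atol=1e-10):
        raise ValidationError("TOM must be symmetric")
    genes = tom.index if isinstance(tom, pd.DataFrame) else pd.RangeIndex(T.shape[0])
    diss = 1.0 - T
    np.fill_diagonal(diss, 0.0)
    diss = np.maximum(diss, 0.0)
    Z = average(squareform(diss, checks=False))
    clusters = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.full(len(genes), UNASSIGNED, dtype=object)
    sizes = pd.Series(clusters).value_counts()
    big = sizes[sizes >= min_module_size]
    # deterministic: order by size desc, ties by smallest member index
    order = sorted(
        big.index,
        key=lambda c: (-big[c], int(np.argmax(clusters == c))),
    )
    for color, c in zip(MODULE_COLORS, order):
        labels[clusters == c] = color
    if len(order) > len(MODULE_COLORS):
        for extra, c in enumerate(order[len(MODULE_COLORS):], start=1):
            labels[clusters == c] = f"module{len(MODULE_COLORS) + extra}"
    return ModuleAssignment(labels=pd.Series(labels, index=genes, name="module"))


@dataclass
class EigengeneTable:
    values: pd.DataFrame  # samples x modules
    variance_explained: pd.Series


def module_eigengenes(
    logtpm: AbundanceMatrix, assignment: ModuleAssignment, include_unassigned: bool = True
) -> EigengeneTable:
    """First-PC eigengene per module, sign-aligned to the module average.

    Genes are z-scored across samples before the SVD, so each eigengene has
    zero mean across samples.  A single-gene module's eigengene is that
    gene's z-scores.  The unassigned set is also summarized as a reportable
    module (the study analyzes its grey set as a signature).
    """
    modules = list(assignment.module_sizes.index)
    if include_unassigned and (assignment.labels == UNASSIGNED).any():
        modules.append(UNASSIGNED)
    cols = {}
    varexp = {}
    for m in modules:
        genes = assignment.genes(m).intersection(logtpm.gene_ids)
        if len(genes) == 0:
            continue
        sub = logtpm.values.loc[genes]
        sd = sub.std(axis=1, ddof=0)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd.mask(sd == 0, np.inf), axis=0)
        zt = z.to_numpy()
        if len(genes) == 1:
            eig = zt[0]
            varexp[m] = 1.0
        else:
            u, s, vt = np.linalg.svd(zt, full_matrices=False)
            eig = vt[0] * s[0] / np.sqrt(max(len(genes), 1))
            varexp[m] = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
        avg = zt.mean(axis=0)
        if len(genes) > 1 and np.std(eig) > 0 and np.corrcoef(eig, avg)[0, 1] < 0:
            eig = -eig
        cols[m] = eig
    values = pd.DataFrame(cols, index=logtpm.sample_ids)
    return EigengeneTable(values=values, variance_explained=pd.Series(varexp))


@dataclass
class InteractionTest:
    table: pd.DataFrame  # per module: F and p for disease, treatment, interaction

    def interaction_significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["interaction_p"] < alpha]


def eigengene_model(eigengenes: EigengeneTable, metadata: SampleMetadata) -> InteractionTest:
    """Per-module linear model eigengene ~ disease * treatment with F-tests."""
    meta = metadata.table.set_index("sample_id").loc[eigengenes.values.index]
    rows = []
    for m in eigengenes.values.columns:
        df = pd.DataFrame(
            {
                "eig": eigengenes.values[m].to_numpy(),
                "disease": meta["diagnosis"].to_numpy(),
                "treatment": meta["treatment"].to_numpy(),
            }
        )
        fit = ols("eig ~ C(disease) * C(treatment)", data=df).fit()
        try:
            an = sm.stats.anova_lm(fit, typ=2)
        except ValueError as err:
            raise ValidationError(f"module {m}: {err}") from err
        get = lambda term: (
            float(an.loc[term, "F"]), float(an.loc[term, "PR(>F)"])
        ) if term in an.index else (np.nan, np.nan)
        dF, dp = get("C(disease)")
        tF, tp = get("C(treatment)")
        iF, ip = get("C(disease):C(treatment)")
        rows.append((m, dF, dp, tF, tp, iF, ip))
    table = pd.DataFrame(
        rows,
        columns=[
            "module", "disease_F", "disease_p", "treatment_F", "treatment_p",
            "interaction_F", "interaction_p",
        ],
    ).set_index("module")
    return InteractionTest(table=table)
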