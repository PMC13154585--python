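"""Co-expression module detection and hub-gene selection.

A simplified weighted co-expression workflow on translation-efficiency
profiles: genes are filtered by mean TE and variance rank, an (unsigned
by default) adjacency ``|cor|**power`` is transformed into topological
overlap (TOM), modules come from average-linkage clustering of 1 - TOM
with a static tree cut followed by iterative eigengene merging, and hub
genes are those exceeding both the gene-significance (|GS|, gene-trait
correlation) and module-membership (|MM|, gene-eigengene correlation)
thresholds inside trait-associated modules.

Defaults follow the profiled cohort's network settings: soft power 9,
merge cut height 0.26, minimum module size 35, mean-TE filter at 1 and
variance filter keeping the top 70%.  The static cut plus eigengene
merging replaces dynamic tree cutting; module recovery on planted
block-correlated data, not numerical identity with any reference
implementation, is the accuracy contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

GREY = "grey"


@dataclass
class NetworkParams:
    """Tunable parameters of the module-detection stage."""

    power: float = 9.0
    merge_cut_height: float = 0.26
    min_module_size: int = 35
    te_min: float = 1.0
    variance_quantile: float = 0.70
    cut_height: float = 0.80
    signed: bool = False

    def validate(self):
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge cut height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min module size must be >= 2")


@dataclass
class ModuleResult:
    """Module assignments, eigengenes and trait statistics."""

    labels: pd.Series  # gene -> module label ('grey' = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    module_trait_cor: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None
    gs: pd.DataFrame | None = None  # genes x traits
    mm: pd.Series | None = None  # gene -> cor with own module eigengene
    hubs: pd.Index | None = None
    expr: pd.DataFrame | None = None  # genes x samples used for detection

    def module_sizes(self) -> pd.Series:
        return self.labels.value_counts()


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_genes(te_matrix: pd.DataFrame, params: NetworkParams) -> pd.Index:
    """Mean-TE filter, then variance-rank filter on the survivors.

    Keeps genes with mean TE >= ``te_min`` and variance in the top
    ``variance_quantile`` of the mean-filtered set (ties broken by gene
    id for a deterministic cut).
    """
    mean_ok = te_matrix.index[te_matrix.mean(axis=1) >= params.te_min]
    if mean_ok.empty:
        raise ValueError(
            f"no gene passes mean TE >= {params.te_min}; relax te_min"
        )
    survivors = te_matrix.loc[mean_ok]
    n_keep = int(np.ceil(params.variance_quantile * len(survivors) - 1e-9))
    if n_keep < 1:
        raise ValueError("variance filter removes every gene; relax it")
    ranked = (
        survivors.var(axis=1)
        .to_frame("var")
        .assign(gene=lambda d: d.index)
        .sort_values(["var", "gene"], ascending=[False, True])
    )
    return pd.Index(ranked.index[:n_keep])


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def adjacency(expr: pd.DataFrame, power: float, signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency from gene-gene Pearson correlation."""
    x = expr.to_numpy(dtype=float)
    cor = np.corrcoef(x)
    if signed:
        a = ((1.0 + cor) / 2.0) ** power
    else:
        a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return np.clip(a, 0.0, 1.0)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap: shared-neighbourhood similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with row connectivity k_i = sum_u a_iu and unit diagonal.
    """
    k = adj.sum(axis=1)
    shared = adj @ adj
    num = shared + adj
    den = np.minimum.outer(k, k) + 1.0 - adj
    tom = num / np.maximum(den, 1e-12)
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(expr: np.ndarray) -> np.ndarray:
    """First principal component of standardized expression, sign-fixed.

    ``expr`` is genes x samples; returns a per-sample vector whose mean
    correlation with the module's genes is non-negative.
    """
    z = expr - expr.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    z = z / np.maximum(sd, 1e-12)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    cors = np.array([_pearson(row, eig) for row in z])
    if cors.mean() < 0:
        eig = -eig
    return eig


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def detect_modules(expr: pd.DataFrame, params: NetworkParams | None = None) -> ModuleResult:
    """Detect co-expression modules in a genes x samples matrix.

    Constant genes are dropped with a warning before correlation.
    Clusters from the static cut that fall below ``min_module_size`` are
    labelled grey; modules whose eigengenes correlate above
    ``1 - merge_cut_height`` are merged iteratively.  Final labels are
    M1, M2, ... in decreasing module size.
    """
    params = params or NetworkParams()
    params.validate()
    variances = expr.var(axis=1)
    constant = expr.index[variances <= 0]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant gene(s) before correlation"
        )
        expr = expr.drop(index=constant)
    if len(expr) < params.min_module_size:
        raise ValueError("fewer genes than min module size")
    if expr.shape[1] < 4:
        raise ValueError("module detection needs >= 4 samples")

    adj = adjacency(expr, params.power, params.signed)
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=params.cut_height, criterion="distance")

    genes = expr.index
    labels = pd.Series(GREY, index=genes, dtype=object)
    clusters = {}
    for cid in np.unique(raw):
        members = genes[raw == cid]
        if len(members) >= params.min_module_size:
            clusters[len(clusters)] = list(members)
    for cid, members in clusters.items():
        labels.loc[members] = f"raw{cid}"

    labels = _merge_modules(expr, labels, params.merge_cut_height)

    # rename by decreasing size with deterministic ties (first gene id)
    sizes = labels[labels != GREY].value_counts()
    order = sorted(
        sizes.index,
        key=lambda m: (-sizes[m], labels.index[labels == m][0]),
    )
    rename = {m: f"M{i + 1}" for i, m in enumerate(order)}
    labels = labels.map(lambda m: rename.get(m, GREY))

    eigengenes = _eigengene_frame(expr, labels)
    return ModuleResult(labels=labels, eigengenes=eigengenes, expr=expr)


def _eigengene_frame(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    cols = {}
    for module in sorted(set(labels) - {GREY}):
        cols[module] = _eigengene(expr.loc[labels == module].to_numpy(float))
    return pd.DataFrame(cols, index=expr.columns)


def _merge_modules(expr: pd.DataFrame, labels: pd.Series, merge_cut: float) -> pd.Series:
    """Iteratively merge module pairs with eigengene correlation > 1 - cut."""
    labels = labels.copy()
    threshold = 1.0 - merge_cut
    while True:
        modules = sorted(set(labels) - {GREY})
        if len(modules) < 2:
            return labels
        eig = _eigengene_frame(expr, labels)
        best, best_cor = None, threshold
        for i, a in enumerate(modules):
            for b in modules[i + 1 :]:
                c = _pearson(eig[a].to_numpy(), eig[b].to_numpy())
                if c > best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            return labels
        a, b = best
        labels[labels == b] = a


# ---------------------------------------------------------------------------
# trait statistics and hubs
# ---------------------------------------------------------------------------

def module_trait_stats(result: ModuleResult, traits: pd.DataFrame) -> ModuleResult:
    """Eigengene-trait correlations with p-values, plus per-gene GS and MM.

    ``traits`` is samples x traits, numerically coded, aligned with the
    expression columns.  Constant traits raise.
    """
    traits = traits.loc[result.eigengenes.index]
    if (traits.std(axis=0) <= 0).any():
        bad = list(traits.columns[traits.std(axis=0) <= 0])
        raise ValueError(f"constant trait(s): {bad}")

    cors, pvals = {}, {}
    for module in result.eigengenes.columns:
        e = result.eigengenes[module].to_numpy(float)
        cors[module], pvals[module] = {}, {}
        for trait in traits.columns:
            r, p = stats.pearsonr(e, traits[trait].to_numpy(float))
            cors[module][trait] = r
            pvals[module][trait] = p
    result.module_trait_cor = pd.DataFrame(cors).T
    result.module_trait_p = pd.DataFrame(pvals).T

    expr = result.expr
    gs = {}
    for trait in traits.columns:
        tvec = traits[trait].to_numpy(float)
        gs[trait] = [
            _pearson(expr.loc[g].to_numpy(float), tvec) for g in expr.index
        ]
    result.gs = pd.DataFrame(gs, index=expr.index)

    mm = pd.Series(np.nan, index=expr.index)
    for module in result.eigengenes.columns:
        e = result.eigengenes[module].to_numpy(float)
        members = result.labels.index[result.labels == module]
        mm.loc[members] = [
            _pearson(expr.loc[g].to_numpy(float), e) for g in members
        ]
    result.mm = mm
    return result


def select_hubs(
    result: ModuleResult,
    trait: str,
    gs_min: float = 0.4,
    mm_min: float = 0.7,
    alpha: float = 0.05,
) -> pd.Index:
    """Hub genes: |GS| > gs_min and |MM| > mm_min within significant modules.

    Only modules whose eigengene correlates with ``trait`` at p < alpha
    (and R^2 > 0) contribute hubs.
    """
    if result.gs is None or result.mm is None:
        raise ValueError("run module_trait_stats first")
    sig_modules = [
        m
        for m in result.eigengenes.columns
        if result.module_trait_p.loc[m, trait] < alpha
        and result.module_trait_cor.loc[m, trait] ** 2 > 0
    ]
    in_sig = result.labels.isin(sig_modules)
    hub = (
        in_sig
        & (result.gs[trait].abs() > gs_min)
        & (result.mm.abs() > mm_min)
    )
    result.hubs = result.labels.index[hub.fillna(False)]
    return result.hubs
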