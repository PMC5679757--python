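"""Signed weighted co-expression networks with eigengene post-processing.

Modules are detected on the top-variance genes of one region: a signed
adjacency ((1 + r)/2)^beta is converted to a topological overlap matrix,
1 - TOM dissimilarities are clustered by average linkage, and the tree is
cut at the constant height that maximizes the number of clusters of at
least the minimum module size.  Post-processing follows the eigengene
rules: iterative merging of the most correlated eigengene pairs down to a
module-count cap, reassignment of every expressed gene to its argmax-kME
module, an unassigned label 0 for genes whose best kME falls below a
threshold, and relabeling by the fraction of neuronal marker genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .enrich import GeneList, hypergeom_upper_tail
from .matrix import LOG2, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkParams:
    variable_gene_fraction: float = 0.5
    soft_power: int = 14
    network_type: str = "signed"
    min_module_size: int = 20
    merge_cut_height: float = 0.1
    kme_threshold: float = 0.4
    max_modules: int = 20
    expressed_floor: float = 0.1  # mean log2(FPKM+1) defining "expressed"
    # a cluster counts as a module only if its mean internal TOM
    # dissimilarity sits at least this relative margin below the matrix
    # background; random clusters from a noise dendrogram sit at the
    # background level and are rejected
    min_cluster_tightness: float = 0.005

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0.0 < self.kme_threshold < 1.0:
            raise ValueError("kme_threshold must be in (0, 1)")
        if self.max_modules < 1:
            raise ValueError("max_modules must be >= 1")
        if self.network_type != "signed":
            raise ValueError("only the signed network type is supported")


@dataclass
class ModulePartition:
    """Gene -> module labels (0 = unassigned), eigengenes and kME table."""

    labels: pd.Series
    eigengenes: pd.DataFrame = None  # samples x modules
    kme: pd.DataFrame = None         # genes x modules

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


def _log2_df(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        if matrix.space != LOG2:
            raise ValueError("co-expression expects log2(FPKM + 1) values")
        return matrix.data
    return matrix


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Standard TOM: T_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_modules(
    matrix, params: NetworkParams = NetworkParams(), samples: pd.DataFrame | None = None
) -> ModulePartition:
    """Detect initial modules in a single-region expression matrix.

    Top ``variable_gene_fraction`` genes by variance enter the network;
    the dendrogram of 1 - TOM distances is cut at the constant height
    yielding the most clusters that are both large (>= ``min_module_size``)
    and cohesive (mean internal dissimilarity below the matrix background
    by ``min_cluster_tightness``), taking the smallest such height on
    ties.  Genes in rejected clusters, and genes outside the variance
    filter, are labeled 0 at this stage.
    """
    df = _log2_df(matrix)
    if samples is not None:
        regions = samples.set_index("sample_id").loc[df.columns, "region"]
        if regions.nunique() > 1:
            raise ValueError("build_modules requires samples from a single region")
    n_keep = max(int(round(params.variable_gene_fraction * df.shape[0])), 1)
    variances = df.var(axis=1)
    keep = variances.sort_values(ascending=False).index[:n_keep]
    if len(keep) < 2 * params.min_module_size:
        raise ValueError("too few genes after variance filtering")
    x = df.loc[keep].to_numpy(dtype=float)
    r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    adj = ((1.0 + r) / 2.0) ** params.soft_power
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    heights = np.unique(z[:, 2])
    if heights.size > 60:
        heights = np.quantile(heights, np.linspace(0.02, 1.0, 60))
    background = np.median(dist[np.triu_indices_from(dist, k=1)])

    def accepted_clusters(cl: np.ndarray) -> list[np.ndarray]:
        out = []
        for c in range(1, cl.max() + 1):
            idx = np.flatnonzero(cl == c)
            if idx.size < params.min_module_size:
                continue
            sub = dist[np.ix_(idx, idx)]
            internal = sub[np.triu_indices(idx.size, k=1)].mean()
            if 1.0 - internal / background >= params.min_cluster_tightness:
                out.append(idx)
        return out

    # scan candidate cut heights for the one giving the most large,
    # cohesive clusters (smallest such height on ties)
    best: tuple[int, float | None, list] = (0, None, [])
    for h in heights:
        cl = fcluster(z, t=h, criterion="distance")
        clusters = accepted_clusters(cl)
        if len(clusters) > best[0]:
            best = (len(clusters), h, clusters)
    labels = pd.Series(0, index=df.index, dtype=int, name="module")
    for new, idx in enumerate(best[2], start=1):
        labels.loc[keep[idx]] = new
    part = ModulePartition(labels=labels)
    part.eigengenes = module_eigengenes(df, labels)
    return part


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(matrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized members.

    Each eigengene has unit variance; its sign is fixed so it correlates
    positively with the mean standardized member expression (falling back
    to the first member gene's orientation in the exact-tie case).
    """
    df = _log2_df(matrix)
    modules = sorted(m for m in pd.unique(labels) if m != 0)
    cols = {}
    for m in modules:
        genes = labels.index[labels == m]
        x = _standardize(df.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            me = x[0]
        else:
            # first left singular vector of samples x genes
            u, s, _ = np.linalg.svd(x.T, full_matrices=False)
            me = u[:, 0]
        sd = me.std(ddof=1)
        me = me / (sd if sd > 0 else 1.0)
        ref = x.mean(axis=0)
        orient = np.dot(me, ref)
        if orient == 0:
            orient = np.dot(me, x[0])
        if orient < 0:
            me = -me
        cols[f"M{m}"] = me
    return pd.DataFrame(cols, index=df.columns)


def _kme(df: pd.DataFrame, eigengenes: pd.DataFrame, genes: pd.Index) -> pd.DataFrame:
    x = _standardize(df.loc[genes].to_numpy(dtype=float))
    e = _standardize(eigengenes.to_numpy(dtype=float).T).T
    n = df.shape[1]
    k = x @ e / (n - 1)
    return pd.DataFrame(k, index=genes, columns=eigengenes.columns)


def refine_modules(
    matrix, partition: ModulePartition, params: NetworkParams = NetworkParams()
) -> ModulePartition:
    """Merge, reassign and threshold an initial partition.

    While the module count exceeds ``max_modules`` — or any eigengene pair
    correlates above 1 - ``merge_cut_height`` — the most correlated pair is
    merged and its eigengene recomputed.  Every expressed gene (mean above
    ``expressed_floor``) is then reassigned to its argmax-kME module, genes
    with max kME below ``kme_threshold`` go to label 0, empty modules are
    dropped with renumbering, and eigengenes/kME are recomputed once.
    """
    df = _log2_df(matrix)
    labels = partition.labels.copy()
    me = partition.eigengenes
    if me is None:
        me = module_eigengenes(df, labels)
    me = me.copy()

    def merge_step() -> bool:
        nonlocal labels, me
        if me.shape[1] < 2:
            return False
        c = np.corrcoef(me.to_numpy().T)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        must = me.shape[1] > params.max_modules
        close = c[i, j] >= 1.0 - params.merge_cut_height
        if not (must or close):
            return False
        mi = int(me.columns[i][1:])
        mj = int(me.columns[j][1:])
        lo, hi = min(mi, mj), max(mi, mj)
        labels[labels == hi] = lo
        me = me.drop(columns=[f"M{hi}"])
        genes = labels.index[labels == lo]
        me[f"M{lo}"] = module_eigengenes(df.loc[genes], labels.loc[genes])[f"M{lo}"]
        me = me[sorted(me.columns, key=lambda s: int(s[1:]))]
        return True

    while merge_step():
        pass

    expressed = df.index[df.mean(axis=1) > params.expressed_floor]
    kme = _kme(df, me, expressed)
    best = kme.idxmax(axis=1)
    best_val = kme.max(axis=1)
    new_labels = pd.Series(0, index=df.index, dtype=int, name="module")
    assigned = best_val >= params.kme_threshold
    new_labels.loc[expressed[assigned]] = [int(s[1:]) for s in best[assigned]]

    # drop empty modules and renumber consecutively
    kept = sorted(m for m in new_labels.unique() if m != 0)
    remap = {m: i + 1 for i, m in enumerate(kept)}
    dropped = set(int(s[1:]) for s in me.columns) - set(kept)
    if dropped:
        logger.info("modules emptied by reassignment and dropped: %s", sorted(dropped))
    new_labels = new_labels.map(lambda m: remap.get(m, 0)).astype(int)
    final_me = module_eigengenes(df, new_labels)
    final_kme = _kme(df, final_me, expressed)
    return ModulePartition(labels=new_labels, eigengenes=final_me, kme=final_kme)


def relabel_by_marker_fraction(
    partition: ModulePartition, marker_genes: GeneList
) -> ModulePartition:
    """Renumber modules by descending marker-gene fraction.

    Ties break by larger module first, then by prior label.  Label 0 is
    untouched; gene co-membership is unchanged.
    """
    markers = set(marker_genes.genes)
    order = []
    for m in partition.module_ids:
        genes = partition.members(m)
        frac = len(set(genes) & markers) / len(genes)
        order.append((-frac, -len(genes), m))
    order.sort()
    remap = {old: new for new, (_, _, old) in enumerate(order, start=1)}
    labels = partition.labels.map(lambda m: remap.get(m, 0)).astype(int)
    me = None
    if partition.eigengenes is not None:
        me = partition.eigengenes.rename(columns={f"M{o}": f"M{n}" for o, n in remap.items()})
        me = me[sorted(me.columns, key=lambda s: int(s[1:]))]
    kme = None
    if partition.kme is not None:
        kme = partition.kme.rename(columns={f"M{o}": f"M{n}" for o, n in remap.items()})
        kme = kme[sorted(kme.columns, key=lambda s: int(s[1:]))]
    return ModulePartition(labels=labels, eigengenes=me, kme=kme)


def me_trait_association(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Pearson association of every eigengene with every trait column.

    Missing trait values are dropped pairwise; constant traits are flagged
    not-assessable.  Bonferroni correction spans the full assessable
    ME x trait grid.
    """
    traits = traits.loc[eigengenes.index]
    rows = []
    n_tests = 0
    for me_name in eigengenes.columns:
        e = eigengenes[me_name]
        for trait in traits.columns:
            t = pd.to_numeric(traits[trait], errors="coerce")
            ok = t.notna()
            if ok.sum() < 3 or t[ok].std() == 0 or e[ok].std() == 0:
                rows.append(dict(module=me_name, trait=trait, r=np.nan,
                                 p=np.nan, assessable=False))
                continue
            r, p = stats.pearsonr(e[ok], t[ok])
            rows.append(dict(module=me_name, trait=trait, r=float(r),
                             p=float(p), assessable=True))
            n_tests += 1
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_corrected"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    elif correction != "none":
        raise ValueError(f"unknown correction: {correction!r}")
    return out


def module_overlap_test(
    labels_a: pd.Series, labels_b: pd.Series, universe_size: int | None = None
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap of two partitions' module pairs."""
    shared = labels_a.index.intersection(labels_b.index)
    if universe_size is None:
        universe_size = len(shared)
    if universe_size == 0:
        raise ValueError("empty gene universe")
    la, lb = labels_a.loc[shared], labels_b.loc[shared]
    mods_a = sorted(m for m in la.unique() if m != 0)
    mods_b = sorted(m for m in lb.unique() if m != 0)
    rows = []
    for ma in mods_a:
        ga = set(la.index[la == ma])
        for mb in mods_b:
            gb = set(lb.index[lb == mb])
            k = len(ga & gb)
            p = hypergeom_upper_tail(universe_size, len(ga), len(gb), k)
            rows.append(dict(module_a=ma, module_b=mb, overlap=k,
                             size_a=len(ga), size_b=len(gb), p=p))
    out = pd.DataFrame(rows)
    out["p_bonf"] = np.minimum(out["p"] * len(out), 1.0)
    return out
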