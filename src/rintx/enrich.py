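"""Cross-study gene-list machinery.

Scaled-rank concordance: given a per-gene metric (e.g. log2 fold change of
dementia vs. control, or correlation with RIN) and an external gene list,
genes are sorted by the metric, ranked, scaled to [0, 1], and the list
members' positions are summarized by their quartiles together with a
two-sided Wilcoxon rank-sum p-value for divergence from a uniform draw.

Also: construction of cell-type marker sets from a genes x cell-types
expression table (2-fold enrichment over every other type and an FPKM
floor) and hypergeometric enrichment of modules in those sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneList:
    name: str
    genes: tuple[str, ...]
    direction: str = "unsigned"  # up | down | unsigned
    source: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "unsigned"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        genes = tuple(dict.fromkeys(self.genes))
        if not genes:
            raise ValueError(f"gene list {self.name!r} is empty")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ConcordanceResult:
    list_name: str
    scaled_ranks: np.ndarray
    p25: float
    p50: float
    p75: float
    wilcoxon_p: float
    n_list_found: int
    n_universe: int


class EmptyOverlapError(ValueError):
    """No gene of the list occurs in the metric's universe."""


def _wilcoxon_rank_sum(in_list: np.ndarray, ranks: np.ndarray) -> float:
    """Two-sided rank-sum p for list members vs the rest.

    Exact enumeration when the smaller group has <= 10 members (valid with
    ties only approximately; scipy's exact method requires no ties, so ties
    fall back to the tie-corrected normal approximation).
    """
    a = ranks[in_list]
    b = ranks[~in_list]
    has_ties = len(np.unique(ranks)) < len(ranks)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def scaled_rank_concordance(
    metric: pd.Series, gene_list: GeneList, sort_order: str = "ascending"
) -> ConcordanceResult:
    """Locate a gene list within the ranking of all genes by a metric.

    Genes are sorted by the metric (``sort_order`` in {ascending,
    descending}), given average ranks 1..N for ties, and scaled to [0, 1]
    via (rank - 1)/(N - 1).  Reported: quartiles of the list members'
    scaled ranks and the two-sided Wilcoxon rank-sum p of members vs
    non-members.
    """
    if sort_order not in ("ascending", "descending"):
        raise ValueError(f"unknown sort_order: {sort_order!r}")
    metric = metric.dropna()
    n = len(metric)
    if n < 2:
        raise ValueError("metric universe must contain >= 2 genes")
    values = metric.to_numpy(dtype=float)
    if sort_order == "descending":
        values = -values
    ranks = stats.rankdata(values, method="average")
    scaled = (ranks - 1.0) / (n - 1.0)
    in_list = metric.index.isin(gene_list.genes)
    if not in_list.any():
        raise EmptyOverlapError(
            f"no gene of list {gene_list.name!r} found in the metric universe"
        )
    member = np.sort(scaled[in_list])
    p25, p50, p75 = np.percentile(member, [25, 50, 75])
    return ConcordanceResult(
        list_name=gene_list.name,
        scaled_ranks=member,
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        wilcoxon_p=_wilcoxon_rank_sum(in_list, ranks),
        n_list_found=int(in_list.sum()),
        n_universe=n,
    )


def concordance_panel(
    metrics: dict[str, pd.Series], gene_lists: list[GeneList]
) -> pd.DataFrame:
    """Evaluate every list against every metric.

    Down-regulated lists are ranked ascending and up-regulated lists
    descending; unsigned lists use the ascending order.  A list landing at
    the leading end of its sort (scaled ranks toward 0) tracks the
    metric's extreme in its own direction, while e.g. degradation-down
    lists evaluated against a RIN-correlation metric shift toward 1.
    """
    rows = []
    for metric_name, metric in metrics.items():
        for gl in gene_lists:
            order = "descending" if gl.direction == "up" else "ascending"
            res = scaled_rank_concordance(metric, gl, sort_order=order)
            rows.append(
                dict(metric=metric_name, list=gl.name, direction=gl.direction,
                     p25=res.p25, median=res.p50, p75=res.p75,
                     wilcoxon_p=res.wilcoxon_p,
                     n_list_found=res.n_list_found, n_universe=res.n_universe)
            )
    return pd.DataFrame(rows)


def build_marker_sets(
    celltype_fpkm: pd.DataFrame, fold: float = 2.0, min_fpkm: float = 1.0
) -> dict[str, GeneList]:
    """Cell-type marker sets from a genes x cell-types FPKM table.

    A gene marks cell type t iff its FPKM in t is at least ``fold`` times
    its FPKM in every other type and exceeds ``min_fpkm``.
    """
    if celltype_fpkm.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    vals = celltype_fpkm.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative FPKM in cell-type table")
    out: dict[str, GeneList] = {}
    for j, ct in enumerate(celltype_fpkm.columns):
        own = vals[:, j]
        others = np.delete(vals, j, axis=1)
        is_marker = (own > min_fpkm) & np.all(own[:, None] >= fold * others, axis=1)
        genes = tuple(celltype_fpkm.index[is_marker])
        if genes:
            out[str(ct)] = GeneList(name=str(ct), genes=genes, source="marker-set rule")
    return out


def celltype_enrichment(
    module_genes: dict[int, set[str] | list[str]],
    marker_sets: dict[str, GeneList],
    universe: set[str] | list[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of modules in marker sets.

    p = P(overlap >= observed) drawing |module| genes from the universe
    containing |marker set in universe| successes; Bonferroni correction is
    over the full module x type grid.  A marker set disjoint from the
    universe yields a not-assessable (NaN) row.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    n_tests = 0
    rows = []
    for mod, genes in module_genes.items():
        genes = set(genes) & universe
        for ct, ms in marker_sets.items():
            markers = set(ms.genes) & universe
            if not markers:
                rows.append(dict(module=mod, cell_type=ct, overlap=0, p=np.nan))
                continue
            k = len(genes & markers)
            p = hypergeom_upper_tail(len(universe), len(markers), len(genes), k)
            rows.append(dict(module=mod, cell_type=ct, overlap=k, p=p))
            n_tests += 1
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_bonf"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    elif correction != "none":
        raise ValueError(f"unknown correction: {correction!r}")
    return out


def hypergeom_upper_tail(universe: int, n_marked: int, n_drawn: int, overlap: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, n_marked, n_drawn)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, n_marked, n_drawn))


# ---------------------------------------------------------------- GMT I/O

def read_gmt(path) -> list[GeneList]:
    """Read gene lists from a GMT file (name, description, genes...).

    A description field of the form ``direction=up`` (or down) sets the
    list direction; anything else is kept as free-text source.
    """
    lists = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            direction = "unsigned"
            if desc.startswith("direction="):
                direction = desc.split("=", 1)[1]
            lists.append(GeneList(name=name, genes=tuple(genes),
                                  direction=direction, source=desc))
    return lists


def write_gmt(lists: list[GeneList], path) -> None:
    with open(path, "w") as fh:
        for gl in lists:
            desc = f"direction={gl.direction}" if gl.direction != "unsigned" else gl.source or "."
            fh.write("\t".join([gl.name, desc, *gl.genes]) + "\n")
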