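"""Hub selection, cross-network hub comparison and gene-set enrichment.

Hubs are genes in the top connectivity quantile of one network; the
interesting hubs are *exclusive* ones — e.g. top 10% Canberra-Mantel
(CoSplicEx) connectivity while sitting in the bottom 80% of coexpression
connectivity — because they carry information the coexpression network
misses.  Hub gene sets are compared against candidate gene lists with
Fisher's exact test, their numeric characteristics (exon counts,
transcript counts, coding length, GC%, count coefficient of variation)
with the Wilcoxon rank-sum test plus a Hodges-Lehmann shift estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mantel_net import GeneNetwork

__all__ = [
    "HubSet",
    "EnrichmentResult",
    "select_exclusive_hubs",
    "cross_hub_edge_quartiles",
    "fisher_enrichment",
    "compare_hub_characteristics",
    "hodges_lehmann_shift",
    "THRESHOLD_PRESETS",
]

# (top_q on network A, low_q on network B): exclusive-hub presets
THRESHOLD_PRESETS = {
    "exclusive": {"top_q": 0.10, "low_q": 0.80},
    "strict_exclusive": {"top_q": 0.10, "low_q": 0.10},
}


@dataclass
class HubSet:
    flavor: str
    genes: list[str]
    rule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def select_exclusive_hubs(
    k_a: pd.Series,
    k_b: pd.Series,
    top_q: float = 0.10,
    low_q: float = 0.80,
    flavor: str = "",
) -> HubSet:
    """Genes in the top ``top_q`` of k_a AND the bottom ``low_q`` of k_b.

    Quantiles are empirical with linear interpolation; both thresholds
    are inclusive, so boundary ties are kept.  Selection depends only on
    ranks, hence is invariant to monotone transforms of connectivity.
    """
    if not (0 < top_q < 1) or not (0 < low_q < 1):
        raise ValueError("quantile fractions must lie in (0, 1)")
    if list(k_a.index) != list(k_b.index):
        raise ValueError("connectivity vectors must cover identical gene lists")
    hi = np.quantile(k_a.to_numpy(), 1.0 - top_q)
    lo = np.quantile(k_b.to_numpy(), low_q)
    sel = (k_a >= hi) & (k_b <= lo)
    return HubSet(
        flavor=flavor,
        genes=list(k_a.index[sel]),
        rule={"top_q": top_q, "low_q": low_q, "k_a_threshold": float(hi), "k_b_threshold": float(lo),
              "quantile_convention": "linear interpolation, inclusive thresholds"},
    )


def cross_hub_edge_quartiles(
    net: GeneNetwork, hubs_a: HubSet, hubs_b: HubSet, scale: str = "adjacency"
) -> np.ndarray:
    """Counts of A-B cross-hub edges per quartile of ALL network edges.

    Quartile breakpoints come from every off-diagonal edge weight of the
    network; assignment is inclusive-upper (an edge equal to a breakpoint
    goes to the higher quartile, so an all-ties network puts everything
    in the 4th quartile).  Returns 4 counts summing to |A| x |B|.
    """
    if not hubs_a.genes or not hubs_b.genes:
        raise ValueError("hub sets must be non-empty")
    if set(hubs_a.genes) & set(hubs_b.genes):
        raise ValueError("hub sets must be disjoint")
    w = net.adjacency if scale == "adjacency" else net.correlation
    tri = w[np.tril_indices(net.n_genes, k=-1)]
    q25, q50, q75 = np.percentile(tri, [25, 50, 75])
    pos = {g: i for i, g in enumerate(net.gene_ids)}
    ia = [pos[g] for g in hubs_a.genes if g in pos]
    ib = [pos[g] for g in hubs_b.genes if g in pos]
    cross = w[np.ix_(ia, ib)].ravel()
    counts = np.array(
        [
            (cross < q25).sum(),
            ((cross >= q25) & (cross < q50)).sum(),
            ((cross >= q50) & (cross < q75)).sum(),
            (cross >= q75).sum(),
        ]
    )
    assert counts.sum() == len(ia) * len(ib)
    return counts


@dataclass
class EnrichmentResult:
    """2x2 overlap table with Fisher exact p-values and the sample odds ratio."""

    overlap: int
    set1_only: int
    set2_only: int
    neither: int
    odds_ratio: float
    p_one_sided: float
    p_two_sided: float
    universe_size: int

    def table(self) -> np.ndarray:
        return np.array([[self.overlap, self.set1_only], [self.set2_only, self.neither]])


def fisher_enrichment(set1, set2, universe) -> EnrichmentResult:
    """Fisher's exact test for overlap of two gene sets within a universe.

    One-sided p is the enrichment (hypergeometric upper) tail; the
    two-sided p is the standard Fisher exact test.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("universe must be non-empty")
    u = set(universe)
    s1 = set(set1) & u
    s2 = set(set2) & u
    if set(set1) - u or set(set2) - u:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(u) - a - b - c
    table = np.array([[a, b], [c, d]])
    odds, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_one = stats.fisher_exact(table, alternative="greater")
    return EnrichmentResult(
        overlap=a, set1_only=b, set2_only=c, neither=d,
        odds_ratio=float(odds), p_one_sided=float(p_one), p_two_sided=float(p_two),
        universe_size=len(u),
    )


def hodges_lehmann_shift(a, b) -> float:
    """Median of all pairwise differences b_j - a_i (location shift of b vs a)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.median(np.subtract.outer(b, a)))


def compare_hub_characteristics(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney p-value and Hodges-Lehmann shift of B relative to A."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0  # identical samples: no evidence of a shift by construction
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p, hodges_lehmann_shift(a, b)
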