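"""Per-gene sample x sample distance matrices.

Each gene is a vector of exon counts per sample.  Two metrics quantify
how differently a gene behaves in two samples:

* **Canberra** (CoSplicEx): ``d(i,j) = sum_e |a_ei - a_ej| / (a_ei + a_ej)``,
  each exon contributing between 0 and 1, so the distance is sensitive to
  both overall expression level and exon-inclusion changes.
* **Cosine** (cosplicing): ``d(i,j) = 1 - cos(a_i, a_j)``, invariant to
  per-sample scaling of the exon vector, hence blind to expression-level
  changes and sensitive only to exon-inclusion (splicing) changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "METRICS",
    "GeneDistanceSet",
    "canberra_distance_matrix",
    "cosine_distance_matrix",
    "all_gene_distances",
]

METRICS = ("canberra", "cosine")


@dataclass
class GeneDistanceSet:
    """Symmetric non-negative sample distance matrix of one gene, zero diagonal."""

    gene_id: str
    metric: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        self.matrix = m

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def _check_counts(gene_counts: np.ndarray) -> np.ndarray:
    x = np.asarray(gene_counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("gene counts must be an exon x sample matrix")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x


def canberra_distance_matrix(gene_counts: np.ndarray, gene_id: str = "") -> GeneDistanceSet:
    """Canberra distances between samples; 0/0 exon terms contribute 0.

    For non-negative counts the denominator |a_ei + a_ej| equals
    a_ei + a_ej, so scipy's Canberra (|x|+|y| denominator, zero terms
    skipped) evaluates the formula exactly.  Distances lie in [0, p]
    where p is the gene's exon count.
    """
    x = _check_counts(gene_counts)
    d = cdist(x.T, x.T, metric="canberra")
    np.fill_diagonal(d, 0.0)
    return GeneDistanceSet(gene_id, "canberra", d)


def cosine_distance_matrix(gene_counts: np.ndarray, gene_id: str = "") -> GeneDistanceSet:
    """Cosine distances 1 - a_i.a_j / (||a_i|| ||a_j||) between samples.

    Conventions for degenerate vectors (normally removed by filtering):
    both samples all-zero -> 0; exactly one all-zero -> 1.
    """
    x = _check_counts(gene_counts)
    norms = np.linalg.norm(x, axis=0)
    zero = norms <= 0
    safe = np.where(zero, 1.0, norms)
    u = x / safe
    d = 1.0 - u.T @ u
    np.clip(d, 0.0, 2.0, out=d)
    if zero.any():
        d[zero, :] = 1.0
        d[:, zero] = 1.0
        d[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry against fp round-off in the gram product
    d = 0.5 * (d + d.T)
    return GeneDistanceSet(gene_id, "cosine", d)


_METRIC_FUNCS = {
    "canberra": canberra_distance_matrix,
    "cosine": cosine_distance_matrix,
}


def all_gene_distances(table, metric: str) -> dict[str, GeneDistanceSet]:
    """One GeneDistanceSet per gene of an ExonCountTable, common sample order."""
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    func = _METRIC_FUNCS[metric]
    return {gene: func(counts, gene_id=gene) for gene, counts in table.iter_genes()}


def export_distance_matrix(dset: GeneDistanceSet, path, sample_ids=None) -> None:
    """Write one gene's distance matrix as TSV for inspection."""
    import pandas as pd

    n = dset.n_samples
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)]
    pd.DataFrame(dset.matrix, index=ids, columns=ids).to_csv(path, sep="\t")
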