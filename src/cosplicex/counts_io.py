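"""Reading, normalizing and filtering exon-level RNA-seq count tables.

The raw input is a table of non-negative counts with one row per
(gene, exon) and one column per sample ("union exon" summarization:
overlapping annotated exons flattened into disjoint intervals).  The
pre-processing pipeline is

1. upper-quartile normalization (per-sample scale factor = 75th
   percentile of non-zero gene totals over library size, geometric-mean
   centred),
2. removal of genes whose mean total count across samples falls below a
   threshold (default 500),
3. removal of genes all of whose exons sit in the bottom quartile of
   exon--exon correlation-network connectivity.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExonCountTable",
    "NormalizationFactors",
    "FilterReport",
    "CountTableFormatError",
    "read_exon_counts",
    "write_exon_counts",
    "upper_quartile_normalize",
    "filter_low_count_genes",
    "filter_low_connectivity_exons",
]


class CountTableFormatError(ValueError):
    """Raised when an exon count table violates the expected format."""


@dataclass
class ExonCountTable:
    """Exon-level counts: rows indexed by (gene_id, exon_id), one column per sample.

    Exon order within a gene follows the input order and is preserved by
    every operation in this module; sample order is never changed.
    """

    data: pd.DataFrame  # MultiIndex (gene_id, exon_id) x sample columns

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 2:
            raise CountTableFormatError("count table requires a (gene_id, exon_id) row index")
        self.data.index = self.data.index.set_names(["gene_id", "exon_id"])
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise CountTableFormatError(f"duplicate (gene_id, exon_id) row: {dup}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise CountTableFormatError("count table contains non-numeric cells")
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise CountTableFormatError(
                f"missing value at row {self.data.index[r]}, column {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise CountTableFormatError(
                f"negative count at row {self.data.index[r]}, column {self.data.columns[c]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data.index.get_level_values("gene_id"):
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_counts(self, gene_id: str) -> np.ndarray:
        """Exon x sample count matrix of one gene (exon order as stored)."""
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def iter_genes(self) -> Iterator[tuple[str, np.ndarray]]:
        for gene_id, block in self.data.groupby(level="gene_id", sort=False):
            yield gene_id, block.to_numpy(dtype=float)

    def gene_totals(self) -> pd.DataFrame:
        """Gene x sample table of exon-summed totals (union-exon gene counts)."""
        return self.data.groupby(level="gene_id", sort=False).sum()

    def subset_genes(self, keep: list[str]) -> "ExonCountTable":
        keep_set = set(keep)
        mask = self.data.index.get_level_values("gene_id").isin(keep_set)
        return ExonCountTable(self.data.loc[mask].copy())


@dataclass
class NormalizationFactors:
    """Per-sample upper-quartile scale factors and library sizes.

    Factors are centred so that their geometric mean is 1; a sample's
    counts are divided by (library size x factor) and rescaled by the
    mean library size, which puts all samples on a common upper quartile.
    """

    sample_ids: list[str]
    factors: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if (self.factors <= 0).any() or (self.library_sizes <= 0).any():
            raise ValueError("factors and library sizes must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of factors is {gm!r}, expected 1")


@dataclass
class FilterReport:
    genes_in: int
    genes_removed_low_count: int = 0
    genes_removed_low_exon_connectivity: int = 0
    genes_retained: int = 0
    removed_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.genes_removed_low_count
            + self.genes_removed_low_exon_connectivity
            + self.genes_retained
        )
        if total != self.genes_in:
            raise ValueError("filter report counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "genes_in": self.genes_in,
            "genes_removed_low_count": self.genes_removed_low_count,
            "genes_removed_low_exon_connectivity": self.genes_removed_low_exon_connectivity,
            "genes_retained": self.genes_retained,
        }


# ---------------------------------------------------------------------------
# I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_exon_counts(path: str | Path) -> ExonCountTable:
    """Read a TSV with header ``gene_id<TAB>exon_id<TAB><sample>...`` (gzip ok)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or list(df.columns[:2]) != ["gene_id", "exon_id"]:
        raise CountTableFormatError(
            f"{path}: expected header 'gene_id<TAB>exon_id<TAB><samples...>', "
            f"got {list(df.columns[:2])}"
        )
    sample_cols = list(df.columns[2:])
    for col in sample_cols:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.iloc[0] if len(bad) else None
            loc = f" at gene {row['gene_id']!r} exon {row['exon_id']!r}" if row is not None else ""
            raise CountTableFormatError(f"{path}: non-numeric cell in column {col!r}{loc}")
    df = df.set_index(["gene_id", "exon_id"])
    return ExonCountTable(df)


def write_exon_counts(table: ExonCountTable, path: str | Path) -> None:
    """Write in the same dialect read_exon_counts accepts."""
    with _open_text(path, "wt") as fh:
        table.data.reset_index().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization


def upper_quartile_normalize(
    table: ExonCountTable,
) -> tuple[ExonCountTable, NormalizationFactors]:
    """Upper-quartile normalization of exon counts.

    Per sample: library size = total count; raw factor = 75th percentile
    of the non-zero gene totals divided by the library size; factors are
    divided by their geometric mean; counts are divided by
    (library size x factor) and multiplied by the mean library size.
    The rescaling is uniform across all exons of a sample, so exon
    proportions within a gene are untouched.
    """
    totals = table.gene_totals().to_numpy(dtype=float)  # genes x samples
    lib_sizes = totals.sum(axis=0)
    zero = lib_sizes <= 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"all-zero sample(s): {bad}")
    uq = np.empty_like(lib_sizes)
    for j in range(totals.shape[1]):
        nz = totals[:, j][totals[:, j] > 0]
        uq[j] = np.percentile(nz, 75)
    raw = uq / lib_sizes
    factors = raw / np.exp(np.mean(np.log(raw)))
    scale = lib_sizes.mean() / (lib_sizes * factors)
    norm = ExonCountTable(table.data * scale)
    return norm, NormalizationFactors(table.sample_ids, factors, lib_sizes)


# ---------------------------------------------------------------------------
# Filtering


def filter_low_count_genes(
    table: ExonCountTable, threshold: float = 500.0
) -> tuple[ExonCountTable, FilterReport]:
    """Drop genes whose mean (over samples) exon-summed total is strictly below threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    totals = table.gene_totals()
    mean_totals = totals.mean(axis=1)
    keep = mean_totals[mean_totals >= threshold].index.tolist()
    removed = [g for g in totals.index if g not in set(keep)]
    report = FilterReport(
        genes_in=table.n_genes,
        genes_removed_low_count=len(removed),
        genes_retained=len(keep),
        removed_gene_ids=removed,
    )
    logger.info("low-count filter: removed %d / %d genes", len(removed), table.n_genes)
    return table.subset_genes(keep), report


def _exon_connectivity(values: np.ndarray, block_size: int = 2048) -> np.ndarray:
    """Row sums of |Pearson| over all exon pairs, excluding self.

    Zero-variance exons get correlation 0 by convention (warned).  The
    computation is chunked over row blocks; results equal the dense
    exon x exon evaluation exactly.
    """
    n = values.shape[1]
    centred = values - values.mean(axis=1, keepdims=True)
    sd = np.sqrt((centred**2).sum(axis=1))
    flat = sd <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance exon(s); their correlations are set to 0",
            stacklevel=3,
        )
    z = np.zeros_like(centred)
    np.divide(centred, sd[:, None], out=z, where=~flat[:, None])
    m = z.shape[0]
    conn = np.empty(m)
    for start in range(0, m, block_size):
        block = z[start : start + block_size]
        corr = np.abs(block @ z.T)
        # exclude self-correlation (1 for regular exons, 0 for flat ones)
        conn[start : start + len(block)] = corr.sum(axis=1) - np.diag(
            corr[:, start : start + len(block)]
        )
    del n
    return conn


def filter_low_connectivity_exons(
    table: ExonCountTable, block_size: int = 2048
) -> tuple[ExonCountTable, FilterReport]:
    """Drop genes where every exon has bottom-quartile exon-network connectivity.

    Exon connectivity is the row sum of absolute Pearson correlations to
    all other exons (any gene); the cutoff is the 25th percentile of all
    exon connectivities, and a gene is removed only if all of its exons
    fall strictly below that cutoff.
    """
    values = table.data.to_numpy(dtype=float)
    if values.shape[0] < 8:
        raise ValueError("need at least 8 exons for a meaningful bottom quartile")
    conn = _exon_connectivity(values, block_size=block_size)
    cutoff = np.percentile(conn, 25)
    genes = table.data.index.get_level_values("gene_id")
    below = pd.Series(conn < cutoff, index=genes)
    all_below = below.groupby(level=0, sort=False).all()
    removed = all_below[all_below].index.tolist()
    keep = [g for g in table.gene_ids if g not in set(removed)]
    report = FilterReport(
        genes_in=table.n_genes,
        genes_removed_low_exon_connectivity=len(removed),
        genes_retained=len(keep),
        removed_gene_ids=removed,
    )
    logger.info(
        "exon-connectivity filter: removed %d / %d genes (cutoff %.4g)",
        len(removed),
        table.n_genes,
        cutoff,
    )
    return table.subset_genes(keep), report
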