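"""Module detection and permutation-based quality / preservation statistics.

Modules are detected by average-linkage hierarchical clustering on the
topological-overlap dissimilarity 1 - TOM, with a static tree cut and a
minimum module size; small clusters fall into the reserved
``"unassigned"`` label.  Module quality (within one network) and module
preservation (between a reference and a test network) are expressed as
permutation Z scores against random same-size gene sets: Z < 2 is read
as poor, Z > 10 as high quality/preservation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .mantel_net import GeneNetwork

__all__ = [
    "UNASSIGNED",
    "MODULE_COLOR_NAMES",
    "ModuleAssignment",
    "PreservationReport",
    "topological_overlap",
    "detect_modules",
    "module_quality",
    "module_preservation",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

# familiarity mapping: size-ranked module labels to the conventional color names
MODULE_COLOR_NAMES = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


@dataclass
class ModuleAssignment:
    """gene -> module label; labels are size-ranked M1, M2, ... plus 'unassigned'."""

    labels: pd.Series  # index gene_id, values str

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index.name = "gene_id"
        self.labels.name = "module"

    @property
    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()

    @property
    def module_names(self) -> list[str]:
        sizes = self.module_sizes
        return list(sizes.index)

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def color_map(self) -> dict[str, str]:
        names = self.module_names
        return {
            m: (MODULE_COLOR_NAMES[i] if i < len(MODULE_COLOR_NAMES) else f"color{i}")
            for i, m in enumerate(names)
        }

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("module").reset_index()


@dataclass
class PreservationReport:
    """Per-module permutation Z statistics; Z_summary = (Z_density + Z_connectivity)/2."""

    table: pd.DataFrame  # index module; columns size, Z_density, Z_connectivity, Z_separability, Z_summary
    n_permutations: int


# ---------------------------------------------------------------------------
# Topological overlap


def topological_overlap(net: GeneNetwork) -> np.ndarray:
    """TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), unit diagonal.

    L_ij sums a_iu * a_uj over shared neighbors u distinct from i and j;
    the adjacency diagonal is excluded throughout.
    """
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # with zero diagonal, (A@A)_ij already skips u in {i, j}
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# Module detection


def detect_modules(
    net: GeneNetwork, min_module_size: int = 30, cut_height: float = 0.9
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than min_module_size become 'unassigned'; surviving
    clusters are renamed M1, M2, ... by decreasing size (ties broken by
    first gene position for determinism).
    """
    if net.n_genes < min_module_size:
        logger.info("fewer genes than min_module_size; everything unassigned")
        return ModuleAssignment(pd.Series(UNASSIGNED, index=net.gene_ids))
    tom = topological_overlap(net)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip(0.5 * (dissim + dissim.T), 0.0, None)
    tree = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=net.gene_ids)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size]
    if keep.empty:
        logger.info("no cluster reached min_module_size=%d", min_module_size)
        return ModuleAssignment(pd.Series(UNASSIGNED, index=net.gene_ids))
    order = sorted(
        keep.index,
        key=lambda c: (-keep[c], int(np.argmax(labels.to_numpy() == c))),
    )
    rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
    out = labels.map(lambda c: rename.get(c, UNASSIGNED))
    return ModuleAssignment(out)


# ---------------------------------------------------------------------------
# Quality / preservation statistics

_MIN_MODULE_GENES = 3


def _density(a: np.ndarray, idx: np.ndarray) -> float:
    """Mean off-diagonal adjacency within a gene set."""
    sub = a[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))

def _separability(a: np.ndarray, idx: np.ndarray) -> float:
    """Within-set mean adjacency over mean adjacency from the set to outside."""
    mask = np.zeros(a.shape[0], dtype=bool)
    mask[idx] = True
    out = ~mask
    within = _density(a, idx)
    between = float(a[np.ix_(idx, np.where(out)[0])].mean())
    return within / between if between > 0 else np.inf

def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])

def _intramodular_connectivity(a: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = a[np.ix_(idx, idx)]
    return sub.sum(axis=1) - np.diag(sub)


def _zscore(observed: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd <= 1e-12:
        return np.inf if observed > null.mean() else (-np.inf if observed < null.mean() else 0.0)
    return float((observed - null.mean()) / sd)


def _missing_row(size: int) -> dict:
    return {"size": size, "Z_density": np.nan, "Z_connectivity": np.nan,
            "Z_separability": np.nan, "Z_summary": np.nan}


def _module_indices(modules: ModuleAssignment, gene_ids: list[str]) -> dict[str, np.ndarray]:
    pos = {g: i for i, g in enumerate(gene_ids)}
    out = {}
    for m in modules.module_names:
        genes = [g for g in modules.genes_in(m) if g in pos]
        out[m] = np.array([pos[g] for g in genes], dtype=int)
    return out


def module_quality(
    net: GeneNetwork,
    modules: ModuleAssignment,
    n_perm: int = 200,
    seed: int | None = None,
) -> PreservationReport:
    """Permutation Z scores for module density, connectivity and separability.

    Observed statistics per module: density = mean within-module
    adjacency; connectivity = correlation between intramodular and
    whole-network connectivity over module genes; separability = within
    density over module-to-outside mean adjacency.  Nulls come from
    n_perm uniformly drawn same-size gene sets.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k_all = a.sum(axis=1)
    n = net.n_genes
    rows = {}
    for m, idx in _module_indices(modules, net.gene_ids).items():
        if len(idx) < _MIN_MODULE_GENES:
            warnings.warn(f"module {m} has fewer than {_MIN_MODULE_GENES} genes; skipped")
            rows[m] = _missing_row(len(idx))
            continue
        obs_d = _density(a, idx)
        obs_c = _safe_corr(_intramodular_connectivity(a, idx), k_all[idx])
        obs_s = _separability(a, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        null_s = np.empty(n_perm)
        for p in range(n_perm):
            ridx = rng.choice(n, size=len(idx), replace=False)
            null_d[p] = _density(a, ridx)
            null_c[p] = _safe_corr(_intramodular_connectivity(a, ridx), k_all[ridx])
            null_s[p] = _separability(a, ridx)
        zd, zc, zs = _zscore(obs_d, null_d), _zscore(obs_c, null_c), _zscore(obs_s, null_s)
        rows[m] = {
            "size": len(idx),
            "Z_density": zd,
            "Z_connectivity": zc,
            "Z_separability": zs,
            "Z_summary": (zd + zc) / 2.0,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "module"
    return PreservationReport(table, n_perm)


def module_preservation(
    ref: GeneNetwork,
    test: GeneNetwork,
    ref_modules: ModuleAssignment,
    n_perm: int = 200,
    seed: int | None = None,
) -> PreservationReport:
    """Z statistics for how well reference modules persist in a test network.

    Both networks are restricted to their shared genes.  Per reference
    module: density = mean test adjacency among the module genes;
    connectivity = mean of cor(kIM_ref, kIM_test) and the correlation of
    within-module adjacency entries between the networks; separability
    as in module_quality but on the test network.  Nulls pair the module
    with random same-size gene sets of the test network.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    shared = [g for g in ref.gene_ids if g in set(test.gene_ids)]
    if not shared:
        raise ValueError("empty gene intersection between reference and test networks")
    logger.info("preservation: %d shared genes (%d ref, %d test)",
                len(shared), ref.n_genes, test.n_genes)
    rng = np.random.default_rng(seed)
    rpos = {g: i for i, g in enumerate(ref.gene_ids)}
    tpos = {g: i for i, g in enumerate(test.gene_ids)}
    ar = ref.adjacency[np.ix_([rpos[g] for g in shared], [rpos[g] for g in shared])].copy()
    at = test.adjacency[np.ix_([tpos[g] for g in shared], [tpos[g] for g in shared])].copy()
    np.fill_diagonal(ar, 0.0)
    np.fill_diagonal(at, 0.0)
    n = len(shared)
    spos = {g: i for i, g in enumerate(shared)}
    tri = lambda m: m[np.tril_indices(m.shape[0], k=-1)]

    def conn_stat(idx_ref: np.ndarray, idx_test: np.ndarray) -> float:
        cor_kim = _safe_corr(
            _intramodular_connectivity(ar, idx_ref), _intramodular_connectivity(at, idx_test)
        )
        cor_adj = _safe_corr(tri(ar[np.ix_(idx_ref, idx_ref)]), tri(at[np.ix_(idx_test, idx_test)]))
        return 0.5 * (cor_kim + cor_adj)

    rows = {}
    for m in ref_modules.module_names:
        genes = [g for g in ref_modules.genes_in(m) if g in spos]
        if len(genes) < _MIN_MODULE_GENES:
            warnings.warn(f"module {m}: fewer than {_MIN_MODULE_GENES} shared genes; skipped")
            rows[m] = _missing_row(len(genes))
            continue
        idx = np.array([spos[g] for g in genes], dtype=int)
        obs_d = _density(at, idx)
        obs_c = conn_stat(idx, idx)
        obs_s = _separability(at, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        null_s = np.empty(n_perm)
        for p in range(n_perm):
            ridx = rng.choice(n, size=len(idx), replace=False)
            null_d[p] = _density(at, ridx)
            null_c[p] = conn_stat(idx, ridx)
            null_s[p] = _separability(at, ridx)
        zd, zc, zs = _zscore(obs_d, null_d), _zscore(obs_c, null_c), _zscore(obs_s, null_s)
        rows[m] = {
            "size": len(idx),
            "Z_density": zd,
            "Z_connectivity": zc,
            "Z_separability": zs,
            "Z_summary": (zd + zc) / 2.0,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "module"
    return PreservationReport(table, n_perm)
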