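"""Synthetic exon-count data with planted coexpression and cosplicing modules.

The generator emulates bulk RNA-seq exon counts for genes that are
mixtures of (by default) two highly expressed isoforms:

* a gene's per-sample total T is negative-binomial around a gene
  baseline; genes in a *coexpression* module multiply T by a shared
  per-sample lognormal factor (strength-scaled), so their totals rise
  and fall together;
* the isoform mixing proportion theta is a logistic transform of a
  per-sample latent factor shared within a *cosplicing* module
  (strength-scaled), independent noise elsewhere, so module genes shift
  exon inclusion together while their totals stay independent;
* exon means are T times the normalized inclusion mixture and observed
  counts are Poisson around them, keeping gene totals unbiased for T.

Everything is deterministic given the seed, which makes the generator
usable both as a first-class simulation tool and as the test bed for
the whole pipeline (recovery_benchmark).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import counts_io, gene_distance, mantel_net, module_detect
from .counts_io import ExonCountTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "recovery_benchmark",
]

BACKGROUND = "background"


@dataclass
class SimulationConfig:
    """Study conditions of the generator.

    Defaults mirror a bulk brain RNA-seq design: 60 samples, genes with
    a handful to a dozen union exons, two dominant isoforms per gene,
    baseline totals well above the 500-count retention threshold, and a
    mild negative-binomial overdispersion.
    """

    n_samples: int = 60
    n_genes: int = 1000
    exons_per_gene: tuple[int, int] = (4, 12)
    n_coexpr_modules: int = 1
    n_cosplice_modules: int = 1
    module_size: tuple[int, int] = (50, 50)
    isoforms_per_gene: int = 2
    expression_strength: float = 0.8
    splicing_strength: float = 0.8
    nb_dispersion: float = 0.05
    baseline_mean: float = 2000.0
    depth_lognorm_sd: float = 0.3  # per-sample sequencing-depth variation (all genes)
    n_mixed_genes: int = 0  # genes loading on BOTH a coexpression and a cosplicing factor
    # couple the first splicing factor to the first expression factor: one module's
    # expression then co-varies with another module's splicing, the interaction only
    # the Canberra (CoSplicEx) flavor can see
    couple_expression_splicing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.expression_strength <= 1 and 0 <= self.splicing_strength <= 1):
            raise ValueError("strengths must lie in [0, 1]")
        if self.isoforms_per_gene < 2:
            raise ValueError("need at least 2 isoforms per gene")


@dataclass
class SimulationTruth:
    """Planted structure: per-gene module label/type, isoforms and latent factors."""

    module_label: pd.Series  # gene -> module name or "background"
    module_type: pd.Series  # gene -> "coexpression" | "cosplicing" | "mixed" | "background"
    isoforms: dict[str, np.ndarray]  # gene -> isoform x exon binary inclusion
    latent_mean: pd.Series = field(default_factory=pd.Series)  # gene -> baseline mean total
    expression_factors: pd.DataFrame = field(default_factory=pd.DataFrame)  # sample x module
    splicing_factors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def labels_of_type(self, kind: str) -> pd.Series:
        """Module labels with all genes of other types collapsed to background."""
        keep = self.module_type.isin([kind, "mixed"])
        return self.module_label.where(keep, BACKGROUND)


def _plant_modules(cfg: SimulationConfig, rng: np.random.Generator):
    sizes = rng.integers(cfg.module_size[0], cfg.module_size[1] + 1,
                         size=cfg.n_coexpr_modules + cfg.n_cosplice_modules)
    needed = int(sizes.sum()) + cfg.n_mixed_genes
    if needed > cfg.n_genes:
        raise ValueError(f"module sizes ({needed}) exceed n_genes ({cfg.n_genes})")
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    label = pd.Series(BACKGROUND, index=genes, dtype=object)
    mtype = pd.Series(BACKGROUND, index=genes, dtype=object)
    cursor = 0
    expr_of = {}
    splice_of = {}
    for m in range(cfg.n_coexpr_modules):
        name = f"coexpr{m + 1}"
        sel = genes[cursor : cursor + sizes[m]]
        label[sel] = name
        mtype[sel] = "coexpression"
        for g in sel:
            expr_of[g] = m
        cursor += sizes[m]
    for m in range(cfg.n_cosplice_modules):
        name = f"cosplice{m + 1}"
        s = sizes[cfg.n_coexpr_modules + m]
        sel = genes[cursor : cursor + s]
        label[sel] = name
        mtype[sel] = "cosplicing"
        for g in sel:
            splice_of[g] = m
        cursor += s
    if cfg.n_mixed_genes:
        if not cfg.n_coexpr_modules or not cfg.n_cosplice_modules:
            raise ValueError("mixed genes require at least one module of each type")
        sel = genes[cursor : cursor + cfg.n_mixed_genes]
        label[sel] = "mixed1"
        mtype[sel] = "mixed"
        for g in sel:
            expr_of[g] = 0
            splice_of[g] = 0
        cursor += cfg.n_mixed_genes
    return genes, label, mtype, expr_of, splice_of


def simulate(cfg: SimulationConfig) -> tuple[ExonCountTable, SimulationTruth]:
    """Generate an exon count table with the configured planted structure."""
    rng = np.random.default_rng(cfg.seed)
    genes, label, mtype, expr_of, splice_of = _plant_modules(cfg, rng)
    ns = cfg.n_samples
    samples = [f"s{i:03d}" for i in range(ns)]
    f_expr = rng.standard_normal((ns, max(cfg.n_coexpr_modules, 1)))
    f_splice = rng.standard_normal((ns, max(cfg.n_cosplice_modules, 1)))
    if cfg.couple_expression_splicing:
        if not (cfg.n_coexpr_modules and cfg.n_cosplice_modules):
            raise ValueError("coupling requires at least one module of each type")
        f_splice[:, 0] = f_expr[:, 0]
    depth = rng.lognormal(0.0, cfg.depth_lognorm_sd, size=ns) if cfg.depth_lognorm_sd > 0 else np.ones(ns)

    rows = []
    index = []
    isoforms: dict[str, np.ndarray] = {}
    latent_mean: dict[str, float] = {}
    for g in genes:
        p = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        iso = np.ones((cfg.isoforms_per_gene, p), dtype=float)
        for k in range(1, cfg.isoforms_per_gene):
            n_excl = int(rng.integers(1, max(2, p // 2 + 1)))
            drop = rng.choice(p, size=n_excl, replace=False)
            iso[k, drop] = 0.0
        isoforms[g] = iso.copy()

        # latent gene total per sample
        mu_g = cfg.baseline_mean * float(rng.lognormal(0.0, 0.4))
        latent_mean[g] = mu_g
        level = np.ones(ns)
        if g in expr_of:
            s = cfg.expression_strength
            # lognormal shared factor, strength-scaled; mean-corrected so E[T] ~= mu_g
            level = np.exp(s * f_expr[:, expr_of[g]] - 0.5 * s**2)
        mean_t = mu_g * level * depth
        if cfg.nb_dispersion > 1e-8:
            shape = 1.0 / cfg.nb_dispersion
            t = rng.gamma(shape, mean_t / shape)
        else:
            t = mean_t

        # isoform proportion per sample
        if g in splice_of:
            s = cfg.splicing_strength
            eta = 2.0 * (s * f_splice[:, splice_of[g]] + (1.0 - s) * rng.standard_normal(ns))
        else:
            eta = 2.0 * rng.standard_normal(ns)
        theta = 1.0 / (1.0 + np.exp(-eta))

        # exon means: T times normalized inclusion mixture (totals unbiased for T)
        mix = theta[None, :] * iso[0][:, None] + (1.0 - theta[None, :]) * iso[1][:, None]
        if cfg.isoforms_per_gene > 2:
            # extra isoforms share the residual mass equally
            extra = iso[2:].mean(axis=0)[:, None]
            mix = 0.8 * mix + 0.2 * extra
        mix = mix / mix.sum(axis=0, keepdims=True)
        means = t[None, :] * mix
        counts = rng.poisson(means).astype(float)
        for e in range(p):
            index.append((g, f"e{e + 1}"))
            rows.append(counts[e])
    data = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "exon_id"]),
        columns=samples,
    )
    truth = SimulationTruth(
        module_label=label,
        module_type=mtype,
        isoforms=isoforms,
        latent_mean=pd.Series(latent_mean),
        expression_factors=pd.DataFrame(
            f_expr, index=samples,
            columns=[f"coexpr{m + 1}" for m in range(f_expr.shape[1])],
        ),
        splicing_factors=pd.DataFrame(
            f_splice, index=samples,
            columns=[f"cosplice{m + 1}" for m in range(f_splice.shape[1])],
        ),
    )
    return ExonCountTable(data), truth


def run_detection(
    table: ExonCountTable,
    flavor: str,
    beta: float = 6.0,
    min_module_size: int = 30,
    cut_height: float = 0.9,
    low_count_threshold: float = 500.0,
    exon_connectivity_filter: bool = True,
) -> tuple[module_detect.ModuleAssignment, mantel_net.GeneNetwork]:
    """Normalize, filter, build one network flavor and detect its modules."""
    norm, _ = counts_io.upper_quartile_normalize(table)
    filt, _ = counts_io.filter_low_count_genes(norm, threshold=low_count_threshold)
    if exon_connectivity_filter:
        filt, _ = counts_io.filter_low_connectivity_exons(filt)
    if flavor == "coexpression":
        net = mantel_net.build_network(filt, "coexpression", beta=beta)
    else:
        metric = "cosine" if flavor == "cosplicing" else "canberra"
        dists = gene_distance.all_gene_distances(filt, metric)
        net = mantel_net.build_network(dists, flavor, beta=beta)
    modules = module_detect.detect_modules(net, min_module_size=min_module_size,
                                           cut_height=cut_height)
    return modules, net


def recovery_benchmark(
    cfg: SimulationConfig,
    flavor: str = "cosplicing",
    truth_type: str = "cosplicing",
    beta: float = 6.0,
    min_module_size: int = 30,
    cut_height: float = 0.9,
) -> float:
    """Adjusted Rand index between planted modules and detected modules.

    Runs the full pipeline (normalize -> filter -> distances -> network
    -> module detection) on a fresh simulation and scores the detected
    partition against the planted labels of the requested module type
    (other planted types count as background).
    """
    if cfg.n_coexpr_modules + cfg.n_cosplice_modules < 1:
        raise ValueError("config must plant at least one module")
    table, truth = simulate(cfg)
    modules, _ = run_detection(table, flavor, beta=beta,
                               min_module_size=min_module_size, cut_height=cut_height)
    planted = truth.labels_of_type(truth_type)
    shared = [g for g in modules.labels.index if g in planted.index]
    return float(adjusted_rand_score(planted[shared], modules.labels[shared]))


def write_truth(truth: SimulationTruth, path) -> None:
    """Truth table TSV: gene_id, module, type."""
    df = pd.DataFrame({"module": truth.module_label, "type": truth.module_type})
    df.index.name = "gene_id"
    df.reset_index().to_csv(path, sep="\t", index=False)
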