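# cosplicex

Gene **cosplicing network inference** from exon-level RNA-seq counts.

Bulk RNA-seq summarized per union exon carries information that a
per-gene scalar destroys: two genes can coordinate their *splicing*
(which exons get included) across samples even when their total
expression levels are uncorrelated. `cosplicex` builds weighted gene
networks that capture this coordination and analyzes them with the
standard weighted-network (WGCNA-style) toolkit. It is aimed at
transcriptomics / systems-biology analysts who have an exon × sample
count table and want network-level structure beyond coexpression.

## The method

Each gene is a vector of exon counts per sample. For every gene a
sample × sample distance matrix is computed under one of two metrics:

| metric | formula | sensitive to | network |
|---|---|---|---|
| Canberra | `d(i,j) = Σ_e |a_ei − a_ej|/(a_ei + a_ej)` | expression **and** exon inclusion | **CoSplicEx** |
| cosine | `d(i,j) = 1 − a_i·a_j/(‖a_i‖‖a_j‖)` | exon inclusion only | **cosplicing** |

For every gene pair the two distance matrices are correlated with the
Mantel procedure (Pearson over the paired lower-triangle entries), and
the resulting correlation `r` is soft-thresholded into an edge weight
`a = |r|^β` (β = 6 by default). A conventional **coexpression** network
(Pearson correlation of gene totals) is built from the same data for
comparison. Downstream: scale-free topology fits, TOM-based module
detection, permutation Z statistics for module quality/preservation,
exclusive-hub selection, Fisher-exact gene-set enrichment, and tests of
how shared regulatory features (PPI, TFBS, SFBS, microRNA sites,
chromosomal folding domains, colocalization) shift edge weights.

Pre-processing follows bulk RNA-seq practice: upper-quartile
normalization, removal of genes with mean total count below 500, and
removal of genes whose exons all sit in the bottom quartile of
exon–exon correlation-network connectivity. See `docs/methods.md` for
the full model, parameter meanings and numerical conventions.

## Worked example

Simulate a 60-sample dataset with one planted coexpression and one
planted cosplicing module (50 genes each among 300), then build the
cosplicing network and detect its modules:

```python
from cosplicex import (SimulationConfig, simulate, upper_quartile_normalize,
                       filter_low_count_genes, all_gene_distances,
                       build_network, topology_stats, detect_modules)

cfg = SimulationConfig(n_samples=60, n_genes=300, n_coexpr_modules=1,
                       n_cosplice_modules=1, module_size=(50, 50), seed=42)
table, truth = simulate(cfg)
norm, factors = upper_quartile_normalize(table)
filt, report = filter_low_count_genes(norm)        # 300 in, 299 retained
net = build_network(all_gene_distances(filt, "cosine"), "cosplicing", beta=6)
ts = topology_stats(net)
modules = detect_modules(net)
```

This prints (via the objects above):

```
genes in/retained: 300 299
density 0.0059  centralization 0.0432  heterogeneity 2.273  scale_free_r2 0.781
module sizes: {'M1': 50}
planted labels of M1: {'cosplice1': 50}
```

The cosine-Mantel network is sparse and strongly heterogeneous at β = 6
with a decent scale-free fit, and its single detected module is exactly
the planted 50-gene cosplicing module — the planted coexpression module
is invisible to this metric by construction, because cosine distances
do not change when a gene's overall level changes.

Enrichment example — overlap of 65 genes between a 425-gene hub set
and a 660-gene candidate list in a 9066-gene universe:

```python
from cosplicex import fisher_enrichment
res = fisher_enrichment(hub_genes, candidate_genes, universe)
res.p_one_sided   # 5.1e-09  -> a highly significant enrichment (OR 2.44)
```

## Command line

```bash
cosplicex simulate --seed 7 --out counts.tsv --truth truth.tsv
cosplicex network --in counts.tsv --metric canberra --beta 6 --out edges.tsv
cosplicex modules --in counts.tsv --metric cosine --out modules.tsv
cosplicex run --counts counts.tsv --seed 7 --out-dir run/
```

`run` executes the whole pipeline (normalize → filter → three networks
→ modules/quality → hubs, plus edge factors when annotation tables are
supplied) and writes TSV/JSON artifacts with a resolved-config copy.

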