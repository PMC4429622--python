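# Methods

## The model

`cosplicex` infers three weighted gene networks from one exon-level
RNA-seq count matrix. A gene is represented not as one scalar but as a
vector of union-exon counts per sample; coordinated changes of that
vector across samples carry information about splicing regulation that
a total-count summary destroys.

For each gene the package computes a sample × sample distance matrix:

* **Canberra**, `d_AC(i,j) = Σ_e |a_ei − a_ej| / (a_ei + a_ej)`, where
  `a_ei` is the count of exon `e` in sample `i`. Each exon contributes a
  value in [0, 1], so `d_AC ∈ [0, p]` for a gene with `p` exons. The
  measure responds to both expression-level and exon-inclusion changes;
  the network built from it is called **CoSplicEx**.
* **cosine**, `d_ACos(i,j) = 1 − a_i·a_j / (‖a_i‖‖a_j‖)`. Scaling a
  sample's exon vector by any positive constant leaves it unchanged, so
  it is blind to expression level and sees only exon-inclusion
  (splicing) changes; its network is the **cosplicing** network.

Two genes' distance matrices are compared with the **Mantel
correlation**: the Pearson correlation over the `N(N−1)/2` paired
lower-triangle entries. The all-pairs Mantel matrix is computed by
centring and L2-normalizing each gene's vectorized triangle and taking
one gram product; tests hold this to within 1e-10 of the looped
pairwise definition. The **coexpression** network uses the ordinary
Pearson correlation of exon-summed gene totals.

All flavors are soft-thresholded the same way, `adjacency = |r|^β`
with β = 6 by default (unsigned so that odd β stay valid; at the even
default the absolute value is inert). Topology statistics follow the
standard weighted-network closed forms: connectivity
`k_i = Σ_{j≠i} a_ij`, density `Σk / (n(n−1))`, centralization
`n/(n−2)·(max k/(n−1) − density)`, heterogeneity = population
coefficient of variation of `k`, and the scale-free fit R² from a
log10–log10 regression of bin frequency on bin mean connectivity over
10 equal-width bins (empty bins dropped).

## Pre-processing

1. **Upper-quartile normalization.** Per sample: library size = total
   count, raw factor = 75th percentile of non-zero gene totals divided
   by library size; factors geometric-mean-centred; counts divided by
   (library size × factor) and rescaled by the mean library size. This
   equalizes the upper quartile of gene totals across samples. Note the
   factor Q75/libsize is invariant under uniform per-sample rescaling,
   so a second pass reproduces the same factors and changes counts only
   by one global constant; the meaningful idempotence (equal upper
   quartiles after one pass) is what the tests assert.
2. **Low-count filter.** A gene is dropped when its mean exon-summed
   total across samples is strictly below 500 (configurable; applied
   after normalization by default).
3. **Exon-connectivity filter.** Connectivity of every exon = row sum
   of absolute Pearson correlations to all other exons (any gene,
   self excluded; zero-variance exons get correlation 0 by convention,
   with a warning). A gene is dropped only when every one of its exons
   falls strictly below the 25th percentile of all exon connectivities.
   The exon × exon correlation matrix is computed in row blocks and is
   exactly equal to the dense evaluation.

## Module detection, quality and preservation

Modules come from average-linkage hierarchical clustering on the
topological-overlap dissimilarity `1 − TOM`, where
`TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` and `L_ij` sums
`a_iu a_uj` over shared neighbors. The tree is cut at a static height
(default **0.90**) and clusters below `min_module_size = 30` become
`unassigned`. The default cut deserves a note: with β = 6 the adjacency
of unrelated gene pairs at realistic sample sizes (N ≈ 60) is of order
|r|⁶ ≲ 1e-3, so the TOM dissimilarity of noise pairs piles up just
below 1. A cut at 0.99 accepts pairs with average topological overlap
of only 0.01 and absorbs roughly 8% of unrelated genes into any real
module; 0.90 demands an order of magnitude more overlap and leaves
planted modules exactly recovered while unrelated genes stay
unassigned. Both knobs are exposed in the API and CLI.

Module **quality** (one network) and **preservation** (reference vs
test network) are permutation Z scores against `n_perm` (default 200)
uniformly drawn same-size gene sets, with a mandatory seed:

* density — mean within-module adjacency (in the test network for
  preservation);
* connectivity — for quality, the correlation between intramodular and
  whole-network connectivity of module genes; for preservation, the
  mean of cor(kIM_ref, kIM_test) and the correlation of within-module
  adjacency entries between the two networks;
* separability — within-module mean adjacency over module-to-outside
  mean adjacency;
* `Z_summary = (Z_density + Z_connectivity)/2`, with Z < 2 read as
  poor and Z > 10 as high quality/preservation.

Null sets for preservation pair the reference module with random
same-size gene sets of the test network, so a test network identical to
the reference scores very high while a label-permuted test network
scores near zero — both calibrations are asserted in the test suite.

## Hubs, enrichment, edge factors

Exclusive hubs are genes in the top connectivity decile of one network
and the bottom 80% (or bottom decile, for the strict preset) of
another; quantiles are empirical with linear interpolation and
inclusive thresholds, so selection is invariant to monotone transforms
of connectivity. Cross-hub edges are mapped onto quartiles of all
network edges with an inclusive-upper tie convention. Gene-set overlap
uses Fisher's exact test (one-sided enrichment tail plus the two-sided
p); numeric hub characteristics are compared with the two-sided
Mann–Whitney test plus the Hodges–Lehmann shift (median of all pairwise
differences).

Edge-factor analysis asks whether gene pairs sharing a regulatory
feature have heavier edges than background pairs. Pair groups come from
known PPI lists, TFBS Jaccard overlap strictly above 0.5, Canberra
distance between length-21 SFBS multiplicity vectors below a threshold
(default: the empirical lower quartile of all pair distances — the
published 7.6 is a dataset-specific value, not a constant), at least
two shared microRNA sites, shared chromosomal folding domains (against
greedy distance-matched cross-domain controls, ±20% midpoint-distance
tolerance, each control used once), and spatial colocalization lists.
Shifts are reported on the **correlation scale** by default — the
soft-thresholding power would crush shift magnitudes of the size these
factors produce (~0.03–0.14) — with a percentile bootstrap 95% CI over
pair resampling (construction choice of this package) and a two-sided
Mann–Whitney p.

## Synthetic data

The generator plants known structure so every stage is testable without
external data. Defaults describe a bulk brain RNA-seq design: 60
samples; 1000 genes with 4–12 union exons; two highly expressed
isoforms per gene (binary inclusion vectors differing in ≥ 1 exon);
baseline gene mean 2000 counts (lognormal gene-to-gene spread, sd 0.4),
comfortably above the 500-count retention threshold; negative-binomial
overdispersion 0.05 (gamma–Poisson); per-sample sequencing-depth
lognormal sd 0.3, which is what the upper-quartile normalization is
there to remove.

Coexpression-module genes multiply their latent total by a shared
per-sample lognormal factor `exp(s·f − s²/2)` (mean-corrected,
strength `s ∈ [0,1]`, default 0.8). Cosplicing-module genes set their
isoform proportion `θ = logistic(2·(s·g + (1−s)·ε))` from a shared
factor `g`; everywhere else `θ` is independent noise. Exon means are
the latent total times the *normalized* inclusion mixture — the
normalization keeps gene totals unbiased for the latent total, which
the raw two-isoform mixture would not be — and observed counts are
Poisson around the exon means. Optionally the first splicing factor can
be coupled to the first expression factor, creating expression–splicing
co-regulation between two modules that only the Canberra flavor can
see; this is how the cross-hub edge-quartile behavior is exercised.
Module genes are kept a ~10% minority of the transcriptome: a global
scaling normalization is mildly confounded by very large co-varying
modules (a compositional effect real analyses share), and a minority
share keeps that artifact at the level real data would show.

What the generator does **not** emulate: positional/GC bias,
read-level noise, correlated gene baselines, isoform count variation
beyond the two-isoform mixture, batch structure. Passing tests
therefore demonstrate correctness and calibration of the machinery on
data satisfying the model's assumptions, not performance on any real
tissue.

## Problem sizes and numerical choices

Simulated studies in the test-suite and in `scripts/acceptance.py` use
60 samples and 200–1000 genes with 50-gene planted modules — large
enough for stable Mantel correlations (1770 triangle entries per gene
pair) and clean module recovery, small enough to run everywhere.
Distances are dense double precision; 0/0 Canberra terms contribute 0;
all-zero vectors under cosine give d = 0 (both zero) or 1 (one zero);
constant Mantel triangles and zero-variance rows correlate 0 with a
warning; degenerate connectivity distributions report a scale-free R²
of 0 with a warning. Permutation draws are without replacement;
bootstrap CIs are percentile-based; all randomness flows from explicit
seeds.

## Known limitations

* Mantel permutation p-values are deliberately absent (the network uses
  the correlations as weights, not as test statistics).
* The quality/preservation statistics are the documented category-level
  subset (density, connectivity, separability, summary), not the full
  published battery of a reference implementation.
* Static tree cut instead of dynamic hybrid cutting; the cut height and
  minimum module size are the two knobs that matter most in practice.
* The SFBS "shared" threshold and the random-background size for edge
  shifts are dataset-dependent choices exposed as configuration, with
  defaults documented above.
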