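# Methods

This note records the models, parameter choices and numerical conventions
behind `lncnet`, and what the synthetic validation does and does not
demonstrate.

## Pipeline model

The analysis assumes bulk RNA-seq expression in RPKM over a developmental
sample series, and that biologically coherent gene groups manifest as
co-expression modules in an *unsigned* weighted network — a gene negatively
correlated with a module's trajectory belongs with it. All stages operate on
`log2(RPKM + 1)` values.

### Curation

* Expression floor: a gene is kept if its maximum over samples is ≥ 1 RPKM
  (`min_rpkm`, inclusive boundary). The unit is RPKM; the floor marks the
  conventional detection limit for bulk RNA-seq.
* Covariance screen: for gene *i*, `cov_sum_i = Σ_j cov(x_i, x_j)` — the row
  sum of the gene × gene covariance matrix, **including** the diagonal (the
  gene's own variance). By bilinearity this equals `cov(x_i, Σ_j x_j)`, so
  the dense matrix is never materialised. Both choices left open by the
  row-sum reading are flags: `include_diagonal` (default on) and `absolute`
  (default off; the absolute variant requires the dense matrix). Covariance
  uses the unbiased `n − 1` denominator; any consistent denominator only
  rescales all sums and cannot move the 2-means split.
* Low-information filter: one-dimensional 2-means (10 restarts, seeded) on
  the covariance sums; the cluster with the larger mean is kept. In one
  dimension the 2-means optimum is a threshold, which the test suite
  verifies against an exhaustive split search. If all sums are identical the
  split is undefined and every gene is kept with a warning.

### Network

* Correlations: plain Pearson, or the biweight midcorrelation (bicor) with
  median/MAD weighting. Two constants govern bicor and are deliberate:
  observations beyond **9 MADs** get zero weight, and at most **10% of
  observations per side** of the median may be zero-weighted — when a side's
  10% quantile of the scaled deviation exceeds the truncation boundary, the
  deviations on that side are rescaled so the quantile lands exactly on it.
  The cap matters for developmental data: a trajectory that switches level
  at birth concentrates its information in a minority of samples, which a
  plain 9-MAD rule can silently discard, collapsing within-module
  correlations. Genes with zero MAD fall back to mean-centring (Pearson);
  zero-variance genes get correlation 0 with a warning.
* Both correlation kinds coexist because they serve different stages: bicor
  (robust) feeds module detection; Pearson feeds the significant-edge
  network and prioritisation adjacency. `PipelineParams.module_corr` /
  `network_corr` select them; defaults as above.
* Soft threshold: `a_ij = |corr_ij|^P`, default `P = 7`, unit diagonal. The
  scale-free fit of a candidate power bins the connectivities
  `k_i = Σ_{j≠i} a_ij` into 10 equal-width bins, regresses log10(bin
  frequency) on log10(bin mean k), and reports R² signed negative when the
  slope is positive. Equal-width bins are used because the regression needs
  the frequency to vary across bins; `soft_threshold_scan` tabulates powers
  1–12 so the choice of power can be inspected.
* TOM: `TOM_ij = (ℓ_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)`, computed dense
  (the intended scale, ≤ a few tens of thousands of genes, fits in memory;
  at 20k genes the dominant cost is one 20k × 20k matrix product).

### Module detection

* Average linkage on `1 − TOM` (scipy). The tree cut is a static-height cut
  (default 0.99 × the maximum merge height) with branches below
  `min_module_size = 30` left unassigned (label 0, the "grey" convention),
  followed by an optional PAM-like stage: an unassigned gene joins the
  module with the smallest mean dissimilarity provided that mean falls below
  the module's internal 0.9 dissimilarity quantile. This is an intentional,
  simpler approximation of the hybrid dynamic tree cut; it is deterministic,
  respects the minimum size by construction, and recovers planted partitions
  at ARI > 0.95 in the validation scenarios. Reproducing the hybrid
  algorithm label-for-label is a non-goal.
* Eigengenes: member genes are z-scored over samples; the module profile is
  the first right singular vector (unit norm), `variance_explained` the
  first squared singular value over the total. Sign is oriented so the
  profile correlates non-negatively with the module's mean standardised
  profile; an exact zero tie resolves to a positive first nonzero
  coordinate. A singleton module's eigengene is its own standardised
  profile.
* Merging: while any module pair has eigengene dissimilarity
  `1 − cor(E_a, E_b) < 0.2` (`merge_cut_height`), the closest pair is
  merged and eigengenes recomputed; iterating closest-pair-first guarantees
  that no surviving pair sits below the cut. Labels are finally reassigned
  1..K by decreasing size (ties by first gene position).

### Enrichment

* Module × gene-type tests: one-sided ("greater") Fisher's exact test on
  (in-module ∧ type, in-module ∧ ¬type; out-module ∧ type, out-module ∧
  ¬type) over all partitioned genes, unassigned genes included in the
  background. One-sided because only enrichment is reported; a two-sided
  alternative is a flag.
* FDR: Benjamini–Hochberg, applied per family — across modules within one
  gene type for the module tests, and across the whole structure × period ×
  type grid for the expressed-gene tests. Family scope is configurable.
  `−log10(FDR)` is reported with the FDR floored at 1e−300.
* Structure × period expressed-gene enrichment counts gene-sample pairs at
  ≥ 1 RPKM among a type set's genes and a cell's samples against the same
  counts over the whole gene group (default background: the module-group
  genes; the pooled pair counting can be switched to per-gene "expressed in
  ≥ 1 sample" with `pair_counting=False`). Cells whose structure has no
  samples in a period are omitted rather than reported as zeros.

### Topology and prioritisation

* Edges: the top `⌈0.05 × n(n−1)/2⌉` unique pairs by powered-Pearson
  adjacency; ties at the cut weight are all kept (deterministic, at the
  cost of occasionally exceeding the nominal count). Module subnetworks
  keep edges with both endpoints in the module and ≥ 1 lncRNA/ASD endpoint,
  classed as asd_asd / asd_lnc / lnc_lnc / other.
* ASD connectivity of lncRNA *g*: `Σ_{a ∈ ASD, a≠g} adj[g, a]`; the
  self-term is excluded when a gene is in both sets (it would add a
  guaranteed +1). Min-max normalisation runs over the lncRNAs analysed, so
  the top candidate scores exactly 1 and the bottom 0; if all scores tie the
  range is undefined and everything maps to 0 with a warning. Adjusted
  intramodular connectivity (within-module minus out-of-module adjacency
  sum) is normalised over **all** genes of the dataset. Ranks are dense on
  the normalised ASD connectivity, ties broken by gene id.

## Synthetic data generator

`generate_dataset` emulates the structure of a developmental brain
transcriptome at desk scale. Defaults (the reference scenario used by the
tests and the acceptance script): 5 modules × 100 genes, 50 noise genes, 60
samples split 20/20/20 over prenatal (8–37 pcw), childhood (4 mos–15 yrs)
and adulthood (18–40 yrs), four brain structures assigned round-robin,
loadings uniform in [0.8, 0.95], residual s.d. 0.3 on the log2 scale, 15%
lncRNAs, 40 ASD genes with 8-fold placement bias toward module 1 (lncRNAs
with 3-fold bias), and 5 hub lncRNAs in module 1 at loading 0.95.

* Gene model: `x_gs = baseline_g + loading_g · E_m(s) + ε`, baselines
  uniform in [2, 6] log2 units, eigengene trajectories standardised to unit
  variance. RPKM values are `2^x − 1` floored at 0 — the exact inverse of
  the curation transform, so the round trip is lossless.
* Trajectories: module 1 falls sigmoidally at 20% of the chronological axis
  (prenatal-high), module 2 rises at 80% (postnatal-high); later modules are
  random smooth cosine mixtures. Every trajectory after the first is
  residualised against its predecessors. The orthogonalisation is what keeps
  an *unsigned* network able to separate modules (a rising mirror image of
  the falling trajectory would be indistinguishable after |corr|) and gives
  all modules comparable covariance sums, so the low-information screen
  treats them symmetrically.
* Noise genes: i.i.d. per-sample jitter (s.d. 0.05) around a constant
  baseline — a true negative class for the covariance screen.
* What it does **not** emulate: empirical RPKM distributions (library-size
  artefacts, length biases), overlapping or hierarchical modules, signed
  regulatory relationships (all loadings are positive), structure-specific
  expression differences (trajectories depend on age only), or realistic
  gene counts. Passing the recovery tests therefore demonstrates the
  correctness and internal consistency of the pipeline machinery on data
  matching its assumptions — not performance on a real transcriptome, where
  module boundaries are far fuzzier.

## Problem sizes and determinism

The validation scenarios use 350–550 genes and 60 samples, where the full
pipeline runs in about half a second; the 20-replicate hub-recovery
experiment completes in a few seconds. All randomness flows from explicit
seeds (the generator's `SimConfig.seed`, the 2-means `seed`); a fitted
pipeline rerun with the same inputs and seed writes byte-identical outputs.

## Known limitations

* The tree cut is a static-cut + PAM approximation of the hybrid dynamic
  algorithm; on dendrograms with strongly nested module structure it can
  split or lump branches differently.
* Dense TOM memory is quadratic in genes; beyond ~30k genes a block-wise
  path would be needed.
* The structure × period enrichment treats gene-sample pairs as independent
  draws in the Fisher test; pairs sharing a gene are correlated, so its
  p-values are optimistic and should be read comparatively, not literally.
* Biotype handling reduces to a binary lncRNA flag (antisense/lincRNA
  against the rest); finer biotype classes are carried through but not
  tested separately.
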