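# Methods

`txdemux` separates the cells of two genetically distinct individuals in a
droplet scRNA-seq sample — the canonical case being transplant donor and
recipient — using only the allele fractions of expressed SNVs, without any
matched germline genotypes. This note describes the model, the free
parameters, the synthetic-data generator, and the numerical choices, in
enough detail to reproduce or critique any result the package computes.

## The observation model

The input is a pair of sparse integer matrices over (SNV site, cell
barcode): alt-allele read count `a[s,c]` and total read count `n[s,c]`.
A cell's *minor allele fraction* (mAF) at a covered site is
`a[s,c] / n[s,c]`; a site with `n = 0` is *uncovered* in that cell and
carries no information (it is never treated as an observed zero).

Each genotype class g ∈ {GT1, GT2, doublet} is summarized by a per-site
allele-fraction profile `p_g[s] ∈ [0,1]`. Conditional on its class, a
cell's alt count at a covered site is modeled Binomial(`n[s,c]`,
`p_g[s]`), independent across sites. Log-likelihoods omit the binomial
coefficient (constant across classes) and clamp `p` to
`[1e-3, 1 - 1e-3]` before taking logs, so no single contaminating read
can contribute an unbounded penalty — this clamp, together with the
unassigned margin, is what stands in for an explicit ambient-RNA model
(ambient contamination is additionally *absorbed*: profiles are estimated
from the contaminated cells themselves, so a genotype's profile drifts
with its cells and classification stays centred).

Genotype profiles are posterior means under a Beta(κ, κ) prior with
pseudocount κ = 1: `p = (Σa + κ) / (Σn + 2κ)`, the sums running over the
cells currently assigned to the class. The doublet profile is derived,
never estimated: a droplet holding one cell of each genotype draws reads
from both in proportion to what a *single* cell of each contributes, so

    p_dbl[s] = (d1[s] p_1[s] + d2[s] p_2[s]) / (d1[s] + d2[s]),

where `d_g[s]` is genotype g's mean per-cell depth at site s (support /
number of cells). Weighting by aggregate group support instead would let
a 900:100 mixture produce a 9:1 "doublet" profile nearly identical to the
dominant genotype, which destroys both doublet detection and the
assignment margins of dominant-genotype cells.

## Stage 1 — discovery by community clustering

Cells covering at least `min_snvs_per_cell` (default 25) sites are
*eligible* for discovery. The pairwise distance between two eligible
cells is the mean absolute mAF difference over sites covered in **both**
(undefined below `min_shared_sites = 5` shared sites). A k-nearest-
neighbour graph (k = 10, undirected union of neighbourhoods) is clustered
with Leiden modularity maximization at a fixed seed. The resulting
communities are agglomerated pairwise by closest centroid-mAF distance
until exactly two super-groups remain; the pair is accepted as two
genotypes only if the centroid distance between them exceeds the
separation floor (mean |Δ mAF| > 0.1 over shared sites). Splits of a
single genotype sit far below the floor (they differ only by sampling
noise), while two diploid individuals differ at roughly half of
informative SNV sites and land far above it. We deliberately do not use
a merge threshold derived from the distribution of inter-community
distances (e.g. its median): when each genotype fragments into several
communities, cross-genotype distances dominate that distribution and the
two true genotype groups can fall under the threshold and be merged —
the failure is silent and catastrophic on balanced mixtures.

## Stage 2 — rescue of a rare second genotype

A minority of a few dozen cells among thousands often cannot form its
own community. When stage 1 finds a single group, every eligible cell is
scored against the *dominant* profile (estimated from all eligible
cells) with a **genotype score**: the per-read mean binomial
log-likelihood, i.e. the summed log-likelihood divided by the cell's
total read count. Per-read normalization makes deep and shallow cells
comparable; the score lives in `[log(1e-3), 0]`. Cells scoring below
`median − 5 × 1.4826 × MAD` are flagged (MAD scaled for normal
consistency; if MAD = 0 no cell is flagged). The flagged set is accepted
as a second genotype only if its pooled raw allele-fraction profile
differs from the dominant one by mean |Δ mAF| above the same separation
floor — a guard against flagging mere low-quality outliers. If both
stages fail, the sample is reported single-genotype
(`second_genotype_found = False`) and every covered cell is labeled GT1.

## Iterative refinement with doublet simulation

Starting from the two-group seed, the algorithm alternates:

1. estimate `p_1`, `p_2` from the current GT1/GT2 **singlet**
   assignments (eligible cells only) and derive `p_dbl`;
2. simulate synthetic doublets — one per observed cell — by summing the
   alt/total counts of a uniformly drawn GT1 cell and a uniformly drawn
   GT2 cell, and set the doublet acceptance threshold at the 5th
   percentile of the synthetic doublets' *per-read* doublet
   log-likelihood (per-read, because a doublet carries roughly twice a
   singlet's reads and a raw-sum threshold would gate nothing);
3. classify **every** cell (discovery-ineligible ones included) by
   arg-max log-likelihood over the three profiles; a cell is downgraded
   to `unassigned` when the top-versus-runner-up margin is below
   `assign_margin` (2.0 nats) or it covers no site; a doublet call must
   additionally clear the calibration threshold, otherwise the cell
   falls back to the better singlet (margin re-checked between the two
   singlets only).

Iteration stops at a label fixed point or after `max_iter = 50` sweeps.
The synthetic-parent draw uses a fixed seed across iterations so the
gate depends only on the current model — otherwise the fixed point can
never be reached. Hard assignment with a derived (non-optimized) doublet
profile is not an exact coordinate ascent, so the total hard-assignment
log-likelihood Σ_c max_g ℓ_g(c) is monotone only up to a small wobble
(observed < 1e-4 relative); a few borderline cells can also flip in a
period-2 limit cycle at high contamination, which is detected and broken
by keeping the cycle state with the highest total log-likelihood
(`converged` is then honestly reported `False`). If either genotype
group empties during refinement the sample falls back to the
single-genotype result with a warning.

## SNV pre-filter

Before demultiplexing (and before export to other demultiplexers), sites
are dropped when (a) their mean mAF across covered cells exceeds 0.999 —
homozygous alt in effectively every cell, hence uninformative; (b) fewer
than 10 cells are covered; or (c) fewer than 5 cells carry an alt read.
Zero-coverage cells are excluded from the mean, otherwise the 0.999
threshold would be unreachable. The filter is idempotent and applied
uniformly by default (a flag disables it).

## The synthetic-data generator

The simulator emulates a transplant-style mixture with known truth:

* **Genotypes.** Population allele frequencies are Beta(0.8, 0.8)
  truncated to [0.05, 0.95]; two diploid individuals are drawn under
  Hardy–Weinberg (copy number Binomial(2, p)). True allele fractions
  per copy number are ε, 0.5, 1−ε with sequencing error ε = 0.005.
  A fraction (5%) of sites is forced genotype-identical with inflated
  error (0.05): "false positive" SNV calls, which add noise but no
  signal — sparse single-cell variant calling produces many of these.
* **Coverage.** Each site gets a relative expression weight from a
  symmetric Dirichlet (concentration 0.3); each cell receives
  Poisson(250) molecules allocated multinomially over sites, and alt
  reads are Binomial at the genotype's true allele fraction. The skew
  matters: it concentrates depth on a core of hot sites (as
  mitochondrial transcripts do in real droplet data), which is what
  makes pairwise mAF distances well-defined — under uniform coverage two
  random cells would share almost no sites on a realistic panel.
* **Doublets.** `round_half_even(0.10 × minor population)` doublets per
  sample (exact rational arithmetic: 0.1 × 25 → 2), each the elementwise
  count sum of one dedicated GT1 parent and one dedicated GT2 parent;
  parents are extra draws that never appear as singlet barcodes.
* **Ambient RNA.** Every collapsed molecule (each read unit of each
  (site, cell) count) is independently swapped, with the configured
  probability, to a uniformly drawn *different* barcode. A molecule
  moves wholesale — its tags never split across cells — and the total
  molecule count is conserved exactly. Truth labels do not change.
* **The grid.** 3 replicates × 12 minor-population sizes (25–2,000 of
  4,000 singlets) × 5 ambient rates (0–40%) = 180 samples by default;
  the singlet mixture of a (replicate, minor count) cell is shared
  across its five ambient rates, and one genotype pair (the same two
  individuals) underlies the whole grid. Per-sample seeds derive
  deterministically from the master seed; identical config + seed gives
  byte-identical output.

What the generator does **not** model: cell types and their expression
differences (so doublets of unequal-size cells, which the real problem's
hardest doublets are, do not occur — doublet detection here is easier
than on tissue data); genotype-specific expression; UMI errors; index
hopping. Passing benchmarks on these simulations therefore demonstrates
the genotype-separation machinery, not robustness to every artifact of
real droplet chemistry.

## Benchmarking conventions

Predicted GT1/GT2 are matched to truth by the label permutation
maximizing singlet agreement (ties keep identity; doublet/unassigned are
never permuted). TPR = TP/(TP+FN) and FDR = FP/(TP+FP) are one-vs-rest
per class; an `unassigned` prediction counts as a false negative for the
cell's true class and never as a false positive; undefined ratios are
NA, never 0. Aggregates are stratified by minor count > 100 versus
≤ 100 (boundary inclusive on the low side), reported as mean ± sample
SD over grid cells. The adjusted Rand index uses the standard
pair-counting form (via scikit-learn, cross-checked in the test suite
against an independent closed-form implementation on all partitions of
up to six items).

## Problem sizes used for the shipped benchmarks

The acceptance script and the end-to-end tests run the grid at 1,000
singlets × 500 sites per sample with minor counts 25–500 — a
proportional scale-down that keeps every minor-count:total ratio and
both aggregation strata intact while a full grid evaluation stays under
ten minutes on one CPU. Minor counts 750/1,000/2,000 would exceed half
of the scaled total and are not materialized at this scale. Tolerances
on reproduced rates are 0.05 absolute, the appropriate width for a
stochastic, scaled-down replication of quantities in [0, 1].

## Known limitations

* Exactly two genotypes; no multiplexed-pool (k > 2) mode.
* No ambient-fraction estimate is produced; robustness degrades
  gracefully up to ~40% contamination but minority-cell recall at the
  extreme corner (tiny minority + 40% ambient) can dip a few percent,
  the cells landing in `unassigned` rather than the wrong genotype.
* Doublet detection is weaker than singlet assignment (as for all
  SNV-only methods); expression-based doublet callers are complementary.
* Which genotype is donor and which recipient is left to the user —
  the labels are arbitrary.
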