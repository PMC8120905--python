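# Methods

## Pipeline overview

Input is one expression matrix per batch (cells × genes; raw counts or
log-normalized) plus a labeled reference for the classifier. The stages:

1. **Normalization.** Counts are library-size normalized and
   log-transformed: `x_ij = ln(1 + s · c_ij / Σ_j c_ij)` with scale factor
   s = 10 000. Cells with zero total count are rejected by name.
2. **Feature panel.** Highly variable genes are ranked by log-normalized
   variance within each batch; per-batch ranks are summed over batches and
   the best `n_hvg` genes present in all batches are kept (default 3000;
   ties broken by gene id, so selection is deterministic and nested in
   `n_hvg`). A mean-binned normalized-dispersion ranking is also provided —
   it is the flavour used by the HVG-conservation metric.
3. **Scaling.** Each gene is z-scored with the population (ddof = 0)
   standard deviation *within its batch*; constant genes map to zero
   columns. Per-batch scaling keeps batch location/scale differences out of
   the embedding that anchors are found in.
4. **Annotation.** A multinomial centroid classifier (below) assigns each
   cell a type or `unknown`.
5. **Anchors.** For each pair of batches, cells are embedded in a shared
   canonical space; within every shared type, mutual k-nearest neighbors
   are computed in the scaled gene space and in the canonical space and
   intersected.
6. **Correction.** Each non-reference cell receives a Gaussian-weighted
   mean of same-type anchor difference vectors, applied additively in the
   log-normalized gene space. Output is the merged corrected matrix.

## Classifier

Informative genes maximize the entropy-reduction statistic on
pseudocounted per-type means m_t(g):

    score(g) = Σ_t m_t log m_t − (Σ_t m_t) · log(mean_t m_t)

which is non-negative by convexity, zero when all types express the gene
equally and large for genes concentrated in few types. Type centroids are
per-type means over the top `n_genes` (default 500) informative genes plus
a pseudocount of 1e-6, renormalized onto the probability simplex. A query
cell x is scored by L_t = Σ_g x_g log c_t(g); posteriors are the softmax of
L/T.

**Temperature calibration.** The raw softmax of likelihood sums over
hundreds of genes is numerically saturated: posteriors are ≈ 1 for almost
every cell, including cells of types absent from the reference, so a fixed
0.8 gate rejects almost nothing. The temperature T is therefore fit on a
held-out fifth of the reference (stratified by type, selected in cell-id
order so training is invariant to input order): T maps the 1st-percentile
held-out best-vs-second log-likelihood margin onto a posterior of exactly
0.8 in the worst case, T = q₀.₀₁ / ln((K−1)·0.8/0.2). In-reference cells
then clear the gate at roughly the 99% level while out-of-reference cells
— whose margins are an order of magnitude smaller — fall below it.
References too small to split (fewer than ~3 cells per type after the
holdout) fall back to T = 1, which preserves the exact closed-form
behavior on degenerate inputs (tied centroids → posterior 0.5 → unknown).

A type counts as *present* in a batch when at least `min_cells = 10` cells
carry it confidently; the shared set of a batch pair is the intersection
of presences, and `unknown` is never shared.

## Canonical embedding and anchors

For a batch pair with scaled matrices X₁ (n₁ × g) and X₂ (n₂ × g) on the
same HVG panel, the top-d SVD of the cross-product K = X₁X₂ᵀ is taken
(d = 20 by default). Batch-1 cells receive the left singular vectors,
batch-2 cells the right ones; each row is L2-normalized. Column signs are
fixed (largest-magnitude entry of each left vector positive) so repeated
runs are bitwise identical. This diagonal-CCA construction captures the
correlated (shared) signal between the batches while per-batch z-scoring
has already removed gene-wise location differences.

Mutual nearest neighbors use exact search (scikit-learn brute-force
backend) with Euclidean distance; a pair is kept only if it is mutual in
*both* the scaled gene space and the canonical space, and only within a
shared type. `k = 20` follows the classical mutual-nearest-neighbors
correction default: the per-type correction is a weighted mean of anchor
difference vectors whose variance scales as 1/n_anchors, and a small k
starves low-abundance types of anchors, leaving their corrections
noise-dominated. No approximate-search mode is provided; all search is
exact.

Anchor difference vectors are stored reference-minus-other on the
log-normalized HVG panel, so corrections add toward the reference.

## Correction field

For a cell x of shared type t, weights over that type's anchors are
w_a ∝ exp(−d(x, a)²/2σ²), where d is the **per-gene RMS distance**
(Euclidean / √n_genes) from the cell to the anchor's endpoint in the
cell's own batch, in scaled space. The RMS convention makes σ
dimension-free: raw Euclidean distances in a z-scored panel grow as
√n_genes, and any fixed bandwidth would otherwise underflow on every
realistic panel. Default σ = 1.0, i.e. the kernel's reach is one z-score
unit per gene. At most `k_weight = 100` nearest anchors enter a cell's
correction; if all weights underflow the kernel falls back to uniform
weights over those nearest anchors.

`unknown` cells are corrected by the `k_weight` nearest anchors regardless
of type. Cells of a predicted type with no same-type anchors are corrected
the same way when no donor batch exists (below); `correction_vectors`
itself, called directly, gives such cells a zero vector with a warning.

## Multi-batch topology and order invariance

Batches are merged in a star: a reference batch is chosen (`auto` = most
cells among the batches with the most predicted types, ties by batch id)
and every other batch is corrected against it independently. Types present
in a batch but not anchorable against the reference are corrected in a
second pass against the lowest-id other batch containing the type — whose
own correction has already aligned it with the reference — through
type-constrained anchors whose diffs are taken from the donor's corrected
values. All per-batch processing happens in sorted batch-id order and the
output rows are ordered by batch id, so the merged matrix is bitwise
invariant to the order batches are passed in. Reference-batch cells are
never modified. A batch with no shared types and no donor passes through
uncorrected with a prominent warning.

## Metrics

* **ARI** — scikit-learn's pair-counting implementation (tested against a
  brute-force contingency oracle).
* **ASW** — mean silhouette over all cells on batch or type labels;
  singleton labels contribute 0.
* **LISI** — per cell, Gaussian neighbor probabilities with the bandwidth
  bisected until the distribution's perplexity matches the target
  (default 30, |log₂ error| < 1e-5) over the 3×perplexity nearest
  neighbors; category probabilities are aggregated and inverted
  (1/Σp_c²). Reported as the median. Note an intrinsic ceiling: at
  Shannon-perplexity P the Gaussian weights have Rényi-2 diversity below
  P, so even perfectly mixed two-batch data scores about 2 − 2/(0.78·P),
  ≈ 1.91 at the default perplexity; limit checks therefore use a wider
  neighborhood (perplexity 100 → ≈ 1.98).
* **KBET** — for neighborhood fractions {5, 10, 15, 20, 25}% of n, each
  cell's k0-neighborhood batch counts are compared to global frequencies
  with a Pearson χ² test (dof = batches − 1, asymptotic p-values); the
  rejection rate at α = 0.05 is reported per fraction and summarized by
  the median. The statistic includes a finite-population correction
  (n−1)/(n−k0): neighborhoods are without-replacement draws, their counts
  have hypergeometric variance, and the uncorrected test is conservative
  at 25% neighborhoods (measured null rejection 0.029 vs 0.0485
  corrected at α = 0.05). All cells are tested (no subsampling).
* **Isolated-label score** — isolated labels are those present in the
  fewest batches. F1 part: best one-cluster-vs-label F1 over Leiden
  partitions of a 15-NN graph across resolutions 0.1–2.0 (step 0.1).
  ASW part: mean silhouette of the label-vs-rest binary split, rescaled by
  (s+1)/2. Final score: mean of both parts, averaged over isolated labels.
* **HVG conservation** — per batch, the top-500 dispersion-flavour HVGs
  (or half the batch's genes if fewer than 500 remain) before and after
  integration, compared by the overlap coefficient |X∩Y|/min(|X|,|Y|);
  the mean over batches is reported, or absent when the integrated object
  has no gene space. The dispersion ranking (variance/mean of de-logged
  expression, standardized within 20 mean-quantile bins) is implemented
  in-package because the common cell-ranger-flavour implementation fails
  on the small inputs this package must handle; a test cross-checks rank
  agreement with scanpy on a larger fixture.
* **Cell-cycle conservation** — S and G2M scores per cell (mean expression
  of the gene set minus a size-matched background drawn from 25
  expression bins, 50 background genes per target, seeded), computed on
  the pre-integration data; the score is
  max(0, 1 − |var_after − var_before|/var_before) of the variance the two
  scores explain linearly, averaged over batches.

Metrics that need an embedding default to a 20-component PCA of the
corrected matrix.

## Simulator

Counts are negative-binomial with dispersion 0.1: gene means are
exp(type program + batch shift), multiplied by a per-cell log-normal
library factor (σ = 0.3), with Bernoulli dropout (rate 0.2). Each type's
program is a shared N(0, 0.5²) baseline with a block of 50 exclusive
marker genes boosted by +2 log units; "similar" type pairs share 80% of
their markers. Batch shifts have magnitude ‖δ‖ (default 6 log units)
split between a random direction orthogonalized against the span of the
centered type programs and a **type-dependent** component along the axis
between two designated types — each of the two types moves toward the
other's program. The mixing weight q = `non_orthogonality` ∈ [0, 1] is the
dial: q = 0 gives a biology-orthogonal effect identical for all types (and
exactly removable by per-batch centering); large q swaps the types'
apparent positions across batches, the regime where unconstrained mutual
neighbors pair wrong types. The type-dependence is essential: a
type-*independent* shift, however oriented, is removed exactly by
per-batch gene centering and can never produce cross-type anchors.

Named scenarios fix all parameters and seeds: a three-batch / eight-type
partial-presence design (one type in all batches, three in two, four
batch-exclusive); a similar-types scenario (four types in two pairs with
80% shared markers; 400 markers per type over 5000 genes, so that an HVG
sweep from 500 to all genes varies the feature panel rather than the
amount of information available — with the 50-marker default, large
panels would bury the 20 discriminating genes in noise for any method);
an unbalanced scenario (1:9 vs 5:5 type ratios); a non-orthogonal
scenario (q = 0.8, shift magnitude comparable to the between-type
distance); a null scenario (identical distributions); and a three-batch
order-invariance scenario. Scenario generation also produces a shift-free
labeled reference batch drawn from the same type programs for classifier
training.

A separate Gaussian fixture (`simulate_lognorm_shift`) plants an exact
additive per-type shift δ directly in log-normalized space (per-gene
sd 0.5, somewhat above the within-type noise sd 0.3 — the regime where a
batch effect visibly displaces clusters); it exists because a shift pushed
through counts, dropout and per-cell normalization no longer has a
well-defined "true" value in the space corrections live in. Values are
deliberately not clipped at zero: truncation attenuates the effective
shift on low-expression genes and would bias recovery measurements.

**What the simulator does not emulate:** platform-specific chemistry (UMI
vs full-length), gene–gene correlation beyond the type programs, ambient
RNA, doublets, or expression-dependent dropout. Passing tests on this
generator demonstrate the mechanics of the method — anchor purity, order
invariance, calibration, shift recovery — not performance on any real
tissue.

## Numerical conventions

* All generators and fits are pure functions of their seeds; SVD sign and
  tie-breaks are fixed, so end-to-end runs are bitwise reproducible.
* Ties in gene rankings break lexicographically by gene id.
* Per-type means are summed in cell-id order, making trained models
  bitwise invariant to cell order.
* χ² p-values are asymptotic; silhouette of singleton clusters is 0;
  LISI of a single category is exactly 1.
* Degenerate inputs (rank-deficient cross-products, constant genes,
  empty anchor sets, types with no anchors) reduce dimension or fall back
  with warnings rather than failing, except where an invariant is
  violated (NaNs, duplicate ids, zero-count cells), which raise.

## Known limitations

* Correction quality degrades when a shared type has very few cells
  (anchor variance); the k = 20 default mitigates but cannot eliminate
  this.
* The classifier's unknown gate assumes the reference and query share the
  informative-gene expression scale (both log-normalized); gross platform
  differences in capture efficiency shift likelihood margins.
* The star topology makes order invariance exact but funnels all
  alignment through one reference; a reference missing many types leans
  on the donor-batch second pass, which chains two corrections and their
  noise.
* KBET and iLISI penalize datasets with batch-exclusive populations even
  under perfect integration; they should be read jointly with the
  biology-conservation metrics.
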