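# Methods

## Model

`spenhance` predicts unmeasured gene expression for spatial
transcriptomic cells from an scRNA-seq reference of matching tissue.
The model assumes the two datasets share cell populations and that a
cell's position in a joint expression space — not its identity, which
is unmatched across datasets — determines which reference cells are
informative about it.

**Preprocessing.** Reference genes detected in fewer than 10 cells are
removed. Each spatial cell is normalized by its total count scaled by
the median total over spatial cells; each reference cell by counts per
million (the scale factor is configurable); both are log1p-transformed
with pseudo-count 1 and natural logarithm. No z-scoring is applied.
The reference-unique gene set *U* is the top 2000 genes (configurable)
outside the spatial panel ranked by binned normalized dispersion:
per-gene dispersion (variance/mean of normalized values) z-scored
within 20 equal-frequency mean bins, ties broken by lexicographic gene
name so selection is deterministic. *U* is selected once globally, not
per cross-validation fold — fold splitting concerns the shared genes
only.

**Joint embedding.** A two-layer auto-encoder (input `N_S + N_U` →
latent 1000 → input, ReLU on both layers) is trained on the merged
matrix of zero-padded spatial cells and reference cells, shuffled by a
seeded permutation. Each batch is fed forward twice. The first pass
scores the spatial rows' reconstruction of the shared genes,
`l1 = Σ SE(E_S, Ê_S)`. The second pass masks the reference rows' *U*
entries to zero and scores the decoded *U* entries against the unmasked
values, each squared error at a zero entry of the target multiplied by
*Q*, the non-zero fraction of the reference submatrix over *S ∪ U*
(computed over this submatrix because those are the only genes the
model sees). The total is `l1 + α·l2` with
`α = (N_S·M_T)/(N_U·M_R)` using per-batch cell counts; a batch lacking
one origin drops the corresponding term (a batch with no spatial cells
has α = 0). Because the decoder also passes through the rectifier,
reconstructions are non-negative like the log-normalized inputs.

**Optimization.** Adam with learning rate 1e-3, no weight decay, batch
size 512, a fixed budget of 100 epochs (all configurable); weights are
initialized uniform fan-in, `U(±1/√fan_in)`, from a seeded generator,
and all training arithmetic is float32. A fixed epoch budget stands in
for "train until convergence": snapshot ensembling makes the precise
stopping point non-critical. The per-epoch loss used to rank snapshots
is the mean of batch total losses; the five lowest-loss epochs'
parameter sets are retained.

**Prediction.** Per snapshot, spatial cells (zero-padded over *U*) and
reference cells (full profile) are embedded by the encoder; for each
spatial cell the 50 nearest reference cells by cosine distance are
taken (ties break toward the lower reference index), neighbors with
non-positive cosine similarity are removed, and weights
`w_ik = (1 − d_ik/Σd)/(K−1)` over the K retained neighbors form the
prediction as a convex combination of reference expression. This
weight formula is the unique normalization of one-minus-relative-
distance whose weights sum to one. Degenerate cases: K=1 gives weight
1; all-equal distances give exactly 1/K (explicit branch, since the
formula evaluated in floating point differs in the last ulp); if all
50 candidates have non-positive similarity the candidates are kept
with uniform weights, preserving the convexity contract rather than
predicting zeros. A zero-norm embedding is assigned similarity 0.
Predictions are averaged over snapshots and live on the reference
normalized-log scale; no back-transform is applied.

**Cross-validation.** The shared genes are split into 5 folds by a
seeded permutation cut into contiguous chunks, larger folds first
(33 genes → 7/7/7/6/6). Each fold is removed from the spatial matrix,
a model is trained on the remaining shared genes plus *U*, and the
held-out genes are predicted, so every shared gene is predicted exactly
once by a model that never saw its spatial measurements.

## Evaluation protocol

Gene-wise (per gene, over cells) and cell-wise (per cell, over genes)
Spearman correlations use average ranks for ties; a constant vector
yields an undefined coefficient, reported as missing and excluded from
medians. Clustering uses PCA to at most 50 components (exact SVD), a
15-nearest-neighbor graph in PC space, and Louvain community detection
with the resolution parameter binary-searched on [0.01, 10] (the upper
bracket doubles up to 100 if it yields too few clusters, at most 50
bisection steps) for the partition whose cluster count is closest to
the number of ground-truth labels, preferring fewer clusters on ties.
Predicted and measured matrices are clustered by the identical pipeline
and seed. ARI, NMI (geometric-mean normalization, the standard reading
that keeps the score in [0,1]), AMI (arithmetic-mean normalizer, exact
hypergeometric expected mutual information) and homogeneity are
delegated to scikit-learn behind this module's surface; the test suite
checks them against independent brute-force contingency-table
implementations. AMI is the headline metric: population sizes in
spatial data are typically unbalanced, where ARI is less appropriate.

## Synthetic data

The generator emulates a paired dataset with shared populations: for
each population and gene a mean count is drawn log-normal (location
2.0, scale 1.0 on the log scale), cells draw negative-binomial counts
(dispersion 2.0) around their population's means, and each entry is
independently zeroed by Bernoulli dropout — 0.6 for the spatial matrix
and 0.8 for the reference by default, matching the sparsity range of
published imaging/scRNA-seq dataset pairs. The per-entry dropout
probability is not uniform: it falls with the underlying mean on a
logistic curve whose midpoint is calibrated by bisection so the *mean*
probability equals the nominal rate. This mirrors real data, where
sparsity concentrates in weakly expressed genes while strong markers
are reliably detected; uniform entry-dropout at these rates would
destroy the population signal in a 30-gene panel outright, which real
data of the same sparsity demonstrably does not. Population proportions
halve from one population to the next (one dominant population), and a
cell emptied entirely by dropout has its strongest pre-dropout entry
restored, since a measured cell always carries some signal. The
noise-free population log-means are retained as the oracle for
parameter-recovery tests.

What the generator does not emulate: batch effects between the pair,
spatial coordinates, gene-gene correlation beyond population structure,
and library-size variation beyond the count noise. Passing tests
therefore demonstrate correct mechanics and recoverability under the
model's own assumptions, not performance on real tissue.

## Problem sizes and numerical choices

The recovery experiments in the test suite and the worked example run
the generator's default conditions (3 populations, 300 spatial × 30
genes, 500 reference × 3030 genes) with a training budget of 30 epochs
and batch size 256 — the loss plateau on data of this size is reached
well before the default 100-epoch budget intended for real datasets.
Determinism: a single seed drives simulation, merge shuffling, weight
initialization and batch order; Louvain uses an explicitly seeded
generator; repeated runs are byte-identical on the same machine.

## Known limitations

Predictions are convex combinations of reference profiles, so genes
expressed in the tissue but absent from the reference cannot be
predicted, and predictions never exceed the range observed in the
reference neighbors. The α balance uses per-batch cell counts, so a
batch containing only reference cells contributes no gradient (α = 0);
with shuffled merging such batches are rare. The embedding is trained
on both origins but no explicit batch-effect correction is performed —
the method relies on the shared genes to anchor the two datasets, and
a reference from poorly matched tissue will degrade neighbors silently.
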