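# spenhance

Reference-based enhancement of spatial transcriptomics.

Imaging-based spatial transcriptomics (osmFISH-, MERFISH-, STARmap-style
assays) measures a targeted panel of genes — tens to around a thousand —
in cells that keep their position in the tissue, and trades panel size
against detection sensitivity. Dissociated scRNA-seq from the same
tissue measures the whole transcriptome but loses position. `spenhance`
transfers the reference's genome-wide expression onto the spatial cells:
it predicts the expression of genes the spatial assay never measured and
re-imputes the ones it did, so that downstream analyses (cell-population
identification in particular) work on a richer, denser matrix.

It is a tool for computational biologists with a paired dataset: a
spatial gene-by-cell count matrix and an scRNA-seq gene-by-cell count
matrix from matching or similar tissue, unmatched cells.

## Method

Let *S* be the genes shared by the two datasets and *U* the top 2000
highly variable genes found only in the reference. After per-cell
normalization (median-total scaling for the spatial data, counts per
million for the reference, both log1p-transformed), spatial cells are
zero-padded over *U* and stacked with the reference cells into one
matrix over *S ∪ U*.

A two-layer auto-encoder (fully connected encoder to a 1000-dimensional
latent space, fully connected decoder back, ReLU on both layers) is
trained on this matrix with a two-part loss. Each batch is fed forward
twice:

* **l₁** — squared-error reconstruction of the *S* entries of the
  spatial cells;
* **l₂** — squared error of the decoded *U* entries of the reference
  cells after masking their *U* input to zero, with each error at a
  zero entry of the target down-weighted by *Q*, the non-zero fraction
  of the reference data — the sparser the reference, the more likely a
  zero is a dropout rather than true absence.

The total loss is `l1 + α·l2` with `α = (N_S·M_T)/(N_U·M_R)` (gene- and
cell-count ratios), which equalizes the per-element contribution of the
two parts. The five epochs with minimal training loss are retained as
snapshots.

For each snapshot, every spatial cell is embedded alongside the
reference cells, its 50 nearest reference cells by cosine distance are
found, neighbors with non-positive cosine similarity are dropped, and
the remaining K neighbors are combined with weights

    w_ik = (1 − d_ik / Σ_k d_ik) / (K − 1),

which sum to one, so the prediction `Y_i = Σ_k w_ik X_k` is a convex
combination of the neighbors' reference expression. Predictions are
averaged over the snapshots.

Evaluation follows two axes: gene-wise and cell-wise Spearman
correlation between predicted and measured expression, and a
clustering-based protocol — PCA, k-nearest-neighbor graph, Louvain
community detection with the resolution binary-searched until the
cluster count matches the number of ground-truth populations — scored
with AMI, ARI, NMI and homogeneity against the labels, with the
measured matrix clustered by the identical pipeline as the baseline.
A gene-split 5-fold cross-validation (train on four folds of *S* plus
*U*, predict the held-out fold) yields a prediction for every shared
gene and doubles as a data-enhancement strategy.

A synthetic-data module generates paired datasets with known population
structure (negative-binomial counts around log-normal population×gene
means, expression-dependent dropout, unbalanced populations), so the
full pipeline is testable without downloads.

## Worked example

Simulate a paired dataset (3 populations, 300 spatial cells × 30 genes,
500 reference cells × 3030 genes, 60% spatial / 80% reference dropout),
run gene-split cross-validation, and score the enhanced matrix:

```sh
spenhance simulate --out demo --seed 0
spenhance cv --spatial demo/spatial_counts.tsv \
             --reference demo/reference_counts.tsv \
             --out demo/cv --epochs 30 --batch-size 256 --seed 0
spenhance eval --pred demo/cv/predictions.tsv \
               --measured demo/spatial_counts.tsv \
               --labels demo/labels_spatial.tsv \
               --out demo/eval --seed 0
```

The eval command prints:

```json
{
  "median_gene_spearman": 0.23252620303653593,
  "median_cell_spearman": 0.42691445018845076,
  "n_genes_undefined": 0,
  "n_cells_undefined": 0,
  "predicted": {
    "ami": 0.8474428205097383,
    "ari": 0.9252911658262624,
    "nmi": 0.8485912678118662,
    "homo": 0.8511484010779157
  },
  "measured": {
    "ami": 0.810550205599056,
    "ari": 0.8762649215842498,
    "nmi": 0.8120634965055507,
    "homo": 0.8258069511740361
  }
}
```

The Spearman medians compare the cross-validated predictions with the
*measured* (dropout-corrupted) spatial matrix, so they are bounded by
the noise of the measurement itself; against the noise-free simulated
ground truth the median gene-wise correlation is 0.68. The clustering
block is the point of the exercise: clustering the enhanced matrix
identifies the simulated populations better than clustering the sparse
measured matrix (AMI 0.847 vs 0.811), i.e. the enhancement recovered
population structure that dropout had obscured.

`spenhance enhance` trains on all shared genes and predicts any
requested gene list (default: all reference-unique HVGs); every command
writes a `manifest.json` (configuration, seeds, input hashes) that makes
the run byte-for-byte reproducible.

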