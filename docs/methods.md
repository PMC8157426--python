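# Methods

## Model

`contraclust` learns a per-cell representation of an scRNA-seq count matrix
`D ∈ R^{n×d}` (n cells, d genes) with a self-supervised contrastive
objective, then clusters that representation. The two phases are fully
decoupled: any clustering algorithm can consume the embedding, and the
embedding never sees cluster assignments during training.

The method's central assumption is that a cell's identity is recoverable
from a small random subset of its genes. Each training step therefore
builds two *views* of every cell in the mini-batch by independently zeroing
each entry with probability p (default 0.9) and rescaling survivors by
1/(1−p) so the view is unbiased in expectation (inverted-dropout
semantics). Heavy masking acts like aggressive image cropping: it forces
the encoder to attend to individual genes rather than the joint profile,
which simultaneously confers robustness to biological dropout — false
zeros are just another mask — without any explicit imputation or count
model (no NB/ZINB likelihood).

### Contrastive loss

Views are arranged as consecutive positive pairs (rows 2k, 2k+1 of the
2N-row batch). With cosine similarity and temperature τ:

    ℓ(i, j) = −log [ exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ]

The loss is the mean of ℓ over all 2N ordered positive pairs. Softmax
terms are evaluated with max-subtraction (logsumexp), so the loss is
finite for any τ ≥ 0.01. Embeddings are L2-normalised *inside* the loss
only; the stored embedding is the raw representation-layer output, since
clustering operates on it directly. The loss and its analytic gradient
(through the similarity matrix and the row normalisation) are unit-checked
against an independent brute-force double-loop implementation and against
finite differences.

Degenerate cases: a single pair (N=1) has loss exactly 0 (the denominator
equals the numerator); a zero-norm embedding row is a validation error.

### Encoder and optimisation

The encoder is a stack of affine layers, default widths `[200, 40, 60]`
on a 500-gene input, with batch normalisation and ReLU after every hidden
layer but not after the final (representation) layer. The batch-norm
scale/shift vectors contribute 2×(200+40) = 480 parameters, giving the
111,180-parameter footprint that `count_parameters` reproduces
(100,200 + 400 + 8,040 + 80 + 2,460). There is no projection head: the
loss is applied to the representation layer itself.

The whole network — forward, analytic backward, optimiser — is implemented
in numpy. At ~1e5 parameters and 150 optimiser steps per fit, a training
run takes single-digit seconds on one CPU, so a deep-learning framework
would add a dependency without adding speed where it matters.

Training defaults, chosen as the recipe the method is defined with:

| parameter | default | notes |
|---|---|---|
| epochs | 30 | longer training changes results only marginally |
| batch size | 200 cells | one full-dataset batch when n < 200; a trailing batch of <2 cells is dropped |
| optimiser | Adam (β = 0.9/0.999, ε = 1e-8) | no weight decay |
| initial learning rate | 0.4 | cosine decay lr(t) = lr₀·½(1+cos(πt/T)), stepped per epoch |
| temperature τ | 0.5 | a widely used value for NT-Xent; configurable |
| mask ratio p | 0.9 | strongest-performing augmentation; survivors rescaled ×1/(1−p) |
| noise σ | 0 | additive Gaussian noise is supported for ablations but does not help, so off by default |

Numerical choices: weights and biases are initialised uniformly in
±1/√fan_in under the run seed; batch norm uses ε = 1e-5 and running-stat
momentum 0.1 (training batches use batch statistics, the final embedding
is computed in evaluation mode with running statistics on the un-augmented
matrix). Both views of a batch pass through the network concatenated, so
batch-norm statistics are computed over the joint 2N rows. All randomness
(initialisation, shuffling, masking, noise) derives from one seed via
spawned generator streams; two runs with the same seed are bit-identical.

### Preprocessing

Applied in order: (1) drop genes with nonzero counts in fewer than 2 cells
("expressed" means count > 0); (2) scale each cell to the median total
count, so library sizes are equal; (3) ln(1+x) — the +1 pseudo-count is
required because the data contain zeros; (4) rank genes by binned
normalised dispersion and keep the top 500; (5) standardise each gene to
zero mean, unit variance (population σ), with constant genes mapped to
all-zero columns rather than NaN. Scaling is computed after the HVG
subset, matching the listed order of the recipe. No post-scaling clipping
is applied.

The dispersion ranking bins genes into 20 equal-frequency mean-expression
bins, computes variance/mean per gene, and z-scores it within each bin; a
bin with a single gene (or zero dispersion spread) keeps raw dispersions.
Ties break by higher mean, then input order, making the ranking
deterministic and invariant to gene order. This is a Seurat-style
dispersion criterion computed directly on the log-normalised matrix; it is
deliberately self-contained rather than delegating to scanpy, whose
`seurat` flavour un-logs the data internally and uses equal-width bins —
the two selections agree broadly but not gene-for-gene.

### Clustering

KMeans uses k-means++ seeding with 10 restarts and is seeded. Leiden runs
modularity (RB-configuration) optimisation at resolution 1.0 on a
symmetrised, unweighted Euclidean kNN graph (15 neighbours) built on the
embedding directly — no PCA step — and infers the number of communities.
Partition labels are always re-indexed to consecutive integers ordered by
decreasing cluster size, so reports are stable across backends. Birch,
Gaussian mixture, MeanShift, spectral and Ward clustering dispatch through
the same interface; a naive baseline (KMeans on the first 2 principal
components of the preprocessed matrix) is included for comparisons.

A note on Leiden and tight clusters: modularity optimisation partitions
the *graph*, not the geometry, so a dense blob whose kNN graph has rich
internal structure can legitimately be split into sub-communities at
resolution 1.0. Exact recovery of well-separated blobs is guaranteed only
when each blob's kNN graph is (near-)complete — the regime the unit tests
exercise; on real embeddings Leiden trades this for the ability to infer
the number of clusters.

### Evaluation scores

External (need ground truth): adjusted Rand index and normalised mutual
information. NMI is normalised by the arithmetic mean of the two
entropies — the convention is configurable in principle but fixed here,
as no single normalisation is canonical. Internal (label-free): mean
Silhouette coefficient (Euclidean) and the Calinski–Harabasz ratio
[B/(K−1)]/[W/(n−K)]. The relative cluster-count error is
(K_pred − K_true)/K_true. Stability across repeated runs is summarised by
the coefficient of variation (sample standard deviation / mean). All four
clustering scores are checked against independent brute-force oracles in
the test suite.

## Synthetic data

The simulator reproduces the distributional structure of the splat
"experiment" model: gene base means λ_g ~ Gamma(0.6, rate 0.3); per group,
each gene is differentially expressed with probability 0.1, with a
multiplicative factor ~ LogNormal(0.1, facScale), half of them inverted
(down-regulated); cell library sizes ~ LogNormal(11, 0.2); counts ~
Poisson(μ_gc) where μ_gc is the cell's normalised group profile scaled to
its library; and finally logistic dropout that zeroes each entry with
probability π_gc = 1/(1+exp(−shape·(ln μ_gc − mid))), shape = −1, so
low-expression entries drop out preferentially. The recorded
`true_dropout_rate` counts only expressed (pre-dropout nonzero) entries
zeroed by the dropout step, which is why it sits below the overall matrix
sparsity. Raising `mid` from −1 to 1.5 moves the realised dropout from
roughly 5% to 30% on the balanced designs while the matrix sparsity runs
higher.

Two suite constructors mirror the study designs: 12 balanced datasets
(2500 genes; 4, 8, 16 groups × mid ∈ {−1, 0, 1, 1.5}; 250 cells/group)
and 12 imbalanced datasets (3000 cells; geometric-decay group sizes whose
smallest/largest ratio spans 0.6 down to 0.01 across the three group
counts, with a 10-cell floor; the exact size vectors are a construction of
this package, as only the ratio band is specified). Stratified
downsampling keeps round(fraction·n_label) cells per label.

What the simulator does *not* emulate: splatter's BCV Gamma–Poisson
over-dispersion layer, expression outliers, batch effects and trajectory
modes, and it makes no attempt to match splatter's RNG streams. Passing
tests on these data therefore demonstrate that the method recovers
group structure under multiplicative DE, library-size variation and
expression-dependent dropout — not that it handles over-dispersion,
batch structure or continuous differentiation, and not any particular
score on real tissues.

## Problem sizes and test design

Tests and the acceptance script run on simulated designs sized so the full
battery completes in about a minute on one CPU: the end-to-end checks use
the 4-group × 250-cell, 2500-gene design (strong DE, facScale 0.5) in two
dropout regimes — negligible (mid −10) for recovery, determinism and
downsampling checks, and mid 1.5 (~30% realised dropout) for the
masking-strength comparison — each repeated over 3 seeds, the repetition
protocol used throughout. With facScale at its 0.2 default, the mid-1.5
design carries essentially no recoverable signal (even clustering the full
preprocessed matrix fails), so the high-dropout comparisons use the
strong-DE variant where recovery is possible in principle. Smaller
fixtures (≤ 300 genes) exercise the pipeline plumbing and sweeps.

## Known limitations

- The encoder trains on dense numpy arrays; inputs are densified on read.
  Comfortable to ~50k cells × 5k genes on a laptop, but not out-of-core.
- Leiden's resolution is not auto-tuned; the inferred cluster count is
  sensitive to it and to the neighbourhood size.
- `CountPreprocessor.transform` re-runs the recipe on the given data (HVG
  selection and scaling are dataset-level operations); it does not project
  new cells onto a previously learned gene set.
- The temperature τ and the NMI normalisation are fixed by convention, not
  derived; both are exposed as parameters.
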