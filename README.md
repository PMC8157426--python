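# contraclust

Self-supervised contrastive clustering of single-cell RNA-seq counts.

Clustering is the workhorse of exploratory scRNA-seq analysis — identifying
cell types or states from a cells × genes count matrix without annotations.
The data are high-dimensional (tens of thousands of transcripts) and very
sparse, with *dropout* events injecting false zero counts. `contraclust`
addresses this with a two-phase method aimed at computational biologists who
want fast, stable cell clustering without fitting an explicit count-noise
model:

1. **Representation phase.** A small MLP encoder maps each cell's
   preprocessed expression profile `x_i ∈ R^{d'}` to an embedding
   `z_i ∈ R^e`. Training is self-supervised: for every mini-batch, two
   *views* of each cell are made by randomly masking 90% of gene values
   (input-level dropout, survivors rescaled by 1/(1−p)), and the encoder is
   trained to pull a cell's two views together and push all other cells
   apart using the normalised-temperature cross-entropy (NT-Xent) loss

   `ℓ(i,j) = −log [ exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ]`

   with cosine similarity `sim` and temperature `τ = 0.5`, averaged over all
   2N ordered positive pairs in the batch. The heavy masking plays the role
   of image cropping in visual contrastive learning: the model must
   recognise a cell from any small random subset of its genes, which also
   confers robustness to biological dropout without imputation.

2. **Clustering phase.** The embedding is clustered with a general
   algorithm: KMeans when the number of clusters k is known, Leiden
   community detection on the embedding's kNN graph when it is not. Birch,
   Gaussian mixtures, MeanShift, spectral and Ward clustering plug into the
   same interface.

The default encoder is `[200, 40, 60]` (embedding size 60) with batch
normalisation after the hidden layers — 111,180 trainable parameters for a
500-gene input — trained for 30 epochs with Adam (initial learning rate 0.4,
cosine decay) on mini-batches of 200 cells. Preprocessing filters genes
expressed in fewer than 2 cells, normalises each cell to the median library
size, applies ln(1+x), keeps the 500 most dispersed genes (binned
normalised dispersion), and standardises each gene. The whole stack runs on
one CPU in seconds; the neural network and its training loop are implemented
directly in numpy.

A splatter-style count simulator (`contraclust.simulate`) generates
group-structured datasets with controllable cluster counts, imbalance and
logistic expression-dependent dropout, so the full method is testable
end-to-end without downloading data.

## Worked example

```python
from contraclust import (
    SimConfig, simulate, preprocess, train, kmeans_cluster,
    ClusterParams, TrainConfig, score_partition,
)

ds = simulate(SimConfig(group_sizes=[250] * 4, de_fac_scale=0.5,
                        dropout_mid=-10.0, seed=0))
pm = preprocess(ds.counts)                      # 1000 cells x 500 HVGs
emb, history = train(pm, tcfg=TrainConfig(seed=0))
part = kmeans_cluster(emb, ClusterParams("kmeans", n_clusters=4, seed=0))
report = score_partition(part.labels, emb, truth_labels=ds.counts.labels)
print(f"embedding: {emb.z.shape}, loss {history[0]:.3f} -> {history[-1]:.3f}")
print(f"ARI {report.ari:.3f}  NMI {report.nmi:.3f}  "
      f"silhouette {report.silhouette:.3f}  clusters {report.n_clusters}")
```

prints

```
embedding: (1000, 60), loss 5.474 -> 4.798
ARI 1.000  NMI 1.000  silhouette 0.960  clusters 4
```

The simulated dataset has four equally sized groups of 250 cells with ~10%
of genes differentially expressed per group; the contrastive loss falls
over training and KMeans on the 60-dimensional embedding recovers the
generating groups exactly (ARI/NMI 1.0), forming tight, well-separated
clusters (silhouette 0.96).

Scikit-learn-style estimators wrap the same machinery
(`CountPreprocessor`, `ContrastiveEmbedding`, `ContrastiveClusterer` with
`fit` / `transform` / `fit_predict`), and a CLI covers the common protocols:

```bash
contraclust simulate --groups 4 --mid -1 --seed 0 --out data/sim.csv
contraclust run --input data/sim.csv --labels data/sim_labels.csv \
    --cluster kmeans --k 4 --seed 0 --out runs/demo
contraclust sweep-mask --input data/sim.csv --labels data/sim_labels.csv \
    --seed 0 --out runs/mask
```

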