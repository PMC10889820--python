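# scmgcn

Multi-view graph convolutional label transfer for single-cell RNA-seq.

Given an annotated **reference** expression matrix and an unannotated
**query** matrix sharing a gene namespace, `scmgcn` predicts a cell type for
every query cell. Instead of committing to one notion of cell–cell
similarity, it builds several cell–cell graphs with different construction
methods (plain SVD KNN, CCA with mutual nearest neighbours, Harmony-style
soft-cluster correction, Scanorama-style scaled SVD with MNN matching,
scmap-style centroid profiles, and an autoencoder bottleneck), encodes each
graph with a graph convolutional network, fuses the per-view embeddings with
learned attention weights, and classifies with a linear head. Because
different graph constructions fail under different batch effects, the fusion
is markedly more robust to cross-platform and cross-dataset shift than any
single similarity measure.

## Model

Each view *p* supplies a binary block adjacency $A^H_p$ over the
$n_r + n_q$ reference and query cells (reference–query *inter* edges and
query–query *intra* edges), normalized with self-loops as

$$\tilde A_p = D^{-1/2}(A^H_p + I)\,D^{-1/2}.$$

The shared feature matrix $X = [X_R; X_Q]$ (log-normalized, HVG-restricted
counts) is encoded per view by a stacked graph convolution

$$H^{(l+1)} = \sigma\!\left(\tilde A_p\, H^{(l)} W_p^{(l)}\right),\qquad H^{(0)} = X,$$

yielding embeddings $E_1,\dots,E_P$. A node-averaged attention score

$$w_p = \tfrac1{|v|}\sum_{i\in v} q^\top \tanh(W e_i^p + b),\qquad
\beta = \mathrm{softmax}(w),\qquad E = \sum_p \beta_p E_p$$

(with $W, b, q$ shared across views) fuses the views, and a single linear
layer maps $E$ to class scores. Training is transductive: all nodes
participate in message passing, but the cross-entropy loss
$L_c = -\sum_{l\in y_L} Y_l \ln \mathrm{softmax}(C E_l)$ runs over labeled
reference training nodes only, with early stopping on a held-out labeled
validation subset. The forward pass, backpropagation and Adam optimizer are
implemented directly in NumPy, keeping the package dependency-light; the
analytic gradients are verified against numerical differentiation in the
test suite.

## Worked example

`examples/04_label_transfer.py` simulates a 4-type reference/query pair
(300+300 cells, 800 genes) with a strong multiplicative per-gene batch
effect, preprocesses it, builds all six views, trains the multi-view model
and scores the query predictions:

```
multi-view query accuracy: 1.000, macro-F1: 1.000
attention weights: {'annoy_knn': 0.203, 'cca_mnn': 0.314, 'harmony': 0.008,
                    'scanorama': 0.004, 'scmap': 0.293, 'autoencoder_knn': 0.179}
1-NN cross-batch baseline accuracy: 0.961
```

Under this batch effect the naive nearest-neighbour transfer mislabels ~4%
of query cells while the fused model recovers every label; the attention
weights show the model leaning on the CCA-MNN and scmap views for this
dataset. `examples/03_build_views.py` prints the per-view edge quality that
explains this (the autoencoder view's inter edges are only 23% type-pure
here, and the attention correspondingly discounts it relative to the clean
views). The remaining examples cover simulation and preprocessing/HVG
selection.

The same pipeline is scriptable from the shell:

```bash
scmgcn simulate --preset batchy --seed 0 --out data/
scmgcn run --ref data/ref.mtx --query data/query.mtx \
    --ref-labels data/ref_labels.tsv --query-labels data/query_labels.tsv \
    --seed 0 --out results/
```

which writes `predictions.tsv`, `metrics.json`, per-fold attention weights
and training logs. `preprocess`, `build-graphs`, `train`, `predict` and
`evaluate` expose the individual stages.

## Layout

- `src/scmgcn/datasets.py` — expression container; MTX/CSV/TSV/h5ad readers and writers
- `src/scmgcn/preprocess.py` — doublet filter, gene matching, ANOVA HVG selection, normalization
- `src/scmgcn/graphs.py` — six view constructions, KNN/MNN edges, adjacency assembly and normalization
- `src/scmgcn/neighbors.py` — exact and random-projection-forest nearest-neighbour search
- `src/scmgcn/model.py` — multi-view GCN, attention fusion, classifier, loss, gradients
- `src/scmgcn/train.py` — split protocol, training loop, metrics, experiment harness
- `src/scmgcn/simulate.py` — synthetic paired-batch generator with ground truth
- `src/scmgcn/benchmark.py` — the standard benchmark run used by the acceptance script
- `docs/methods.md` — modeling decisions, parameters, and limitations
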