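# Methods

## Problem and model

`scmgcn` performs reference-based cell-type annotation: an annotated
reference scRNA-seq dataset supplies labels, an unannotated query dataset
receives predictions, and the two may come from different donors, platforms
or species (given a shared gene namespace). The central difficulty is the
batch effect — systematic, non-biological expression shift between the two
datasets — which breaks naive similarity-based transfer.

The model treats annotation as transductive semi-supervised node
classification on a joint cell graph. Each of P *views* contributes its own
graph over the same n_r + n_q cells; a view-specific GCN stack
σ(Ã H W) encodes each graph from the shared feature matrix; node-averaged
attention scores softmax into view weights β; the fused embedding
E = Σ_p β_p E_p feeds one linear classification layer. The cross-entropy
loss runs over labeled reference training nodes only. All message passing
includes the query cells, so query predictions benefit from query–query
structure (the intra-graph), not just query→reference edges.

Assumptions worth stating:

- The reference covers the query's cell types. A query cell of a type absent
  from the reference is scored as an error; there is no rejection or
  "unassigned" mechanism.
- Edges are unweighted. A view asserts that two cells are related, not how
  strongly.
- The shared gene namespace is the caller's responsibility (cross-species
  use requires pre-mapped homologs).

## Preprocessing

1. **Doublet filtering** (raw counts, both datasets): a self-contained
   simulation-based scorer. `doublet_rate_expected · n` synthetic doublets
   are formed by summing random cell pairs; observed + synthetic cells are
   embedded by 30-component truncated SVD of log1p-normalized counts; each
   observed cell's score is the synthetic fraction among its
   `doublet_knn_k = 20` nearest neighbours; cells above the
   `1 − doublet_rate_expected` quantile (default rate 0.06) are removed.
   This is the pair-sum/KNN core of the standard simulation-based doublet
   detectors, kept deliberately small so the package has no heavyweight
   dependency for a preprocessing step.
2. **Gene matching**: genes with ≥ 1 total read in *each* dataset,
   intersected, identical sorted order in both outputs.
3. **HVG selection**: per gene, one-way ANOVA of log-normalized expression
   across reference cell types; Bonferroni adjustment
   (p_adj = min(1, p·m) over the m testable genes); the 2000 genes with
   smallest p_adj are kept, ties broken by larger F then lexicographic gene
   id, so the output is deterministic. Zero-variance genes are excluded
   before testing. When fewer than 2000 genes are testable, all are returned
   with a warning.
4. **Normalization**: every cell scaled to a common total (default 1e4) then
   log1p. Whether the log should follow the scaling is a genuinely open
   choice; applying log1p after total-count scaling is standard practice and
   is a config switch (`log_transform`).

## Graph views

Each view = joint embedding + inter edges (reference↔query) + intra edges
(k_intra = 5 KNN among query cells). Node order is always reference cells
first. The reference–reference block is empty by default (an experimental
`ref_ref_knn` flag adds it). The six embeddings are lightweight renditions
of the standard integration ideas — the downstream model consumes only
adjacencies, so diversity across views matters more than fidelity to any
single published tool:

- **annoy_knn** — truncated SVD of the stacked matrix; query→reference KNN
  (k_inter = 5), exact by default or via the random-projection-tree forest
  (`exact_knn=False`), which the tests hold to ≥ 90% neighbour recall.
- **cca_mnn** — canonical correlation via SVD of the gene-standardized
  cross-covariance; per-cell loadings L2-normalized; mutual nearest
  neighbours as inter edges.
- **harmony** — joint SVD followed by iterative soft-k-means batch
  correction: per cluster, the batch-specific centroid offset from the
  global centroid is subtracted, responsibility-weighted, for
  `harmony_iters = 10` rounds over `harmony_clusters = 10` clusters. A
  single batch is returned unchanged.
- **scanorama** — joint randomized SVD of per-dataset L2-row-scaled
  matrices; MNN inter edges.
- **scmap** — every cell represented by its cosine-similarity profile
  against reference type centroids; each query cell's inter edges are
  restricted to reference cells of its best-matching centroid.
- **autoencoder_knn** — bottleneck of a single-hidden-layer autoencoder
  (128 hidden units, 30-dim bottleneck, 50 full-batch Adam epochs on MSE);
  query→reference KNN.

Adjacency normalization adds self-loops and rescales symmetrically:
Ã = D^{−1/2}(A + I)D^{−1/2}, so Ã's diagonal entry at a degree-d node is
1/(d+1) and all eigenvalues lie in [−1, 1]. The sparse implementation is
tested to < 1e−10 against the dense formula.

## Model and training defaults

| parameter | default | note |
|---|---|---|
| GCN layers | 2 | deeper stacks gain little and overfit; a 3-layer variant is one config switch away |
| hidden width h | 64 | |
| hidden activation | ReLU | attention nonlinearity is tanh by definition |
| dropout | 0.5 | after every graph-convolution activation except the last, training mode only |
| attention dim | 64 | two linear maps (W,b then q) with tanh between, shared across views |
| loss reduction | sum over labeled nodes | `mean` switch provided since optimizers are scale-sensitive |
| optimizer | Adam, lr 1e−3, weight decay 5e−4 (weights only) | standard semi-supervised GCN practice |
| epochs / patience | 200 / 20 | early stopping on validation accuracy |
| initialization | Glorot-uniform, seeded | |

The literal loss ln(C·E_l) of the definition is not a log-probability;
it is implemented as numerically stable log-softmax cross-entropy
(max-subtraction), which is the evident intent. Among epochs with equal
best validation accuracy the most recent parameters are kept, so training
continues to refine the fit during validation plateaus.

One deliberate consequence of node-averaged attention: because w_p averages
over *all* nodes, adding an isolated unlabeled node shifts every view's
score slightly (per-view GCN weights differ), so the labeled nodes' loss is
exactly invariant to such a node only per view / in the single-view model.
The test suite checks the invariance in that exact form.

## Evaluation protocol

Within one dataset: per fold, each cell type is split 60/40 into a training
pool and test cells, the pool 80/20 into train/validation; five folds
re-randomize the stratified partition (the fraction arithmetic is held to
±1 cell per label by the tests). Across datasets: the reference splits
80/20 per type into train/validation and the whole query is the test set.
Singleton labels go to train with a warning.

Metrics: accuracy, per-class precision/recall/F1 (zero when the denominator
is zero), macro-F1 averaged over classes present in the truth, micro-F1
from pooled TP/FP/FN (identical to accuracy for single-label multi-class —
asserted in tests). The implementation is a plain contingency-table
computation; scikit-learn serves as the independent oracle in the tests.
Label encoding is fit on reference labels only; a query label never seen in
the reference can only count as an error.

## Synthetic data

The generator emulates the regimes the method targets: per-gene baseline
means are log-normal (ln-mean ln 0.5, σ 1.0 — ~80% zeros at the default
scale); each of 5 types up-regulates its own disjoint block of 50 marker
genes by e² ≈ 7.4; per-cell library sizes are log-normal (σ 0.3); counts
are negative-binomial (dispersion 0.3) thinned by logistic dropout with
midpoint 1.0 (P(drop) = midpoint/(midpoint + μ), so the observed mean has
the closed form μ²/(midpoint + μ), Monte-Carlo-checked in the tests).
Reference and query batches share profiles but draw independent
multiplicative per-gene factors exp(N(0, σ_batch)), σ_batch = 0.5 by
default — the dominant batch-effect mode that MNN/Harmony-style views are
built to absorb. All randomness derives from a single seed; batches use
(seed, batch_id) streams.

What the generator does *not* emulate: real gene–gene correlation
structure, trajectories/doublet-specific biology, platform-specific count
distributions, or unshared cell types. Passing the synthetic benchmark
therefore demonstrates that the machinery is correct and that fusion is
robust to multiplicative batch shift — not that any particular accuracy
carries over to a given real dataset pair.

## Problem sizes and determinism

The standard benchmark (also run by `scripts/acceptance.py`) uses the
default study conditions — 5 types, 2000 genes, 500+500 cells,
σ_batch = 0.5 — over three replicate seeds, with all six views and the
1-NN baseline and single-view ablations; one replicate takes ~20 s on a
single CPU. Unit tests use smaller fixtures (hundreds of cells, hundreds of
genes) chosen so every property is exercised in seconds. Every stochastic
stage (simulation, SVD, k-means, autoencoder, dropout, splits, init)
consumes an explicit seed; end-to-end runs are bit-reproducible.

## Known limitations

- Dense per-view forward passes are O((n_r+n_q)·m·h); tens of thousands of
  cells are feasible, but atlas-scale inputs would need minibatched or
  sparse-feature training.
- The Harmony/Scanorama/scmap/ANNOY views capture the core idea of their
  namesakes, not their full algorithms; comparisons against the original
  tools should use the originals.
- No novelty detection: every query cell is forced into a reference class.
- Doublet scoring assumes raw counts and enough cells (> k) to embed;
  below that it is skipped with a warning.
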