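"""Multi-view cell–cell graph construction.

A *view* is one way of relating cells across and within datasets.  Each
view embeds all reference and query cells into a shared low-dimensional
space with one of six methods, then builds

* an **inter-graph**: edges between reference and query cells, and
* an **intra-graph**: KNN edges among query cells,

and assembles them into one binary symmetric block adjacency ``A`` over the
``n_r + n_q`` cells (reference cells first).  The graph convolution consumes
the symmetrically normalized matrix with self-loops,

    A_norm = D^{-1/2} (A + I) D^{-1/2},

where ``D`` is the diagonal degree matrix of ``A + I``.

The six embedding methods are deliberately lightweight renditions of the
field's standard integration ideas: plain truncated SVD (with exact or
ANNOY-style approximate KNN), CCA with mutual nearest neighbours, a
Harmony-style soft-cluster batch correction, a Scanorama-style L2-scaled
joint SVD with MNN matching, scmap-style similarity profiles against
reference cell-type centroids, and an autoencoder bottleneck.  The
downstream model consumes only the resulting adjacencies, so the views need
to be diverse and reasonable rather than bit-faithful to any one tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.utils.extmath import randomized_svd

from .datasets import ExpressionDataset
from .neighbors import RPForest, knn_indices
from .optim import Adam

__all__ = [
    "GRAPH_METHODS",
    "GraphConfig",
    "ViewGraph",
    "MultiViewBundle",
    "embed_joint",
    "harmony_correct",
    "knn_edges",
    "mutual_nn_edges",
    "assemble_adjacency",
    "normalize_adjacency",
    "build_view",
    "build_bundle",
]

GRAPH_METHODS = (
    "annoy_knn",
    "cca_mnn",
    "harmony",
    "scanorama",
    "scmap",
    "autoencoder_knn",
)


@dataclass
class GraphConfig:
    k_inter: int = 5
    k_intra: int = 5
    n_components: int = 30
    harmony_clusters: int = 10
    harmony_iters: int = 10
    ae_hidden: int = 128
    ae_epochs: int = 50
    annoy_trees: int = 10
    exact_knn: bool = True
    ref_ref_knn: bool = False  # experimental reference-reference KNN block
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_inter", "k_intra", "n_components", "harmony_clusters",
                     "harmony_iters", "ae_hidden", "ae_epochs", "annoy_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ViewGraph:
    """One view: its edges, block adjacency and normalized adjacency."""

    method: str
    inter_edges: set  # (ref_index, query_index)
    intra_edges: set  # (query_index, query_index)
    adjacency: sp.csr_matrix
    normalized: sp.csr_matrix
    n_ref: int
    n_query: int
    config: GraphConfig = field(default_factory=GraphConfig)


@dataclass
class MultiViewBundle:
    """Shared node feature matrix plus one ViewGraph per construction method."""

    features: np.ndarray  # (n_r + n_q) × m, reference cells first
    views: list
    n_ref: int
    n_query: int

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.n_ref + self.n_query:
            raise ValueError("feature row count must equal n_ref + n_query")
        for v in self.views:
            if v.adjacency.shape[0] != self.n_ref + self.n_query:
                raise ValueError("view adjacency does not match bundle size")

    @property
    def n_views(self) -> int:
        return len(self.views)


# --------------------------------------------------------------------------
# joint embeddings
# --------------------------------------------------------------------------

def _dense(mat) -> np.ndarray:
    return np.asarray(mat.todense(), dtype=float) if sp.issparse(mat) else np.asarray(mat, dtype=float)


def _clamped_components(n_components: int, *shapes: int) -> int:
    limit = min(shapes)
    if n_components >= limit:
        import warnings

        warnings.warn(f"n_components={n_components} clamped to {limit - 1}")
        return max(1, limit - 1)
    return n_components


def _joint_svd(stacked: np.ndarray, n_components: int, seed: int) -> np.ndarray:
    n_components = _clamped_components(n_components, *stacked.shape)
    U, S, _ = randomized_svd(stacked, n_components=n_components,
                             random_state=int(seed) % (2**31))
    return U * S


def harmony_correct(
    Z: np.ndarray,
    batches: np.ndarray,
    n_clusters: int = 10,
    n_iters: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Soft-cluster batch correction of an embedding (Harmony's core idea).

    Repeatedly soft-assigns cells to ``n_clusters`` centroids and subtracts,
    from every cell, the responsibility-weighted difference between its
    batch's cluster centroid and the global cluster centroid.  With a single
    batch the correction is identically zero and ``Z`` is returned unchanged.
    """
    batches = np.asarray(batches)
    uniq = np.unique(batches)
    if len(uniq) < 2:
        return Z.copy()
    rng = np.random.default_rng([seed, 11])
    Z = Z.astype(float).copy()
    k = min(n_clusters, Z.shape[0])
    centroids = Z[rng.choice(Z.shape[0], size=k, replace=False)]
    for _ in range(n_iters):
        d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        tau = max(d2.min(axis=1).mean(), 1e-12)
        logits = -d2 / tau
        logits -= logits.max(axis=1, keepdims=True)
        R = np.exp(logits)
        R /= R.sum(axis=1, keepdims=True)
        mass = R.sum(axis=0)  # (k,)
        mu = (R.T @ Z) / np.maximum(mass, 1e-12)[:, None]
        shift = np.zeros_like(Z)
        for b in uniq:
            sel = batches == b
            mass_b = R[sel].sum(axis=0)
            mu_b = (R[sel].T @ Z[sel]) / np.maximum(mass_b, 1e-12)[:, None]
            ok = mass_b > 1e-8
            delta = np.where(ok[:, None], mu_b - mu, 0.0)
            shift[sel] = R[sel] @ delta
        Z -= shift
        centroids = mu
    return Z


def _autoencoder_embed(
    stacked: np.ndarray, n_components: int, hidden: int, epochs: int, seed: int
) -> np.ndarray:
    """Bottleneck activations of a single-hidden-layer autoencoder.

    Encoder: input -> ``hidden`` (ReLU) -> ``n_components`` (linear);
    decoder: one linear layer back to the input.  Trained full-batch with
    Adam on mean-squared reconstruction error.
    """
    X = stacked.astype(np.float32)
    n, m = X.shape
    n_components = _clamped_components(n_components, n, m)
    rng = np.random.default_rng([seed, 29])

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)

    W1, b1 = glorot(m, hidden), np.zeros(hidden, dtype=np.float32)
    W2, b2 = glorot(hidden, n_components), np.zeros(n_components, dtype=np.float32)
    W3, b3 = glorot(n_components, m), np.zeros(m, dtype=np.float32)
    params = [W1, b1, W2, b2, W3, b3]
    opt = Adam(params, lr=1e-3, decay_mask=[True, False, True, False, True, False])

    for _ in range(epochs):
        A1 = X @ W1 + b1
        H1 = np.maximum(A1, 0.0)
        Z = H1 @ W2 + b2
        Xhat = Z @ W3 + b3
        diff = (Xhat - X) * (2.0 / (n * m))
        gW3, gb3 = Z.T @ diff, diff.sum(axis=0)
        dZ = diff @ W3.T
        gW2, gb2 = H1.T @ dZ, dZ.sum(axis=0)
        dH1 = (dZ @ W2.T) * (A1 > 0)
        gW1, gb1 = X.T @ dH1, dH1.sum(axis=0)
        opt.step([gW1, gb1, gW2, gb2, gW3, gb3])

    return (np.maximum(X @ W1 + b1, 0.0) @ W2 + b2).astype(float)


def _scmap_profiles(
    ref: np.ndarray, query: np.ndarray, ref_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cosine-similarity profiles of every cell against reference type centroids."""
    types = np.unique(ref_labels)
    centroids = np.stack([ref[ref_labels == t].mean(axis=0) for t in types])
    cnorm = centroids / np.maximum(np.linalg.norm(centroids, axis=1, keepdims=True), 1e-12)

    def profile(X):
        Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        return Xn @ cnorm.T

    return profile(ref), profile(query), types


def embed_joint(
    ref_matrix,
    query_matrix,
    method: str,
    cfg: GraphConfig | None = None,
    ref_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed reference and query cells into one shared space.

    Inputs are normalized (log) expression matrices over identical genes.
    ``ref_labels`` is required by the ``scmap`` method (centroid profiles).
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or GraphConfig()
    if method not in GRAPH_METHODS:
        raise ValueError(f"unknown graph method {method!r}; choose from {GRAPH_METHODS}")
    Xr, Xq = _dense(ref_matrix), _dense(query_matrix)
    if Xr.shape[1] != Xq.shape[1]:
        raise ValueError("reference and query must share gene order")
    n_r = Xr.shape[0]

    if method == "annoy_knn":
        emb = _joint_svd(np.vstack([Xr, Xq]), cfg.n_components, cfg.seed)
    elif method == "cca_mnn":
        def std(X):
            mu, sd = X.mean(axis=0), X.std(axis=0)
            return (X - mu) / np.where(sd > 1e-12, sd, 1.0)

        K = std(Xr) @ std(Xq).T
        n_comp = _clamped_components(cfg.n_components, *K.shape)
        U, S, Vt = randomized_svd(K, n_components=n_comp,
                                  random_state=int(cfg.seed) % (2**31))
        er, eq = U * np.sqrt(S), Vt.T * np.sqrt(S)
        er /= np.maximum(np.linalg.norm(er, axis=1, keepdims=True), 1e-12)
        eq /= np.maximum(np.linalg.norm(eq, axis=1, keepdims=True), 1e-12)
        return er, eq
    elif method == "harmony":
        Z = _joint_svd(np.vstack([Xr, Xq]), cfg.n_components, cfg.seed)
        batches = np.array([0] * n_r + [1] * Xq.shape[0])
        emb = harmony_correct(Z, batches, cfg.harmony_clusters,
                              cfg.harmony_iters, cfg.seed)
    elif method == "scanorama":
        def l2(X):
            return X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)

        emb = _joint_svd(np.vstack([l2(Xr), l2(Xq)]), cfg.n_components, cfg.seed)
    elif method == "scmap":
        if ref_labels is None:
            raise ValueError("scmap embedding requires reference labels")
        er, eq, _ = _scmap_profiles(Xr, Xq, np.asarray(ref_labels))
        return er, eq
    else:  # autoencoder_knn
        emb = _autoencoder_embed(np.vstack([Xr, Xq]), cfg.n_components,
                                 cfg.ae_hidden, cfg.ae_epochs, cfg.seed)
    return emb[:n_r], emb[n_r:]


# --------------------------------------------------------------------------
# edges and adjacency
# --------------------------------------------------------------------------

def knn_edges(
    source_embedding: np.ndarray,
    target_embedding: np.ndarray,
    k: int,
    metric: str = "euclidean",
    exclude_self: bool = False,
    exact: bool = True,
    annoy_trees: int = 10,
    seed: int = 0,
) -> set:
    """Directed KNN edge set {(source_i, target_j)}.

    ``exclude_self`` removes (i, i) pairs when source and target are the
    same point set.  ``exact=False`` uses the random-projection forest and
    is validated to high neighbour recall in the test suite.
    """
    source_embedding = np.asarray(source_embedding, dtype=float)
    target_embedding = np.asarray(target_embedding, dtype=float)
    if source_embedding.shape[1] != target_embedding.shape[1]:
        raise ValueError("embeddings must share dimension")
    if exact:
        idx = knn_indices(source_embedding, target_embedding, k, metric, exclude_self)
        return {(i, int(j)) for i, row in enumerate(idx) for j in row}
    forest = RPForest(target_embedding, n_trees=annoy_trees, seed=seed, metric=metric)
    rows = forest.query(source_embedding, k, exclude_self=exclude_self)
    return {(i, int(j)) for i, row in enumerate(rows) for j in row}


def mutual_nn_edges(
    ref_embedding: np.ndarray,
    query_embedding: np.ndarray,
    k: int,
    metric: str = "euclidean",
) -> set:
    """Mutual nearest neighbour pairs (ref_i, query_j).

    A pair is kept iff j is among the k nearest query cells of ref i AND i
    is among the k nearest reference cells of query j.
    """
    fwd = knn_edges(ref_embedding, query_embedding, k, metric)
    rev = knn_edges(query_embedding, ref_embedding, k, metric)
    return {(i, j) for (i, j) in fwd if (j, i) in rev}


def assemble_adjacency(
    inter_edges, intra_edges, n_r: int, n_q: int,
    ref_edges=None,
) -> sp.csr_matrix:
    """Assemble the symmetric binary block adjacency over n_r + n_q nodes.

    Reference cells occupy rows/columns 0..n_r-1, query cells the rest.
    Inter edges land in the off-diagonal blocks, intra edges in the
    query–query block; the reference–reference block is empty unless
    explicit ``ref_edges`` are supplied.  The diagonal is zero.
    """
    n = n_r + n_q
    rows, cols = [], []
    for i, j in inter_edges:
        if not (0 <= i < n_r and 0 <= j < n_q):
            raise ValueError(f"inter edge out of range: {(i, j)}")
        rows += [i, n_r + j]
        cols += [n_r + j, i]
    for j, j2 in intra_edges:
        if not (0 <= j < n_q and 0 <= j2 < n_q):
            raise ValueError(f"intra edge out of range: {(j, j2)}")
        if j == j2:
            continue
        rows += [n_r + j, n_r + j2]
        cols += [n_r + j2, n_r + j]
    for i, i2 in ref_edges or ():
        if not (0 <= i < n_r and 0 <= i2 < n_r):
            raise ValueError(f"reference edge out of range: {(i, i2)}")
        if i == i2:
            continue
        rows += [i, i2]
        cols += [i2, i]
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    A.data[:] = 1.0  # de-duplicate multiply-inserted edges
    A.setdiag(0)
    A.eliminate_zeros()
    return A


def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    A = sp.csr_matrix(A)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A != A.T).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.nnz and not np.all(np.isin(A.data, (0.0, 1.0))):
        raise ValueError("adjacency must be binary")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    A_hat = A + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return sp.csr_matrix(d_inv_sqrt @ A_hat @ d_inv_sqrt)


def build_view(
    ref_ds: ExpressionDataset,
    query_ds: ExpressionDataset,
    method: str,
    cfg: GraphConfig | None = None,
) -> ViewGraph:
    """Build one complete view from preprocessed, gene-matched datasets.

    Inter edges: mutual nearest neighbours for ``cca_mnn`` and
    ``scanorama``; query→reference KNN restricted to the best-matching
    centroid's cells for ``scmap``; plain query→reference KNN (symmetrized
    by the undirected adjacency) otherwise.  Intra edges: ``k_intra`` KNN
    among query cells.
    """
    cfg = cfg or GraphConfig()
    if list(ref_ds.gene_ids) != list(query_ds.gene_ids):
        raise ValueError("datasets must be gene-matched before graph construction")
    er, eq = embed_joint(ref_ds.matrix, query_ds.matrix, method, cfg,
                         ref_labels=ref_ds.labels)
    n_r, n_q = er.shape[0], eq.shape[0]
    k_inter = min(cfg.k_inter, n_r)

    if method in ("cca_mnn", "scanorama"):
        inter = mutual_nn_edges(er, eq, k_inter)
    elif method == "scmap":
        # restrict each query cell's candidates to the best-matching type
        labels = np.asarray(ref_ds.labels)
        types = np.unique(labels)
        best = np.argmax(eq, axis=1)  # scmap embedding = similarity per centroid
        inter = set()
        for t_idx, t in enumerate(types):
            qsel = np.where(best == t_idx)[0]
            rsel = np.where(labels == t)[0]
            if len(qsel) == 0 or len(rsel) == 0:
                continue
            k = min(k_inter, len(rsel))
            idx = knn_indices(eq[qsel], er[rsel], k, metric="euclidean")
            for qi, row in zip(qsel, idx):
                inter.update((int(rsel[j]), int(qi)) for j in row)
    else:
        fwd = knn_edges(eq, er, k_inter, exact=cfg.exact_knn,
                        annoy_trees=cfg.annoy_trees, seed=cfg.seed)
        inter = {(r, q) for (q, r) in fwd}

    k_intra = min(cfg.k_intra, max(1, n_q - 1))
    intra = knn_edges(eq, eq, k_intra, exclude_self=True, exact=cfg.exact_knn,
                      annoy_trees=cfg.annoy_trees, seed=cfg.seed)

    ref_edges = None
    if cfg.ref_ref_knn:
        k_ref = min(cfg.k_intra, max(1, n_r - 1))
        ref_edges = knn_edges(er, er, k_ref, exclude_self=True)

    A = assemble_adjacency(inter, intra, n_r, n_q, ref_edges=ref_edges)
    return ViewGraph(
        method=method,
        inter_edges=inter,
        intra_edges=intra,
        adjacency=A,
        normalized=normalize_adjacency(A),
        n_ref=n_r,
        n_query=n_q,
        config=cfg,
    )


def build_bundle(
    ref_ds: ExpressionDataset,
    query_ds: ExpressionDataset,
    methods=GRAPH_METHODS,
    cfg: GraphConfig | None = None,
    dtype=np.float32,
) -> MultiViewBundle:
    """Build all requested views plus the shared stacked feature matrix."""
    cfg = cfg or GraphConfig()
    views = [build_view(ref_ds, query_ds, m, cfg) for m in methods]
    X = np.vstack([_dense(ref_ds.matrix), _dense(query_ds.matrix)]).astype(dtype)
    return MultiViewBundle(features=X, views=views,
                           n_ref=ref_ds.n_cells, n_query=query_ds.n_cells)


# --------------------------------------------------------------------------
# on-disk form: edge-list TSV + MTX of the normalized adjacency + manifest
# --------------------------------------------------------------------------

def save_view(view: ViewGraph, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "edges.tsv", "w") as fh:
        fh.write("src\tdst\tblock\n")
        for i, j in sorted(view.inter_edges):
            fh.write(f"{i}\t{j}\tinter\n")
        for j, j2 in sorted(view.intra_edges):
            fh.write(f"{j}\t{j2}\tintra\n")
    mmwrite(str(directory / "normalized.mtx"), view.normalized)
    manifest = {
        "method": view.method,
        "n_ref": view.n_ref,
        "n_query": view.n_query,
        "k_inter": view.config.k_inter,
        "k_intra": view.config.k_intra,
        "seed": view.config.seed,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_view(directory) -> ViewGraph:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    inter, intra = set(), set()
    with open(directory / "edges.tsv") as fh:
        next(fh)
        for line in fh:
            a, b, block = line.split()
            (inter if block == "inter" else intra).add((int(a), int(b)))
    n_r, n_q = manifest["n_ref"], manifest["n_query"]
    A = assemble_adjacency(inter, intra, n_r, n_q)
    normalized = sp.csr_matrix(mmread(directory / "normalized.mtx"))
    cfg = GraphConfig(k_inter=manifest["k_inter"], k_intra=manifest["k_intra"],
                      seed=manifest["seed"])
    return ViewGraph(method=manifest["method"], inter_edges=inter, intra_edges=intra,
                     adjacency=A, normalized=normalized, n_ref=n_r, n_query=n_q,
                     config=cfg)
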