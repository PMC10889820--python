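import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from scmgcn.graphs import (
    GRAPH_METHODS,
    GraphConfig,
    assemble_adjacency,
    build_view,
    embed_joint,
    harmony_correct,
    knn_edges,
    mutual_nn_edges,
    normalize_adjacency,
    save_view,
    load_view,
)
from scmgcn.neighbors import RPForest, knn_indices


def _random_adjacency(rng, n, p=0.2):
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return sp.csr_matrix((upper | upper.T).astype(float))


def _dense_normalize_oracle(A):
    """Brute-force dense evaluation of D^{-1/2}(A+I)D^{-1/2}."""
    A_hat = A.toarray() + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    Dinv = np.diag(1.0 / np.sqrt(d))
    return Dinv @ A_hat @ Dinv


# ------------------------------------------------------------ normalization

def test_normalize_empty_graph_is_identity():
    A = sp.csr_matrix((2, 2))
    np.testing.assert_allclose(normalize_adjacency(A).toarray(), np.eye(2))


def test_normalize_single_edge_by_hand():
    A = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    np.testing.assert_allclose(
        normalize_adjacency(A).toarray(), [[0.5, 0.5], [0.5, 0.5]]
    )


def test_normalize_matches_dense_oracle_on_random_graphs(rng):
    for _ in range(25):
        n = int(rng.integers(2, 50))
        A = _random_adjacency(rng, n)
        got = normalize_adjacency(A).toarray()
        assert np.abs(got - _dense_normalize_oracle(A)).max() < 1e-10


def test_regular_graph_rows_sum_to_one():
    n = 12  # cycle graph: every node has degree 2
    A = sp.csr_matrix(
        (np.ones(2 * n), (list(range(n)) * 2,
                          [(i + 1) % n for i in range(n)] + [(i - 1) % n for i in range(n)])),
        shape=(n, n),
    )
    rows = np.asarray(normalize_adjacency(A).sum(axis=1)).ravel()
    np.testing.assert_allclose(rows, 1.0)


def test_normalized_diagonal_is_inverse_degree(rng):
    A = _random_adjacency(rng, 20)
    d = np.asarray(A.sum(axis=1)).ravel() + 1.0
    np.testing.assert_allclose(normalize_adjacency(A).diagonal(), 1.0 / d)


def test_normalize_eigenvalues_within_unit_interval(rng):
    for _ in range(5):
        A = _random_adjacency(rng, 30)
        eig = np.linalg.eigvalsh(normalize_adjacency(A).toarray())
        assert eig.min() >= -1 - 1e-10 and eig.max() <= 1 + 1e-10


def test_normalize_rejects_bad_input():
    with pytest.raises(ValueError, match="symmetric"):
        normalize_adjacency(sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]])))
    with pytest.raises(ValueError, match="diagonal"):
        normalize_adjacency(sp.csr_matrix(np.eye(2)))


# ------------------------------------------------------------ assembly

def test_assemble_no_edges_gives_zero_matrix():
    assert assemble_adjacency(set(), set(), 2, 2).nnz == 0


def test_assemble_single_inter_edge_block_placement():
    A = assemble_adjacency({(0, 0)}, set(), 1, 1)
    np.testing.assert_array_equal(A.toarray(), [[0, 1], [1, 0]])


def test_assemble_symmetric_zero_trace_no_ref_block(rng):
    inter = {(int(i), int(j)) for i, j in rng.integers(0, 5, size=(10, 2))}
    intra = {(int(i), int(j)) for i, j in rng.integers(0, 5, size=(10, 2))}
    A = assemble_adjacency(inter, intra, 5, 5)
    assert (A != A.T).nnz == 0
    assert A.diagonal().sum() == 0
    assert A[:5, :5].nnz == 0  # reference-reference block empty


def test_assemble_out_of_range_raises():
    with pytest.raises(ValueError, match="out of range"):
        assemble_adjacency({(0, 7)}, set(), 2, 2)


# ------------------------------------------------------------ KNN / MNN

def test_knn_collinear_points_brute_force():
    pts = np.array([[0.0], [1.0], [3.0]])
    edges = knn_edges(pts, pts, k=1, exclude_self=True)
    assert edges == {(0, 1), (1, 0), (2, 1)}


def test_knn_k_at_least_n_minus_one_is_complete():
    pts = np.random.default_rng(0).random((6, 3))
    edges = knn_edges(pts, pts, k=5, exclude_self=True)
    assert edges == {(i, j) for i in range(6) for j in range(6) if i != j}


def test_duplicated_points_pair_up():
    pts = np.array([[0.0], [0.0], [5.0], [5.0]])
    edges = knn_edges(pts, pts, k=1, exclude_self=True)
    assert edges == {(0, 1), (1, 0), (2, 3), (3, 2)}


def test_knn_clamps_oversized_k():
    pts = np.array([[0.0], [1.0]])
    with pytest.warns(UserWarning, match="clamping"):
        edges = knn_edges(pts, pts, k=10, exclude_self=True)
    assert edges == {(0, 1), (1, 0)}


def test_mnn_identical_points_are_mutual():
    p = np.array([[1.0, 2.0]])
    assert mutual_nn_edges(p, p.copy(), k=1) == {(0, 0)}


def test_mnn_asymmetric_case_brute_force():
    ref = np.array([[0.0], [10.0]])
    query = np.array([[1.0]])
    assert mutual_nn_edges(ref, query, k=1) == {(0, 0)}


def test_mnn_subset_of_directed_knn(rng):
    ref, query = rng.random((20, 4)), rng.random((15, 4))
    mnn = mutual_nn_edges(ref, query, k=3)
    assert mnn <= knn_edges(ref, query, k=3)


def test_approximate_knn_recall_above_90_percent(rng):
    pts = rng.normal(size=(500, 20))
    exact = knn_indices(pts, pts, k=10, exclude_self=True)
    forest = RPForest(pts, n_trees=10, seed=0)
    approx = forest.query(pts, k=10, exclude_self=True)
    hits = sum(len(set(e) & set(a)) for e, a in zip(exact, approx))
    assert hits / exact.size >= 0.90


# ------------------------------------------------------------ embeddings

def test_svd_embedding_preserves_gram_matrix_of_low_rank_input(rng):
    basis = rng.normal(size=(2, 40))
    coeff = rng.normal(size=(25, 2))
    X = coeff @ basis  # exactly rank 2
    er, eq = embed_joint(X[:15], X[15:], "annoy_knn", GraphConfig(n_components=2, seed=0))
    emb = np.vstack([er, eq])
    np.testing.assert_allclose(emb @ emb.T, X @ X.T, atol=1e-6)


def test_scmap_embedding_dimension_is_number_of_types(rng):
    Xr, Xq = rng.random((12, 30)), rng.random((8, 30))
    labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    er, eq = embed_joint(Xr, Xq, "scmap", ref_labels=labels)
    assert er.shape == (12, 3) and eq.shape == (8, 3)


def test_harmony_single_batch_is_identity(rng):
    Z = rng.normal(size=(30, 5))
    out = harmony_correct(Z, np.zeros(30), n_clusters=4, n_iters=5, seed=0)
    np.testing.assert_array_equal(out, Z)


def test_harmony_two_batches_reduces_batch_shift(rng):
    base = rng.normal(size=(60, 5))
    shift = np.full(5, 3.0)
    Z = np.vstack([base[:30], base[30:] + shift])
    batches = np.array([0] * 30 + [1] * 30)
    corrected = harmony_correct(Z, batches, n_clusters=3, n_iters=10, seed=0)
    before = np.linalg.norm(Z[:30].mean(0) - Z[30:].mean(0))
    after = np.linalg.norm(corrected[:30].mean(0) - corrected[30:].mean(0))
    assert after < before


def test_unknown_method_raises(rng):
    with pytest.raises(ValueError, match="unknown graph method"):
        embed_joint(rng.random((4, 5)), rng.random((4, 5)), "umap")


def test_embed_clamps_excess_components(rng):
    X = rng.random((5, 4))
    with pytest.warns(UserWarning, match="clamped"):
        er, eq = embed_joint(X[:3], X[3:], "annoy_knn", GraphConfig(n_components=30))
    assert er.shape[1] < 4


# ------------------------------------------------------------ build_view

@pytest.mark.parametrize("method", GRAPH_METHODS)
def test_view_invariants_all_methods(small_preprocessed, method):
    ref, query, _ = small_preprocessed
    cfg = GraphConfig(k_inter=3, k_intra=3, ae_epochs=5, seed=0)
    view = build_view(ref, query, method, cfg)
    A = view.adjacency
    n_r, n_q = view.n_ref, view.n_query
    assert A.shape == (n_r + n_q, n_r + n_q)
    assert (A != A.T).nnz == 0
    assert A.diagonal().sum() == 0
    assert set(np.unique(A.toarray())) <= {0.0, 1.0}
    assert A[:n_r, :n_r].nnz == 0
    # normalized diagonal entries are 1/(degree+1)
    d = np.asarray(A.sum(axis=1)).ravel() + 1.0
    np.testing.assert_allclose(view.normalized.diagonal(), 1.0 / d)


def test_build_view_deterministic(small_preprocessed):
    ref, query, _ = small_preprocessed
    cfg = GraphConfig(ae_epochs=5, seed=5)
    for method in ("annoy_knn", "autoencoder_knn", "harmony"):
        v1 = build_view(ref, query, method, cfg)
        v2 = build_view(ref, query, method, cfg)
        assert v1.inter_edges == v2.inter_edges
        assert v1.intra_edges == v2.intra_edges


def test_inter_edges_mostly_within_type(small_preprocessed):
    ref, query, _ = small_preprocessed
    view = build_view(ref, query, "annoy_knn", GraphConfig(k_inter=3, seed=0))
    same = sum(ref.labels[i] == query.labels[j] for i, j in view.inter_edges)
    assert same / len(view.inter_edges) >= 0.8


def test_view_roundtrip_on_disk(tmp_path, small_preprocessed):
    ref, query, _ = small_preprocessed
    view = build_view(ref, query, "annoy_knn", GraphConfig(seed=1))
    save_view(view, tmp_path / "v")
    back = load_view(tmp_path / "v")
    assert back.method == view.method
    assert back.inter_edges == view.inter_edges
    assert back.intra_edges == view.intra_edges
    assert np.abs((back.normalized - view.normalized)).max() < 1e-12


# ------------------------------------------------------------ property tests

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=40), st.integers(min_value=0, max_value=10**6))
def test_normalization_oracle_property(n, seed):
    rng = np.random.default_rng(seed)
    A = _random_adjacency(rng, n)
    got = normalize_adjacency(A).toarray()
    assert np.abs(got - _dense_normalize_oracle(A)).max() < 1e-10
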