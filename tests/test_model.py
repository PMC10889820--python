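import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from scmgcn.graphs import normalize_adjacency
from scmgcn.model import (
    MGCNParams,
    ModelConfig,
    attention_scores,
    attention_weights,
    classify,
    cross_entropy_loss,
    encode_view,
    forward,
    fuse,
    gcn_layer,
    init_params,
    load_params,
    loss_and_grads,
    save_params,
)
from scmgcn.optim import Adam


def _random_A(rng, n):
    upper = np.triu(rng.random((n, n)) < 0.3, k=1)
    return normalize_adjacency(sp.csr_matrix((upper | upper.T).astype(float))).toarray()


# ------------------------------------------------------------ gcn_layer

def test_gcn_layer_identity_propagation(rng):
    H = rng.normal(size=(5, 4))
    out = gcn_layer(H, np.eye(5), np.eye(4), activation="identity")
    np.testing.assert_allclose(out, H)


def test_gcn_layer_zero_weights(rng):
    H = rng.normal(size=(5, 4))
    out = gcn_layer(H, np.eye(5), np.zeros((4, 3)))
    np.testing.assert_array_equal(out, np.zeros((5, 3)))


def test_gcn_layer_matches_per_node_loop(rng):
    for _ in range(10):
        n, d_in, d_out = 10, 6, 4
        A = _random_A(rng, n)
        H = rng.normal(size=(n, d_in))
        W = rng.normal(size=(d_in, d_out))
        got = gcn_layer(H, A, W, activation="relu")
        HW = H @ W
        want = np.array(
            [np.maximum(sum(A[i, j] * HW[j] for j in range(n)), 0.0) for i in range(n)]
        )
        assert np.abs(got - want).max() < 1e-8


def test_gcn_layer_shape_errors(rng):
    with pytest.raises(ValueError, match="incompatible"):
        gcn_layer(rng.normal(size=(4, 3)), np.eye(5), rng.normal(size=(3, 2)))
    with pytest.raises(ValueError, match="input dim"):
        gcn_layer(rng.normal(size=(4, 3)), np.eye(4), rng.normal(size=(5, 2)))


# ------------------------------------------------------------ encode_view

def test_encode_single_layer_equals_gcn_layer(rng):
    cfg = ModelConfig(n_classes=2, n_views=1, n_layers=1, dropout=0.0)
    A = _random_A(rng, 8)
    X = rng.normal(size=(8, 5))
    W = rng.normal(size=(5, 3))
    np.testing.assert_allclose(encode_view(X, A, [W], cfg), gcn_layer(X, A, W))


def test_encode_eval_mode_is_deterministic(rng):
    cfg = ModelConfig(n_classes=2, n_views=1, dropout=0.5)
    A = _random_A(rng, 8)
    X = rng.normal(size=(8, 5))
    Ws = [rng.normal(size=(5, 4)), rng.normal(size=(4, 4))]
    out1 = encode_view(X, A, Ws, cfg, training=False)
    out2 = encode_view(X, A, Ws, cfg, training=False)
    np.testing.assert_array_equal(out1, out2)


def test_identical_views_give_identical_embeddings(rng):
    cfg = ModelConfig(n_classes=2, n_views=2)
    A = _random_A(rng, 8)
    X = rng.normal(size=(8, 5))
    Ws = [rng.normal(size=(5, 4)), rng.normal(size=(4, 4))]
    np.testing.assert_array_equal(
        encode_view(X, A, Ws, cfg), encode_view(X, A.copy(), [w.copy() for w in Ws], cfg)
    )


# ------------------------------------------------------------ attention

def test_attention_zero_transform_gives_zero_scores(rng):
    E = [rng.normal(size=(6, 4)) for _ in range(3)]
    w = attention_scores(E, np.zeros((4, 2)), np.zeros(2), rng.normal(size=2))
    np.testing.assert_array_equal(w, np.zeros(3))


def test_attention_scalar_case_is_tanh_half():
    E = [np.array([[0.5]])]
    w = attention_scores(E, np.ones((1, 1)), np.zeros(1), np.ones(1))
    assert abs(w[0] - np.tanh(0.5)) < 1e-12


def test_attention_permuting_views_permutes_scores(rng):
    E = [rng.normal(size=(6, 4)) for _ in range(3)]
    W, b, q = rng.normal(size=(4, 2)), rng.normal(size=2), rng.normal(size=2)
    w = attention_scores(E, W, b, q)
    w_rev = attention_scores(E[::-1], W, b, q)
    np.testing.assert_allclose(w_rev, w[::-1])


def test_softmax_of_constants_is_uniform():
    np.testing.assert_allclose(attention_weights(np.full(4, 2.7)), np.full(4, 0.25))


def test_softmax_closed_form():
    np.testing.assert_allclose(
        attention_weights(np.array([np.log(2.0), 0.0])), [2 / 3, 1 / 3]
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=-30, max_value=30), min_size=1, max_size=8),
    st.floats(min_value=-100, max_value=100),
)
def test_softmax_simplex_and_shift_invariance(w, shift):
    w = np.array(w)
    beta = attention_weights(w)
    assert np.all(beta > 0) and abs(beta.sum() - 1) < 1e-12
    np.testing.assert_allclose(attention_weights(w + shift), beta, atol=1e-12)


# ------------------------------------------------------------ fusion / head

def test_fuse_single_view_is_identity(rng):
    E = rng.normal(size=(5, 3))
    np.testing.assert_array_equal(fuse([E], np.array([1.0])), E)


def test_fuse_identical_views_any_simplex_weights(rng):
    E = rng.normal(size=(5, 3))
    out = fuse([E, E.copy(), E.copy()], np.array([0.2, 0.5, 0.3]))
    np.testing.assert_allclose(out, E)


def test_fuse_half_half_rows():
    out = fuse([np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])], np.array([0.5, 0.5]))
    np.testing.assert_allclose(out, [[0.5, 0.5]])


def test_classify_constant_bias_wins(rng):
    E = rng.normal(size=(7, 3))
    _, labels = classify(E, np.zeros((3, 3)), np.array([1.0, 0.0, 0.0]))
    assert (labels == 0).all()


def test_classify_hand_set_separating_weights():
    E = np.array([[2.0], [-2.0], [0.5], [-0.1]])
    W = np.array([[1.0, -1.0]])  # class 0 score = e, class 1 score = -e
    scores, labels = classify(E, W, np.zeros(2))
    np.testing.assert_array_equal(labels, [0, 1, 0, 1])
    np.testing.assert_allclose(scores[:, 0], E[:, 0])


# ------------------------------------------------------------ loss

def test_loss_vanishes_in_perfect_fit_limit():
    scores = np.array([[50.0, 0.0], [0.0, 50.0]])
    assert cross_entropy_loss(scores, [0, 1], [0, 1]) < 1e-10


def test_loss_uniform_scores_closed_form():
    n, k = 7, 4
    scores = np.zeros((n + 3, k))  # 3 extra unlabeled nodes
    loss = cross_entropy_loss(scores, np.arange(n), np.zeros(n, dtype=int))
    np.testing.assert_allclose(loss, n * np.log(k))


def test_unlabeled_nodes_do_not_contribute(rng):
    scores = rng.normal(size=(10, 3))
    l1 = cross_entropy_loss(scores, [0, 1, 2], [0, 1, 2])
    bigger = np.vstack([scores, rng.normal(size=(5, 3))])
    l2 = cross_entropy_loss(bigger, [0, 1, 2], [0, 1, 2])
    np.testing.assert_allclose(l1, l2)


def test_empty_labeled_set_raises():
    with pytest.raises(ValueError, match="empty"):
        cross_entropy_loss(np.zeros((3, 2)), [], [])


# ------------------------------------------------------------ full model

def _tiny_problem(rng, n=12, m=5, P=2, K=3, dropout=0.0):
    cfg = ModelConfig(n_classes=K, n_views=P, hidden_dim=4, attention_dim=3,
                      dropout=dropout, seed=1)
    A_list = [_random_A(rng, n) for _ in range(P)]
    X = rng.normal(size=(n, m))
    params = init_params(cfg, m)
    labeled = np.arange(6)
    y = rng.integers(0, K, size=6)
    return cfg, params, X, A_list, labeled, y


def test_gradients_match_numerical_differentiation(rng):
    cfg, params, X, A_list, labeled, y = _tiny_problem(rng)
    loss, grads, _, _ = loss_and_grads(params, X, A_list, labeled, y, cfg,
                                       training=False)
    eps = 1e-6
    flat_p, flat_g = params.flat(), grads.flat()
    for p_arr, g_arr in zip(flat_p, flat_g):
        it = np.nditer(p_arr, flags=["multi_index"])
        # probe a handful of entries per tensor
        probes = 0
        for _ in it:
            if probes >= 4:
                break
            idx = it.multi_index
            orig = p_arr[idx]
            p_arr[idx] = orig + eps
            lp = loss_and_grads(params, X, A_list, labeled, y, cfg, training=False)[0]
            p_arr[idx] = orig - eps
            lm = loss_and_grads(params, X, A_list, labeled, y, cfg, training=False)[0]
            p_arr[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert abs(numeric - g_arr[idx]) < 1e-5 * max(1.0, abs(numeric))
            probes += 1


def test_one_small_gradient_step_reduces_loss(rng):
    cfg, params, X, A_list, labeled, y = _tiny_problem(rng, n=20)
    loss0, grads, _, _ = loss_and_grads(params, X, A_list, labeled, y, cfg,
                                        training=False)
    for p, g in zip(params.flat(), grads.flat()):
        p -= 1e-4 * g
    loss1 = loss_and_grads(params, X, A_list, labeled, y, cfg, training=False)[0]
    assert loss1 < loss0


def test_identical_views_match_single_view_predictions(rng):
    cfg1 = ModelConfig(n_classes=3, n_views=1, hidden_dim=4, attention_dim=3, seed=2)
    A = _random_A(rng, 10)
    X = rng.normal(size=(10, 5))
    params1 = init_params(cfg1, 5)
    scores1, beta1, _ = forward(params1, X, [A], cfg1, training=False)

    cfgP = ModelConfig(n_classes=3, n_views=3, hidden_dim=4, attention_dim=3, seed=2)
    paramsP = MGCNParams(
        gcn_weights=[[W.copy() for W in params1.gcn_weights[0]] for _ in range(3)],
        att_W=params1.att_W, att_b=params1.att_b, att_q=params1.att_q,
        clf_W=params1.clf_W, clf_b=params1.clf_b,
    )
    scoresP, betaP, _ = forward(paramsP, X, [A, A.copy(), A.copy()], cfgP,
                                training=False)
    np.testing.assert_allclose(betaP, np.full(3, 1 / 3))
    np.testing.assert_allclose(scoresP, scores1, atol=1e-12)


def test_eval_forward_is_deterministic(rng):
    cfg, params, X, A_list, _, _ = _tiny_problem(rng, dropout=0.5)
    s1, b1, _ = forward(params, X, A_list, cfg, training=False)
    s2, b2, _ = forward(params, X, A_list, cfg, training=False)
    np.testing.assert_array_equal(s1, s2)
    np.testing.assert_array_equal(b1, b2)


def _extend_with_isolated_node(rng, X, A_list):
    n = X.shape[0]
    X2 = np.vstack([X, rng.normal(size=(1, X.shape[1]))])
    A2 = []
    for A in A_list:
        bigger = np.zeros((n + 1, n + 1))
        bigger[:n, :n] = A
        bigger[n, n] = 1.0  # its own self-loop after normalization
        A2.append(bigger)
    return X2, A2


def test_isolated_unlabeled_node_leaves_loss_unchanged_single_view(rng):
    """Transductive consistency: an edgeless extra node cannot change labeled loss.

    With one view the attention weight is fixed at 1, so the fused embedding
    of the original nodes — and hence the labeled loss — is exactly invariant.
    (With several views the per-view embeddings of the original nodes are
    still invariant, checked below, but the node-averaged attention scores
    shift slightly because the new node participates in the average.)
    """
    cfg, params, X, A_list, labeled, y = _tiny_problem(rng, P=1)
    loss0 = loss_and_grads(params, X, A_list, labeled, y, cfg, training=False)[0]
    X2, A2 = _extend_with_isolated_node(rng, X, A_list)
    loss1 = loss_and_grads(params, X2, A2, labeled, y, cfg, training=False)[0]
    np.testing.assert_allclose(loss0, loss1, rtol=1e-12)


def test_isolated_node_leaves_per_view_embeddings_unchanged(rng):
    cfg, params, X, A_list, _, _ = _tiny_problem(rng)
    X2, A2 = _extend_with_isolated_node(rng, X, A_list)
    n = X.shape[0]
    for A_small, A_big, weights in zip(A_list, A2, params.gcn_weights):
        before = encode_view(X, A_small, weights, cfg)
        after = encode_view(X2, A_big, weights, cfg)
        np.testing.assert_allclose(after[:n], before, rtol=1e-12)


def test_params_roundtrip(tmp_path, rng):
    cfg, params, *_ = _tiny_problem(rng)
    save_params(params, cfg, tmp_path / "p.npz")
    back, cfg2 = load_params(tmp_path / "p.npz")
    assert cfg2.n_classes == cfg.n_classes and cfg2.hidden_dim == cfg.hidden_dim
    for a, b in zip(params.flat(), back.flat()):
        np.testing.assert_array_equal(a, b)


def test_adam_converges_on_quadratic():
    x = [np.array([5.0, -3.0])]
    opt = Adam(x, lr=0.1)
    for _ in range(500):
        opt.step([2 * x[0]])
    assert np.abs(x[0]).max() < 1e-3
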