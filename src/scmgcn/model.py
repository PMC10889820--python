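"""The multi-view graph convolutional network.

Every view p has its own stack of graph-convolution layers

    H^(l+1) = sigma(A_norm_p H^(l) W_p^(l)),    H^(0) = X,

all views sharing the input feature matrix X.  The per-view embeddings
E_1..E_P are fused by a node-averaged attention score

    w_p = mean_i  q . tanh(W_a e_i^p + b_a),      beta = softmax(w),
    E    = sum_p beta_p E_p,

and a single linear layer maps the fused embedding to class scores.  The
training loss is the cross-entropy of the log-softmaxed scores over the
labeled (reference training) nodes only; all other nodes participate in
message passing but not in the loss (transductive semi-supervised learning).

Everything here is plain NumPy with hand-written backpropagation; the
gradients are verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ModelConfig",
    "MGCNParams",
    "init_params",
    "gcn_layer",
    "encode_view",
    "attention_scores",
    "attention_weights",
    "fuse",
    "classify",
    "cross_entropy_loss",
    "forward",
    "loss_and_grads",
    "save_params",
    "load_params",
]

_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(x.dtype)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


@dataclass
class ModelConfig:
    n_classes: int
    n_views: int
    n_layers: int = 2
    hidden_dim: int = 64
    activation: str = "relu"
    dropout: float = 0.5
    attention_dim: int = 64
    loss_reduction: str = "sum"  # "sum" (as defined) or "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_views < 1 or self.n_classes < 1:
            raise ValueError("n_layers, n_views and n_classes must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")


@dataclass
class MGCNParams:
    """All learnable parameters.

    ``gcn_weights[p][l]`` is view p's layer-l weight matrix (input_dim × h
    for l = 0, h × h after).  The attention transform (W_a, b_a) and vector
    q are shared across views; (clf_W, clf_b) is the linear classifier.
    """

    gcn_weights: list  # per view, per layer
    att_W: np.ndarray
    att_b: np.ndarray
    att_q: np.ndarray
    clf_W: np.ndarray
    clf_b: np.ndarray

    def flat(self) -> list[np.ndarray]:
        out = [W for view in self.gcn_weights for W in view]
        out += [self.att_W, self.att_b, self.att_q, self.clf_W, self.clf_b]
        return out

    def decay_mask(self) -> list[bool]:
        mask = [True for view in self.gcn_weights for _ in view]
        mask += [True, False, True, True, False]
        return mask

    def copy(self) -> "MGCNParams":
        return MGCNParams(
            gcn_weights=[[W.copy() for W in view] for view in self.gcn_weights],
            att_W=self.att_W.copy(),
            att_b=self.att_b.copy(),
            att_q=self.att_q.copy(),
            clf_W=self.clf_W.copy(),
            clf_b=self.clf_b.copy(),
        )


def init_params(cfg: ModelConfig, n_features: int, dtype=np.float64) -> MGCNParams:
    """Glorot-uniform initialization, seeded from the model config."""
    rng = np.random.default_rng([cfg.seed, 7])

    def glorot(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)

    h, a = cfg.hidden_dim, cfg.attention_dim
    gcn = []
    for _ in range(cfg.n_views):
        dims = [n_features] + [h] * cfg.n_layers
        gcn.append([glorot(dims[l], dims[l + 1]) for l in range(cfg.n_layers)])
    return MGCNParams(
        gcn_weights=gcn,
        att_W=glorot(h, a),
        att_b=np.zeros(a, dtype=dtype),
        att_q=glorot(a, 1)[:, 0],
        clf_W=glorot(h, cfg.n_classes),
        clf_b=np.zeros(cfg.n_classes, dtype=dtype),
    )


# --------------------------------------------------------------------------
# functional building blocks
# --------------------------------------------------------------------------

def gcn_layer(H, A_norm, W, activation: str = "relu") -> np.ndarray:
    """One graph convolution: activation(A_norm @ H @ W)."""
    H = np.asarray(H)
    if A_norm.shape[0] != A_norm.shape[1] or A_norm.shape[1] != H.shape[0]:
        raise ValueError(
            f"A_norm shape {A_norm.shape} incompatible with H shape {H.shape}"
        )
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"H width {H.shape[1]} != W input dim {W.shape[0]}")
    act, _ = _ACTIVATIONS[activation]
    out = act(A_norm @ (H @ W))
    out = np.asarray(out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite output from graph convolution layer")
    return out


def encode_view(
    X,
    A_norm,
    view_weights: list,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stacked graph convolutions for one view (dropout between layers)."""
    H = np.asarray(X)
    for l, W in enumerate(view_weights):
        H = gcn_layer(H, A_norm, W, cfg.activation)
        if training and cfg.dropout > 0 and l < len(view_weights) - 1:
            if rng is None:
                rng = np.random.default_rng(cfg.seed)
            keep = 1.0 - cfg.dropout
            mask = (rng.random(H.shape) < keep).astype(H.dtype)
            H = H * mask / keep
    return H


def attention_scores(embeddings: list, att_W, att_b, att_q) -> np.ndarray:
    """Per-view importance: mean over nodes of q . tanh(W_a e_i + b_a)."""
    shapes = {e.shape for e in embeddings}
    if len(shapes) != 1:
        raise ValueError("all view embeddings must share a shape")
    if next(iter(shapes))[1] != att_W.shape[0]:
        raise ValueError("embedding width does not match attention transform")
    return np.array(
        [float(np.mean(np.tanh(E @ att_W + att_b) @ att_q)) for E in embeddings]
    )


def attention_weights(w: np.ndarray) -> np.ndarray:
    """Softmax of the view scores (max-subtracted for stability)."""
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("attention scores must be finite")
    z = np.exp(w - w.max())
    return z / z.sum()


def fuse(embeddings: list, beta: np.ndarray) -> np.ndarray:
    """Convex combination of the view embeddings, node-wise."""
    if len(beta) != len(embeddings):
        raise ValueError("one weight per view required")
    out = np.zeros_like(embeddings[0])
    for b, E in zip(beta, embeddings):
        out = out + b * E
    return out


def classify(E, clf_W, clf_b) -> tuple[np.ndarray, np.ndarray]:
    """Linear class scores and argmax labels (ties -> smallest class index)."""
    if E.shape[1] != clf_W.shape[0]:
        raise ValueError("embedding width does not match classifier")
    scores = E @ clf_W + clf_b
    return scores, np.argmax(scores, axis=1)


def _log_softmax(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def cross_entropy_loss(
    scores: np.ndarray,
    labeled_idx: np.ndarray,
    labels: np.ndarray,
    reduction: str = "sum",
) -> float:
    """Cross-entropy of softmaxed scores over the labeled nodes only."""
    labeled_idx = np.asarray(labeled_idx, dtype=int)
    if labeled_idx.size == 0:
        raise ValueError("the labeled node set is empty")
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= scores.shape[1]:
        raise ValueError("labels out of class range")
    logp = _log_softmax(scores[labeled_idx])
    nll = -logp[np.arange(len(labeled_idx)), labels]
    return float(nll.sum() if reduction == "sum" else nll.mean())


# --------------------------------------------------------------------------
# full forward / backward
# --------------------------------------------------------------------------

def forward(
    params: MGCNParams,
    X: np.ndarray,
    A_list: list,
    cfg: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Full forward pass; returns (scores, beta, cache for backprop)."""
    if len(A_list) != len(params.gcn_weights):
        raise ValueError("one normalized adjacency per view required")
    act, dact = _ACTIVATIONS[cfg.activation]
    keep = 1.0 - cfg.dropout
    caches = []
    embeddings = []
    for A, weights in zip(A_list, params.gcn_weights):
        H = X
        Zs, Ss, masks = [], [], []
        for l, W in enumerate(weights):
            Z = A @ H
            S = Z @ W
            H = act(S)
            Zs.append(Z)
            Ss.append(S)
            if training and cfg.dropout > 0 and l < len(weights) - 1:
                mask = (rng.random(H.shape) < keep).astype(H.dtype)
                H = H * mask / keep
                masks.append(mask)
            else:
                masks.append(None)
        embeddings.append(H)
        caches.append({"Z": Zs, "S": Ss, "mask": masks})

    n = X.shape[0]
    Ms = [np.tanh(E @ params.att_W + params.att_b) for E in embeddings]
    w = np.array([float(np.mean(M @ params.att_q)) for M in Ms])
    beta = attention_weights(w)
    E = fuse(embeddings, beta)
    scores = E @ params.clf_W + params.clf_b
    cache = {
        "views": caches,
        "embeddings": embeddings,
        "Ms": Ms,
        "w": w,
        "beta": beta,
        "E": E,
        "n": n,
        "act": (act, dact),
        "keep": keep,
    }
    return scores, beta, cache


def _backward(params: MGCNParams, X, A_list, cfg: ModelConfig, cache, d_scores):
    """Gradients of the loss wrt every parameter, given d(loss)/d(scores)."""
    _, dact = cache["act"]
    E, beta = cache["E"], cache["beta"]
    embeddings, Ms, n = cache["embeddings"], cache["Ms"], cache["n"]
    P = len(embeddings)

    g_clf_W = E.T @ d_scores
    g_clf_b = d_scores.sum(axis=0)
    dE = d_scores @ params.clf_W.T

    # fused E = sum_p beta_p E_p
    d_beta = np.array([float(np.sum(dE * embeddings[p])) for p in range(P)])
    dE_p = [beta[p] * dE for p in range(P)]

    # softmax backward
    dw = beta * (d_beta - float(beta @ d_beta))

    # w_p = mean_i M_p[i] . q
    g_att_W = np.zeros_like(params.att_W)
    g_att_b = np.zeros_like(params.att_b)
    g_att_q = np.zeros_like(params.att_q)
    for p in range(P):
        M = Ms[p]
        g_att_q += dw[p] * M.mean(axis=0)
        dM = (dw[p] / n) * np.outer(np.ones(n), params.att_q)
        dPre = dM * (1.0 - M**2)
        g_att_W += embeddings[p].T @ dPre
        g_att_b += dPre.sum(axis=0)
        dE_p[p] = dE_p[p] + dPre @ params.att_W.T

    g_gcn = []
    for p in range(P):
        weights = params.gcn_weights[p]
        vc = cache["views"][p]
        dH = dE_p[p]
        g_view = [None] * len(weights)
        for l in range(len(weights) - 1, -1, -1):
            if vc["mask"][l] is not None:
                dH = dH * vc["mask"][l] / cache["keep"]
            dS = dH * dact(vc["S"][l])
            g_view[l] = vc["Z"][l].T @ dS
            if l > 0:
                dZ = dS @ weights[l].T
                dH = A_list[p].T @ dZ
        g_gcn.append(g_view)

    return MGCNParams(
        gcn_weights=g_gcn,
        att_W=g_att_W,
        att_b=g_att_b,
        att_q=g_att_q,
        clf_W=g_clf_W,
        clf_b=g_clf_b,
    )


def loss_and_grads(
    params: MGCNParams,
    X: np.ndarray,
    A_list: list,
    labeled_idx: np.ndarray,
    labels: np.ndarray,
    cfg: ModelConfig,
    training: bool = True,
    rng: np.random.Generator | None = None,
):
    """Loss, parameter gradients, and class scores in one pass."""
    scores, beta, cache = forward(params, X, A_list, cfg, training=training, rng=rng)
    labeled_idx = np.asarray(labeled_idx, dtype=int)
    labels = np.asarray(labels, dtype=int)
    loss = cross_entropy_loss(scores, labeled_idx, labels, cfg.loss_reduction)

    logp = _log_softmax(scores[labeled_idx])
    probs = np.exp(logp)
    probs[np.arange(len(labeled_idx)), labels] -= 1.0
    if cfg.loss_reduction == "mean":
        probs /= len(labeled_idx)
    d_scores = np.zeros_like(scores)
    d_scores[labeled_idx] = probs.astype(scores.dtype)

    grads = _backward(params, X, A_list, cfg, cache, d_scores)
    return loss, grads, scores, beta


# --------------------------------------------------------------------------
# serialization: NPZ archive + JSON manifest
# --------------------------------------------------------------------------

def save_params(params: MGCNParams, cfg: ModelConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for p, view in enumerate(params.gcn_weights):
        for l, W in enumerate(view):
            arrays[f"gcn_{p}_{l}"] = W
    arrays.update(
        att_W=params.att_W, att_b=params.att_b, att_q=params.att_q,
        clf_W=params.clf_W, clf_b=params.clf_b,
    )
    np.savez(path, **arrays)
    manifest = {
        "n_views": len(params.gcn_weights),
        "n_layers": len(params.gcn_weights[0]),
        "config": {
            "n_classes": cfg.n_classes, "n_views": cfg.n_views,
            "n_layers": cfg.n_layers, "hidden_dim": cfg.hidden_dim,
            "activation": cfg.activation, "dropout": cfg.dropout,
            "attention_dim": cfg.attention_dim,
            "loss_reduction": cfg.loss_reduction, "seed": cfg.seed,
        },
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=1))


def load_params(path) -> tuple[MGCNParams, ModelConfig]:
    manifest = json.loads(Path(str(path) + ".json").read_text())
    data = np.load(path)
    gcn = [
        [data[f"gcn_{p}_{l}"] for l in range(manifest["n_layers"])]
        for p in range(manifest["n_views"])
    ]
    params = MGCNParams(
        gcn_weights=gcn, att_W=data["att_W"], att_b=data["att_b"],
        att_q=data["att_q"], clf_W=data["clf_W"], clf_b=data["clf_b"],
    )
    return params, ModelConfig(**manifest["config"])
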