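"""Nearest-neighbour search: exact brute force and random-projection forests.

Exact search computes full pairwise distances and is the default (datasets
at the scale this package targets fit comfortably).  The approximate path
is a forest of random-projection trees — each tree recursively splits the
points by the hyperplane bisecting two randomly chosen points; a query
descends every tree and the union of reached leaves forms the candidate set,
which is then ranked exactly.

Ties in distance are always broken by smaller target index, so results are
deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["knn_indices", "RPForest"]


def _pairwise(source: np.ndarray, target: np.ndarray, metric: str) -> np.ndarray:
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    return cdist(source, target, metric=metric)


def knn_indices(
    source: np.ndarray,
    target: np.ndarray,
    k: int,
    metric: str = "euclidean",
    exclude_self: bool = False,
) -> np.ndarray:
    """Exact k-nearest-neighbour indices of each source point among targets.

    ``exclude_self=True`` removes the pairing (i, i) — used when source and
    target are the same point set.  Ties are broken by smaller target index
    (stable sort).  ``k`` is clamped to the number of valid targets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_t = target.shape[0]
    max_k = n_t - 1 if exclude_self else n_t
    if max_k < 1:
        raise ValueError("no valid neighbour targets")
    if k > max_k:
        import warnings

        warnings.warn(f"k={k} exceeds {max_k} valid targets; clamping")
        k = max_k
    dist = _pairwise(source, target, metric)
    if exclude_self:
        np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    return order[:, :k]


class RPForest:
    """Forest of random-projection trees over a fixed target point set.

    Each internal node stores the hyperplane bisecting two randomly chosen
    points of its subset; leaves hold at most ``leaf_size`` point indices.
    Querying returns, for each query point, the union of leaf members over
    all trees as candidates, re-ranked by exact distance.
    """

    def __init__(
        self,
        target: np.ndarray,
        n_trees: int = 10,
        leaf_size: int = 64,
        seed: int = 0,
        metric: str = "euclidean",
    ) -> None:
        self.target = np.asarray(target, dtype=float)
        self.metric = metric
        self.leaf_size = max(2, leaf_size)
        rng = np.random.default_rng([seed, 53])
        self.trees = [
            self._build(np.arange(len(self.target)), rng) for _ in range(n_trees)
        ]

    def _build(self, idx: np.ndarray, rng: np.random.Generator):
        if len(idx) <= self.leaf_size:
            return ("leaf", idx)
        pts = self.target[idx]
        for _ in range(8):  # retry degenerate (coincident) pivot draws
            a, b = rng.choice(len(idx), size=2, replace=False)
            normal = pts[a] - pts[b]
            norm = np.linalg.norm(normal)
            if norm > 1e-12:
                break
        else:
            return ("leaf", idx)
        normal = normal / norm
        offset = normal @ (pts[a] + pts[b]) / 2.0
        proj = pts @ normal
        left = proj < offset
        if not left.any() or left.all():
            # numerically flat split: fall back to median split
            offset = np.median(proj)
            left = proj < offset
            if not left.any() or left.all():
                return ("leaf", idx)
        return (
            "node",
            normal,
            offset,
            self._build(idx[left], rng),
            self._build(idx[~left], rng),
        )

    def _leaf(self, tree, point: np.ndarray) -> np.ndarray:
        while tree[0] == "node":
            _, normal, offset, left, right = tree
            tree = left if point @ normal < offset else right
        return tree[1]

    def query(self, source: np.ndarray, k: int, exclude_self: bool = False):
        """Approximate k nearest targets for every source row.

        Returns an object array of index arrays (row lengths may differ when
        a candidate set is smaller than ``k``).
        """
        source = np.asarray(source, dtype=float)
        out = []
        for i, point in enumerate(source):
            cand = np.unique(np.concatenate([self._leaf(t, point) for t in self.trees]))
            if exclude_self:
                cand = cand[cand != i]
            dist = _pairwise(point[None, :], self.target[cand], self.metric)[0]
            order = np.argsort(dist, kind="stable")[:k]
            out.append(cand[order])
        return out
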