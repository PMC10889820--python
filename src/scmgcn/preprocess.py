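"""Preprocessing: doublet removal, gene matching, ANOVA HVG selection, normalization.

The pipeline for a reference/query pair is:

1. :func:`filter_doublets` on each raw-count dataset — a self-contained
   simulation-based scorer (synthetic pair-sum doublets, truncated-SVD
   embedding, KNN doublet-neighbour fraction).
2. :func:`match_genes` — keep genes expressed in both datasets and align
   gene order.
3. :func:`select_hvg_anova` on the reference — one-way ANOVA of expression
   across cell types, Bonferroni-adjusted, top ``n_hvg`` genes.
4. :func:`normalize_total` — total-count scaling to ``target_sum`` per cell
   followed (by default) by log1p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .datasets import ExpressionDataset

__all__ = [
    "PreprocessConfig",
    "filter_doublets",
    "match_genes",
    "select_hvg_anova",
    "normalize_total",
    "preprocess_pair",
]


@dataclass
class PreprocessConfig:
    n_hvg: int = 2000
    bonferroni_alpha: float = 0.05
    doublet_rate_expected: float = 0.06
    doublet_knn_k: int = 20
    target_sum: float = 1e4
    min_reads_per_gene: int = 1
    log_transform: bool = True
    filter_doublets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if not 0 < self.bonferroni_alpha <= 1:
            raise ValueError("bonferroni_alpha must be in (0, 1]")
        if not 0 <= self.doublet_rate_expected < 1:
            raise ValueError("doublet_rate_expected must be in [0, 1)")


def _scale_rows_to_target(matrix: sp.csr_matrix, target_sum: float) -> sp.csr_matrix:
    sums = np.asarray(matrix.sum(axis=1)).ravel()
    scale = np.divide(target_sum, sums, out=np.zeros_like(sums, dtype=float),
                      where=sums > 0)
    return sp.diags(scale) @ matrix


def normalize_total(
    ds: ExpressionDataset, target_sum: float = 1e4, log1p: bool = True
) -> ExpressionDataset:
    """Scale every cell to the same total count, then (optionally) log1p.

    Cells with zero total count cannot be scaled and are dropped with a
    warning.  The scaling step is idempotent; the returned dataset is
    flagged ``normalized``.
    """
    sums = np.asarray(ds.matrix.sum(axis=1)).ravel()
    keep = sums > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-zero cells")
        ds = ds.subset_cells(np.where(keep)[0])
    matrix = _scale_rows_to_target(sp.csr_matrix(ds.matrix, dtype=float), target_sum)
    if log1p:
        matrix = matrix.copy()
        matrix.data = np.log1p(matrix.data)
    return replace(ds, matrix=matrix, normalized=True)


def match_genes(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    cfg: PreprocessConfig | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to shared genes expressed in each of them.

    A gene is kept when its total read count is at least
    ``min_reads_per_gene`` in the reference AND in the query; both outputs
    carry the surviving genes in the same (sorted) order.
    """
    cfg = cfg or PreprocessConfig()
    thr = cfg.min_reads_per_gene

    def expressed(ds: ExpressionDataset) -> set:
        totals = np.asarray(ds.matrix.sum(axis=0)).ravel()
        return {g for g, t in zip(ds.gene_ids, totals) if t >= thr}

    shared = sorted(expressed(ref) & expressed(query))
    if not shared:
        raise ValueError("no shared expressed genes between reference and query")
    return ref.reorder_genes(shared), query.reorder_genes(shared)


def _anova_f_by_type(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across label groups for every gene (column).

    Returns (F, p).  Genes with zero between- and within-group variance get
    F = nan; zero within-group variance with signal gets F = inf, p = 0.
    """
    n, m = X.shape
    groups = np.unique(labels)
    k = len(groups)
    grand = X.mean(axis=0)
    ssb = np.zeros(m)
    ssw = np.zeros(m)
    for g in groups:
        sub = X[labels == g]
        mu = sub.mean(axis=0)
        ssb += len(sub) * (mu - grand) ** 2
        ssw += ((sub - mu) ** 2).sum(axis=0)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(np.isinf(F), 0.0, p)
    return F, p


def select_hvg_anova(
    ref: ExpressionDataset,
    cfg: PreprocessConfig | None = None,
    return_stats: bool = False,
):
    """Select highly variable genes by one-way ANOVA across reference cell types.

    Expression (normalized + log1p, applied internally when the input is
    raw) is tested per gene for differences across cell types; p-values are
    Bonferroni-adjusted (``p_adj = min(1, p * n_tested)``) and the ``n_hvg``
    genes with the smallest adjusted p-values are returned, ties broken by
    larger F statistic and then by gene id.  Genes with zero variance across
    all cells are excluded before testing.
    """
    cfg = cfg or PreprocessConfig()
    if ref.labels is None or len(np.unique(ref.labels)) < 2:
        raise ValueError("HVG selection requires reference labels with >= 2 types")
    counts = np.unique(ref.labels, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("every cell type needs >= 2 cells for ANOVA")

    work = ref if ref.normalized else normalize_total(ref, cfg.target_sum, cfg.log_transform)
    X = work.dense()
    variances = X.var(axis=0)
    testable = variances > 0
    if not testable.any():
        raise ValueError("no variable genes to test")

    F = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    F[testable], p[testable] = _anova_f_by_type(X[:, testable], work.labels)
    n_tested = int(testable.sum())
    p_adj = np.minimum(1.0, p * n_tested)

    idx = np.where(testable)[0]
    order = sorted(
        idx, key=lambda i: (p_adj[i], -F[i], str(work.gene_ids[i]))
    )
    if len(order) < cfg.n_hvg:
        warnings.warn(
            f"only {len(order)} testable genes for n_hvg={cfg.n_hvg}; returning all"
        )
    selected = [work.gene_ids[i] for i in order[: cfg.n_hvg]]
    if return_stats:
        import pandas as pd

        table = pd.DataFrame(
            {
                "gene_id": list(work.gene_ids),
                "F": F,
                "p": p,
                "p_adj": p_adj,
                "significant": p_adj <= cfg.bonferroni_alpha,
            }
        )
        return selected, table
    return selected


def doublet_scores(
    ds: ExpressionDataset, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulation-based doublet scores for every observed cell.

    Synthesizes ``doublet_rate_expected * n`` artificial doublets by summing
    counts of random cell pairs, embeds observed + synthetic cells with a
    30-component truncated SVD of log1p-normalized counts, and scores each
    observed cell as the fraction of synthetic doublets among its
    ``doublet_knn_k`` nearest neighbours.

    Returns (scores for observed cells, scores for synthetic doublets).
    """
    rng = np.random.default_rng([cfg.seed, 97])
    n = ds.n_cells
    n_sim = max(1, int(round(cfg.doublet_rate_expected * n)))
    pairs = rng.integers(0, n, size=(n_sim, 2))
    synth = ds.matrix[pairs[:, 0]] + ds.matrix[pairs[:, 1]]
    combined = sp.vstack([sp.csr_matrix(ds.matrix, dtype=float), synth])
    combined = _scale_rows_to_target(combined, cfg.target_sum)
    combined.data = np.log1p(combined.data)

    n_comp = min(30, min(combined.shape) - 1)
    emb = TruncatedSVD(n_components=n_comp, random_state=int(cfg.seed) % (2**31)).fit_transform(
        combined
    )
    k = min(cfg.doublet_knn_k, combined.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    idx = idx[:, 1:]  # drop self
    is_synth = idx >= n
    frac = is_synth.mean(axis=1)
    return frac[:n], frac[n:]


def filter_doublets(
    ds: ExpressionDataset, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionDataset, list]:
    """Remove likely doublets from a raw-count dataset.

    Cells scoring above the ``1 - doublet_rate_expected`` quantile of the
    observed-cell score distribution are removed.  With an expected rate of
    zero the dataset is returned unchanged; datasets too small for the KNN
    scorer are skipped with a warning.  Deterministic given the config seed.
    """
    cfg = cfg or PreprocessConfig()
    if ds.normalized:
        raise ValueError("doublet filtering expects raw counts")
    if cfg.doublet_rate_expected == 0:
        return ds, []
    if ds.n_cells < cfg.doublet_knn_k + 1:
        warnings.warn("too few cells for doublet scoring; skipping filter")
        return ds, []
    scores, _ = doublet_scores(ds, cfg)
    threshold = np.quantile(scores, 1.0 - cfg.doublet_rate_expected)
    remove = scores > threshold
    removed_ids = list(ds.cell_ids[remove])
    return ds.subset_cells(np.where(~remove)[0]), removed_ids


def preprocess_pair(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    cfg: PreprocessConfig | None = None,
) -> tuple[ExpressionDataset, ExpressionDataset, list]:
    """Full preprocessing of a reference/query pair.

    Doublet-filters both raw datasets, matches genes, selects HVGs on the
    reference, restricts both to the HVG set (reference gene order) and
    normalizes.  Returns (reference, query, selected gene ids).
    """
    cfg = cfg or PreprocessConfig()
    if cfg.filter_doublets and not ref.normalized:
        ref, _ = filter_doublets(ref, cfg)
    if cfg.filter_doublets and not query.normalized:
        query, _ = filter_doublets(query, cfg)
    ref, query = match_genes(ref, query, cfg)
    hvg = select_hvg_anova(ref, cfg)
    ref = ref.reorder_genes(hvg)
    query = query.reorder_genes(hvg)
    ref = normalize_total(ref, cfg.target_sum, cfg.log_transform)
    query = normalize_total(query, cfg.target_sum, cfg.log_transform)
    return ref, query, hvg
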