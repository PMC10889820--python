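"""Synthetic paired reference/query scRNA-seq datasets with ground truth.

The generator draws per-type gene-expression profiles, then samples counts
with the standard scRNA-seq noise model: negative-binomial counts around a
per-cell mean that combines the type profile, a log-normal library-size
factor, and a multiplicative per-batch per-gene factor, followed by logistic
dropout.  Reference and query batches share the profiles but get independent
batch factors, so the pair exhibits exactly the kind of systematic
cross-dataset shift that label transfer must overcome.

All randomness flows from ``SimConfig.seed``; a batch's stream is derived
from ``(seed, batch_id)`` so the reference and query draws are independent
but individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datasets import ExpressionDataset

__all__ = ["SimConfig", "make_type_profiles", "simulate_batch", "make_ref_query_pair"]

# Baseline per-gene mean expression ~ LogNormal(ln 0.5, 1): mean counts per
# cell of ~1.6k over 2000 genes, i.e. sparse 10x-like matrices.
_BASE_MEAN_LOG = np.log(0.5)
_BASE_SIGMA = 1.0


@dataclass
class SimConfig:
    """Study conditions for the paired-batch simulation.

    ``marker_log_fc`` is a natural-log fold change: each type's disjoint
    block of ``n_marker_per_type`` marker genes is up-regulated by
    ``exp(marker_log_fc)`` in that type only.  ``batch_effect_sigma`` is the
    standard deviation of the per-batch per-gene multiplicative log-normal
    factor; 0 disables the batch effect.  ``dropout_midpoint`` is the mean
    expression at which the logistic dropout probability equals 0.5.
    """

    n_types: int = 5
    n_genes: int = 2000
    n_marker_per_type: int = 50
    marker_log_fc: float = 2.0
    n_ref_cells: int = 500
    n_query_cells: int = 500
    nb_dispersion: float = 0.3
    libsize_lognorm_sigma: float = 0.3
    dropout_midpoint: float = 1.0
    batch_effect_sigma: float = 0.5
    type_proportions: tuple | None = None
    rare_type_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_marker_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.nb_dispersion <= 0 or self.marker_log_fc < 0:
            raise ValueError("nb_dispersion must be positive, marker_log_fc >= 0")
        if self.batch_effect_sigma < 0:
            raise ValueError("batch_effect_sigma must be non-negative")
        if self.type_proportions is not None:
            p = np.asarray(self.type_proportions, dtype=float)
            if len(p) != self.n_types or not np.isclose(p.sum(), 1.0):
                raise ValueError("type_proportions must be a length-n_types simplex")

    def proportions(self) -> np.ndarray:
        if self.type_proportions is not None:
            return np.asarray(self.type_proportions, dtype=float)
        if self.rare_type_fraction is not None:
            rare = float(self.rare_type_fraction)
            rest = (1.0 - rare) / (self.n_types - 1)
            return np.array([rest] * (self.n_types - 1) + [rare])
        return np.full(self.n_types, 1.0 / self.n_types)


def make_type_profiles(cfg: SimConfig) -> np.ndarray:
    """Draw the genes × types matrix of mean expression levels.

    Baseline means are log-normal and shared across types; type ``t`` then
    has its own disjoint marker block (genes ``t*K .. (t+1)*K-1`` for
    ``K = n_marker_per_type``) multiplied by ``exp(marker_log_fc)``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    base = rng.lognormal(_BASE_MEAN_LOG, _BASE_SIGMA, size=cfg.n_genes)
    profiles = np.tile(base[:, None], (1, cfg.n_types))
    k = cfg.n_marker_per_type
    for t in range(cfg.n_types):
        profiles[t * k : (t + 1) * k, t] *= np.exp(cfg.marker_log_fc)
    return profiles


def marker_gene_ids(cfg: SimConfig) -> list[str]:
    """Gene ids of all planted marker genes (the first n_types*K genes)."""
    return [f"g{i}" for i in range(cfg.n_types * cfg.n_marker_per_type)]


def dropout_probability(mean: np.ndarray, midpoint: float) -> np.ndarray:
    """Logistic dropout in log-mean: p = midpoint / (midpoint + mean)."""
    return midpoint / (midpoint + mean)


def expected_observed_mean(mean: np.ndarray, midpoint: float) -> np.ndarray:
    """Closed-form dropout-adjusted mean: mu * (1 - p_dropout(mu))."""
    return mean * (1.0 - dropout_probability(mean, midpoint))


def simulate_batch(
    profiles: np.ndarray,
    n_cells: int,
    batch_id: int,
    cfg: SimConfig,
    role: str = "reference",
) -> ExpressionDataset:
    """Sample one batch of cells from the given type profiles.

    Per cell: a type from the configured proportions and a log-normal
    library factor.  Per gene: a batch-wide multiplicative factor
    ``exp(N(0, batch_effect_sigma))``.  Counts are negative-binomial with
    size ``1/nb_dispersion`` around the combined mean, then thinned by
    logistic dropout.
    """
    n_genes, n_types = profiles.shape
    rng = np.random.default_rng([cfg.seed, 1 + int(batch_id)])

    types = rng.choice(n_types, size=n_cells, p=cfg.proportions())
    lib = rng.lognormal(0.0, cfg.libsize_lognorm_sigma, size=n_cells)
    batch_factor = np.exp(rng.normal(0.0, cfg.batch_effect_sigma, size=n_genes))

    mean = profiles[:, types].T * lib[:, None] * batch_factor[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int64)
    keep = rng.random(mean.shape) >= dropout_probability(mean, cfg.dropout_midpoint)
    counts *= keep

    labels = np.array([f"type_{t}" for t in types], dtype=object)
    cell_ids = np.array([f"b{batch_id}_c{i}" for i in range(n_cells)], dtype=object)
    gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    return ExpressionDataset(
        matrix=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        labels=labels,
        role=role,
    )


def make_ref_query_pair(cfg: SimConfig) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Simulate a labeled reference batch and a query batch with held-out labels.

    Both batches share the same type profiles and gene ids but receive
    independent batch factors.  Query labels are attached for evaluation
    only; training code must never read them.
    """
    profiles = make_type_profiles(cfg)
    ref = simulate_batch(profiles, cfg.n_ref_cells, 0, cfg, role="reference")
    query = simulate_batch(profiles, cfg.n_query_cells, 1, cfg, role="query")
    return ref, query
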