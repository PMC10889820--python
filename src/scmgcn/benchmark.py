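"""The standard synthetic cross-batch label-transfer benchmark.

One run: simulate a reference/query pair under the default study conditions
(5 types, 2000 genes, 500+500 cells, multiplicative per-gene batch effect),
preprocess, build all requested views once, then train and score

* the multi-view model on all views,
* optionally each single view through the identical harness (the ablation),
* the naive 1-NN cross-batch baseline on the same preprocessed matrices.
"""

from __future__ import annotations

import numpy as np

from .graphs import GRAPH_METHODS, GraphConfig, MultiViewBundle, build_view
from .model import ModelConfig
from .preprocess import PreprocessConfig, preprocess_pair
from .simulate import SimConfig, make_ref_query_pair
from .train import (
    LabelEncoder,
    TrainConfig,
    evaluate,
    make_splits,
    nearest_neighbor_baseline,
    predict,
    train_model,
)

__all__ = ["benchmark_label_transfer"]


def benchmark_label_transfer(
    seed: int,
    methods=GRAPH_METHODS,
    include_single_views: bool = True,
    sim_cfg: SimConfig | None = None,
) -> dict:
    """Run the benchmark once; returns accuracies, macro-F1s and view weights."""
    sim_cfg = sim_cfg or SimConfig(seed=seed)
    ref, query = make_ref_query_pair(sim_cfg)
    ref_p, query_p, _ = preprocess_pair(ref, query, PreprocessConfig(seed=seed))

    graph_cfg = GraphConfig(seed=seed)
    views = {m: build_view(ref_p, query_p, m, graph_cfg) for m in methods}
    X = np.vstack([ref_p.dense(), query_p.dense()]).astype(np.float32)
    encoder = LabelEncoder(ref_p.labels)
    y = encoder.encode(ref_p.labels)
    split = make_splits(ref_p.labels, "cross_dataset", seed=seed, n_folds=1)[0]
    truth = np.asarray(query_p.labels)

    def run(view_list):
        bundle = MultiViewBundle(features=X, views=view_list,
                                 n_ref=ref_p.n_cells, n_query=query_p.n_cells)
        model_cfg = ModelConfig(n_classes=len(encoder.classes_),
                                n_views=len(view_list), seed=seed)
        params, _ = train_model(bundle, y, split, model_cfg, TrainConfig(seed=seed))
        codes, _, beta = predict(params, bundle, model_cfg)
        return evaluate(encoder.decode(codes), truth), beta

    multi_report, beta = run([views[m] for m in methods])
    result = {
        "seed": seed,
        "n_query": query_p.n_cells,
        "multiview_accuracy": multi_report.accuracy,
        "multiview_macro_f1": multi_report.macro_f1,
        "beta": {m: float(b) for m, b in zip(methods, beta)},
    }

    baseline_report = evaluate(nearest_neighbor_baseline(ref_p, query_p), truth)
    result["baseline_1nn_accuracy"] = baseline_report.accuracy

    if include_single_views:
        result["single_view_accuracy"] = {
            m: run([views[m]])[0].accuracy for m in methods
        }
    return result
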