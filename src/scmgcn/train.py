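"""Transductive training, the evaluation protocol, and the experiment harness.

Training is full-graph and transductive: every forward pass runs on all
reference and query nodes, the cross-entropy loss is taken over the labeled
reference training nodes only, a held-out labeled validation subset drives
early stopping, and query nodes receive predictions from the best-validation
parameters.

The evaluation protocol mirrors standard benchmarking practice for label
transfer: within one annotated dataset, cells are split 60/40 into a
training pool and a test set stratified by type, the pool is split 80/20
into train/validation within each type, and the whole procedure is repeated
over five folds.  Across datasets, the full reference supplies train/val
(80/20 per type) and the entire query is the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .graphs import GRAPH_METHODS, GraphConfig, MultiViewBundle, build_bundle
from .model import (
    MGCNParams,
    ModelConfig,
    forward,
    init_params,
    loss_and_grads,
)
from .optim import Adam
from .preprocess import PreprocessConfig, preprocess_pair
from .neighbors import knn_indices

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "EvalReport",
    "make_splits",
    "train_model",
    "predict",
    "evaluate",
    "run_experiment",
    "nearest_neighbor_baseline",
]


@dataclass
class SplitPlan:
    """Index sets for one fold (indices into the labeled cell array)."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray  # empty in cross-dataset mode (test = whole query)
    fold_index: int = 0
    n_folds: int = 5
    seed: int = 0
    mode: str = "single_dataset"


@dataclass
class TrainConfig:
    max_epochs: int = 200
    patience: int = 20
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class EvalReport:
    accuracy: float
    per_class: pd.DataFrame  # precision, recall, f1, support per class
    macro_f1: float
    micro_f1: float
    confusion: np.ndarray
    classes: list


def _split_label_group(members: np.ndarray, rng, test_frac=0.4, val_frac=0.2):
    """Stratified 60/40 pool/test then 80/20 train/val split of one label's cells."""
    members = rng.permutation(members)
    n = len(members)
    n_test = int(round(test_frac * n))
    if n - n_test < 1:  # keep at least one training cell per label
        n_test = max(0, n - 1)
    test = members[:n_test]
    pool = members[n_test:]
    n_val = int(round(val_frac * len(pool)))
    if len(pool) - n_val < 1:
        n_val = max(0, len(pool) - 1)
    return pool[n_val:], pool[:n_val], test


def make_splits(
    labels: np.ndarray,
    mode: str = "single_dataset",
    seed: int = 0,
    n_folds: int = 5,
) -> list[SplitPlan]:
    """Build per-fold stratified splits of the labeled cells.

    ``single_dataset``: per fold, each cell type is split 60/40 into a
    training pool and test cells, and the pool 80/20 into train/validation.
    ``cross_dataset``: the labeled (reference) cells are split 80/20 into
    train/validation per type; the test set is the entire query dataset and
    is therefore left empty here.  Labels with a single member go to train
    with a warning.  Each fold re-randomizes the stratified partition.
    """
    labels = np.asarray(labels)
    if mode not in ("single_dataset", "cross_dataset"):
        raise ValueError(f"unknown split mode {mode!r}")
    plans = []
    for fold in range(n_folds):
        rng = np.random.default_rng([seed, 1000 + fold])
        train, val, test = [], [], []
        for lab in np.unique(labels):
            members = np.where(labels == lab)[0]
            if len(members) == 1:
                warnings.warn(f"label {lab!r} has a single cell; kept in train")
                train.extend(members)
                continue
            if mode == "single_dataset":
                tr, va, te = _split_label_group(members, rng)
            else:
                tr, va, te = _split_label_group(members, rng, test_frac=0.0)
            train.extend(tr)
            val.extend(va)
            test.extend(te)
        plans.append(
            SplitPlan(
                train_idx=np.sort(np.array(train, dtype=int)),
                val_idx=np.sort(np.array(val, dtype=int)),
                test_idx=np.sort(np.array(test, dtype=int)),
                fold_index=fold,
                n_folds=n_folds,
                seed=seed,
                mode=mode,
            )
        )
    return plans


class LabelEncoder:
    """Fit on reference labels only; query labels map through the same vocabulary."""

    def __init__(self, labels) -> None:
        self.classes_ = sorted(set(map(str, labels)))
        self._index = {c: i for i, c in enumerate(self.classes_)}

    def encode(self, labels) -> np.ndarray:
        return np.array([self._index.get(str(l), -1) for l in labels], dtype=int)

    def decode(self, codes) -> np.ndarray:
        return np.array([self.classes_[int(c)] for c in codes], dtype=object)


def train_model(
    bundle: MultiViewBundle,
    labels_encoded: np.ndarray,
    split: SplitPlan,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig | None = None,
) -> tuple[MGCNParams, pd.DataFrame]:
    """Full-graph gradient training with early stopping on validation accuracy.

    ``labels_encoded`` gives integer classes for the reference nodes (the
    first ``bundle.n_ref`` rows of the feature matrix); the split's index
    sets refer to those nodes.  Returns the best-validation parameters and a
    per-epoch log (train_loss, val_accuracy, best_val_accuracy).
    """
    train_cfg = train_cfg or TrainConfig()
    X = bundle.features
    A_list = [v.normalized.astype(X.dtype) for v in bundle.views]
    params = init_params(model_cfg, X.shape[1], dtype=X.dtype)
    flat = params.flat()
    opt = Adam(
        flat,
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
        decay_mask=params.decay_mask(),
    )
    rng = np.random.default_rng([train_cfg.seed, 3])

    train_idx = np.asarray(split.train_idx, dtype=int)
    val_idx = np.asarray(split.val_idx, dtype=int)
    y_train = labels_encoded[train_idx]
    y_val = labels_encoded[val_idx]

    best = params.copy()
    best_val = -np.inf
    since_best = 0
    records = []
    for epoch in range(train_cfg.max_epochs):
        loss, grads, _, _ = loss_and_grads(
            params, X, A_list, train_idx, y_train, model_cfg, training=True, rng=rng
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch} (loss={loss})")
        opt.step(grads.flat())

        scores, _, _ = forward(params, X, A_list, model_cfg, training=False)
        val_acc = (
            float((scores[val_idx].argmax(axis=1) == y_val).mean())
            if len(val_idx)
            else float((scores[train_idx].argmax(axis=1) == y_train).mean())
        )
        if val_acc > best_val:
            best_val = val_acc
            best = params.copy()
            since_best = 0
        else:
            if val_acc == best_val:
                # among equally good validation epochs keep the most trained
                best = params.copy()
            since_best += 1
        records.append(
            {"epoch": epoch, "train_loss": loss, "val_accuracy": val_acc,
             "best_val_accuracy": best_val}
        )
        if since_best > train_cfg.patience:
            break
    return best, pd.DataFrame(records)


def predict(
    params: MGCNParams, bundle: MultiViewBundle, model_cfg: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eval-mode forward pass over the full graph.

    Returns (query predicted class codes, query class probabilities, beta) —
    beta being the learned per-view attention weights, reported because the
    relative usefulness of the graph construction methods is itself of
    biological interest.
    """
    X = bundle.features
    A_list = [v.normalized.astype(X.dtype) for v in bundle.views]
    scores, beta, _ = forward(params, X, A_list, model_cfg, training=False)
    q = scores[bundle.n_ref :]
    shifted = q - q.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    return q.argmax(axis=1), probs, beta


def evaluate(pred_labels, true_labels) -> EvalReport:
    """Accuracy, per-class precision/recall/F1, macro- and micro-F1.

    Classes are the union of predicted and true label vocabularies; the
    macro average runs over classes present in the truth only (a class that
    is predicted but never true contributes false positives, not a zero F1
    of its own).  Micro-F1 pools TP/FP/FN over classes, which for
    single-label classification equals accuracy.
    """
    pred = np.asarray([str(l) for l in pred_labels], dtype=object)
    true = np.asarray([str(l) for l in true_labels], dtype=object)
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    if len(pred) == 0:
        raise ValueError("cannot evaluate empty label vectors")

    classes = sorted(set(true) | set(pred))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, ([index[t] for t in true], [index[p] for p in pred]), 1)

    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)

    present = confusion.sum(axis=1) > 0
    macro_f1 = float(f1[present].mean())
    micro_f1 = float(2 * tp.sum() / (2 * tp.sum() + fp.sum() + fn.sum()))
    accuracy = float(tp.sum() / confusion.sum())
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": confusion.sum(axis=1),
        },
        index=classes,
    )
    return EvalReport(
        accuracy=accuracy,
        per_class=per_class,
        macro_f1=macro_f1,
        micro_f1=micro_f1,
        confusion=confusion,
        classes=classes,
    )


def nearest_neighbor_baseline(
    ref: ExpressionDataset, query: ExpressionDataset, k: int = 1
) -> np.ndarray:
    """k-NN label transfer directly on the (normalized) expression matrices.

    The naive cross-batch baseline: each query cell takes the majority label
    of its k nearest reference cells in gene space.
    """
    Xr = np.asarray(ref.matrix.todense(), dtype=float)
    Xq = np.asarray(query.matrix.todense(), dtype=float)
    idx = knn_indices(Xq, Xr, k)
    labels = np.asarray(ref.labels)
    if k == 1:
        return labels[idx[:, 0]]
    out = []
    for row in idx:
        vals, counts = np.unique(labels[row], return_counts=True)
        out.append(vals[np.argmax(counts)])
    return np.array(out, dtype=object)


@dataclass
class ExperimentResult:
    fold_reports: list
    mean_accuracy: float
    mean_macro_f1: float
    betas: list
    logs: list = field(default_factory=list)
    predictions: list = field(default_factory=list)  # per fold: query labels
    query_cell_ids: np.ndarray | None = None


def run_experiment(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    methods=GRAPH_METHODS,
    pre_cfg: PreprocessConfig | None = None,
    graph_cfg: GraphConfig | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_folds: int = 1,
    seed: int = 0,
) -> ExperimentResult:
    """Cross-dataset label transfer, end to end.

    Preprocesses the pair once, builds the requested views, then per fold
    re-randomizes the 80/20 per-type train/validation split of the reference,
    trains, predicts the query cells and (when query labels are available)
    evaluates against them.  Passing a single method runs the single-view
    ablation through the identical harness.
    """
    pre_cfg = pre_cfg or PreprocessConfig(seed=seed)
    graph_cfg = graph_cfg or GraphConfig(seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)

    ref_p, query_p, _ = preprocess_pair(ref, query, pre_cfg)
    bundle = build_bundle(ref_p, query_p, methods, graph_cfg)

    encoder = LabelEncoder(ref_p.labels)
    y_ref = encoder.encode(ref_p.labels)
    if model_cfg is None:
        model_cfg = ModelConfig(
            n_classes=len(encoder.classes_), n_views=len(bundle.views), seed=seed
        )

    splits = make_splits(ref_p.labels, mode="cross_dataset", seed=seed, n_folds=n_folds)
    reports, betas, logs, predictions = [], [], [], []
    for split in splits:
        fold_train_cfg = TrainConfig(
            max_epochs=train_cfg.max_epochs,
            patience=train_cfg.patience,
            learning_rate=train_cfg.learning_rate,
            weight_decay=train_cfg.weight_decay,
            seed=train_cfg.seed + split.fold_index,
        )
        params, log = train_model(bundle, y_ref, split, model_cfg, fold_train_cfg)
        codes, _, beta = predict(params, bundle, model_cfg)
        decoded = encoder.decode(codes)
        predictions.append(decoded)
        betas.append(beta)
        logs.append(log)
        if query_p.labels is not None:
            reports.append(evaluate(decoded, query_p.labels))
    if reports:
        mean_acc = float(np.mean([r.accuracy for r in reports]))
        mean_f1 = float(np.mean([r.macro_f1 for r in reports]))
    else:
        mean_acc = mean_f1 = float("nan")
    return ExperimentResult(
        fold_reports=reports, mean_accuracy=mean_acc, mean_macro_f1=mean_f1,
        betas=betas, logs=logs, predictions=predictions,
        query_cell_ids=query_p.cell_ids,
    )
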