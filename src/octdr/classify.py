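"""Per-layer neural-network ensemble with majority-vote fusion.

Twelve small feed-forward networks — one per retinal layer — consume the
layer's Gibbs-energy decile vector and emit softmax posteriors over
(healthy, DR).  The architecture follows the tuned configuration: input
-> 20 tanh -> 10 tanh -> 2 softmax, trained from scratch with per-sample
stochastic gradient descent on the cross-entropy loss, normally-distributed
initial weights, and a stopping rule on the maximum weight change between
epochs.  A subject's global diagnosis fuses the twelve layer decisions by
majority vote; the even 6-6 split is broken by the higher mean DR
posterior, then defaults to healthy.

The evaluation harness offers subject-level stratified k-fold
cross-validation (and a 70/30 holdout split), pooled confusion counts,
accuracy/sensitivity/specificity with DR as the positive class, and
per-layer ROC/AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import FeatureSchemaError, FoldError, TrainingError
from .io_formats import FEATURE_DECILE_COLUMNS, N_LAYERS

CLASS_ORDER = ("healthy", "DR")  # column order of all posteriors


@dataclass
class AnnConfig:
    """Architecture and SGD hyperparameters of the per-layer network."""

    hidden: tuple[int, ...] = (20, 10)
    learning_rate: float = 0.01
    max_epochs: int = 500
    tolerance: float = 1e-6      # stop when max |delta w| per epoch drops below
    init_scale: float = 0.5      # std of the normal weight initialisation

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate and max_epochs must be positive")


@dataclass
class EvalConfig:
    """Cross-validation protocol."""

    k_folds: int = 5
    test_fraction: float = 0.3   # for the holdout-split mode
    metric_convention: str = "standard"  # or "printed"


@dataclass
class AnnModel:
    """A trained feed-forward network plus its feature standardization."""

    layer: int
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    config: AnnConfig
    seed: int
    epochs_run: int = 0
    final_loss: float = np.nan

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[1]


@dataclass
class EnsembleModel:
    """One AnnModel per retinal layer 1..12 plus the vote fusion rule."""

    models: dict[int, AnnModel]

    def __post_init__(self) -> None:
        if sorted(self.models) != list(range(1, N_LAYERS + 1)):
            raise ValueError("ensemble needs exactly one model per layer 1..12")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


# ---------------------------------------------------------------------------
# Network internals (kept functional so gradients are finite-difference
# checkable against the loss)
# ---------------------------------------------------------------------------

def _init_params(
    n_in: int, hidden: tuple[int, ...], rng: np.random.Generator, scale: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    sizes = (n_in,) + tuple(hidden) + (2,)
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, scale / np.sqrt(a), size=(b, a)))
        biases.append(rng.normal(0.0, scale, size=b))
    return weights, biases


def _forward(weights, biases, X: np.ndarray):
    """Returns (activations per layer, softmax posteriors)."""
    acts = [np.atleast_2d(X)]
    h = acts[0]
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.tanh(h @ W.T + b)
        acts.append(h)
    logits = h @ weights[-1].T + biases[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    return acts, p


def cross_entropy_loss(weights, biases, X: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of the softmax outputs; y is 0/1 (healthy/DR)."""
    _, p = _forward(weights, biases, X)
    n = p.shape[0]
    return float(-np.mean(np.log(p[np.arange(n), np.asarray(y, int)] + 1e-300)))


def gradients(weights, biases, X: np.ndarray, y: np.ndarray):
    """Backpropagated mean-loss gradients, same structure as the params."""
    X = np.atleast_2d(X)
    y = np.asarray(y, int)
    n = X.shape[0]
    acts, p = _forward(weights, biases, X)
    delta = p.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    gw = [None] * len(weights)
    gb = [None] * len(biases)
    for li in range(len(weights) - 1, -1, -1):
        gw[li] = delta.T @ acts[li]
        gb[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ weights[li]) * (1.0 - acts[li] ** 2)
    return gw, gb


def train_ann(
    X: np.ndarray,
    y: Sequence[int],
    config: AnnConfig | None = None,
    seed: int = 0,
    layer: int = 0,
) -> AnnModel:
    """Train one network with per-sample SGD; deterministic given the seed.

    Features are standardized with the training set's mean/scale (stored on
    the model).  Training stops when the maximum absolute weight change
    over an epoch falls below ``config.tolerance`` or at the epoch cap.
    """
    config = config or AnnConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("X must be n x d with matching labels")
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise TrainingError("training needs >= 2 samples covering both classes")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    rng = np.random.default_rng(seed)
    weights, biases = _init_params(X.shape[1], config.hidden, rng, config.init_scale)
    lr = config.learning_rate
    epochs_run = 0
    for epoch in range(config.max_epochs):
        prev = [w.copy() for w in weights] + [b.copy() for b in biases]
        order = rng.permutation(X.shape[0])
        for idx in order:
            gw, gb = gradients(weights, biases, Xs[idx:idx + 1], y[idx:idx + 1])
            for li in range(len(weights)):
                weights[li] -= lr * gw[li]
                biases[li] -= lr * gb[li]
        epochs_run = epoch + 1
        cur = weights + biases
        delta = max(np.abs(c - p).max() for c, p in zip(cur, prev))
        if delta < config.tolerance:
            break
    return AnnModel(
        layer=layer,
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_scale=scale,
        config=config,
        seed=seed,
        epochs_run=epochs_run,
        final_loss=cross_entropy_loss(weights, biases, Xs, y),
    )


def ann_predict(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Softmax posteriors, columns ordered (healthy, DR); rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_inputs:
        raise FeatureSchemaError(
            f"model expects {model.n_inputs} features, got {X.shape[1]}"
        )
    Xs = (X - model.feature_mean) / model.feature_scale
    _, p = _forward(model.weights, model.biases, Xs)
    return p


# ---------------------------------------------------------------------------
# Ensemble and fusion
# ---------------------------------------------------------------------------

def _pivot_features(features: pd.DataFrame):
    """(subjects, y, per-layer X) from a long feature table."""
    subjects = features["subject_id"].drop_duplicates().tolist()
    y = (
        features.drop_duplicates("subject_id")
        .set_index("subject_id")["class"]
        .reindex(subjects)
        .map({"healthy": 0, "DR": 1})
    )
    if y.isna().any():
        raise FeatureSchemaError("class column must be 'healthy' or 'DR'")
    per_layer = {}
    cols = list(FEATURE_DECILE_COLUMNS)
    for layer in range(1, N_LAYERS + 1):
        sub = features[features["layer"] == layer]
        if set(sub["subject_id"]) != set(subjects):
            raise FeatureSchemaError(f"layer {layer} missing for some subjects")
        sub = sub.set_index("subject_id").loc[subjects]
        per_layer[layer] = sub[cols].to_numpy(float)
    return subjects, y.to_numpy(int), per_layer


def train_ensemble(
    features: pd.DataFrame, config: AnnConfig | None = None, seed: int = 0
) -> EnsembleModel:
    """Train the 12 per-layer networks on a long feature table."""
    _, y, per_layer = _pivot_features(features)
    models = {
        layer: train_ann(per_layer[layer], y, config, seed=seed + layer, layer=layer)
        for layer in range(1, N_LAYERS + 1)
    }
    return EnsembleModel(models=models)


def ensemble_posteriors(
    ensemble: EnsembleModel, features: pd.DataFrame
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(subjects, true y, n_subjects x 12 x 2 posterior array)."""
    subjects, y, per_layer = _pivot_features(features)
    post = np.zeros((len(subjects), N_LAYERS, 2))
    for layer in range(1, N_LAYERS + 1):
        post[:, layer - 1, :] = ann_predict(ensemble.models[layer], per_layer[layer])
    return subjects, y, post


def majority_vote(layer_posteriors: np.ndarray) -> tuple[str, tuple[int, int], np.ndarray]:
    """Fuse 12 layer posteriors into one diagnosis.

    Returns (class, (healthy_votes, dr_votes), mean posterior).  A 6-6 tie
    goes to DR only when the mean DR posterior exceeds 0.5, otherwise
    healthy.
    """
    p = np.asarray(layer_posteriors, dtype=np.float64)
    if p.shape != (N_LAYERS, 2):
        raise ValueError(f"expected {N_LAYERS} x 2 posteriors, got {p.shape}")
    votes = p.argmax(axis=1)
    dr_votes = int(votes.sum())
    healthy_votes = N_LAYERS - dr_votes
    mean_post = p.mean(axis=0)
    if dr_votes > healthy_votes:
        cls = "DR"
    elif dr_votes < healthy_votes:
        cls = "healthy"
    else:
        cls = "DR" if mean_post[1] > 0.5 else "healthy"
    return cls, (healthy_votes, dr_votes), mean_post


# ---------------------------------------------------------------------------
# Metrics and ROC
# ---------------------------------------------------------------------------

def compute_metrics(
    c: ConfusionCounts, convention: str = "standard"
) -> tuple[float | None, float | None, float | None]:
    """(accuracy, sensitivity, specificity), DR positive.

    ``standard``: sensitivity TP/(TP+FN), specificity TN/(TN+FP).
    ``printed`` reports TP/(TP+FP) (a precision formula) in the specificity
    slot, exposed for auditability.  Zero-denominator rates are ``None``.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")

    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    accuracy = (c.tp + c.tn) / c.total
    sensitivity = _rate(c.tp, c.tp + c.fn)
    if convention == "printed":
        specificity = _rate(c.tp, c.tp + c.fp)
    elif convention == "standard":
        specificity = _rate(c.tn, c.tn + c.fp)
    else:
        raise ValueError(f"unknown metric convention {convention!r}")
    return accuracy, sensitivity, specificity


def roc_curve(scores: Sequence[float], labels: Sequence[int]):
    """Threshold-sweep ROC and trapezoidal AUC; DR (1) is positive.

    Constant scores collapse to the chance diagonal (AUC 0.5 under the
    tie-averaging convention).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    return (fpr, tpr), float(_sk_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-layer and majority-vote performance over a validation scheme."""

    table: pd.DataFrame                      # rows: layers 1..12 + majority_vote
    confusion: dict[str, ConfusionCounts]
    roc: dict[int, tuple[tuple[np.ndarray, np.ndarray], float]]
    fold_assignment: pd.DataFrame            # subject_id, class, fold


def _check_folds(y: np.ndarray, k: int) -> None:
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if k < 2:
        raise FoldError("k must be >= 2")
    if k > min(n_pos, n_neg):
        raise FoldError(
            f"k={k} exceeds the minority class count {min(n_pos, n_neg)}"
        )


def kfold_evaluate(
    features: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    ann_config: AnnConfig | None = None,
    convention: str = "standard",
) -> EvalReport:
    """Subject-level stratified k-fold CV of the full ensemble.

    All rows of one subject stay in the same fold.  Confusion counts are
    pooled over folds; ROC per layer uses the pooled held-out DR
    posteriors.
    """
    subjects, y, _ = _pivot_features(features)
    _check_folds(y, k)
    subjects = np.asarray(subjects)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.zeros(len(subjects), dtype=int)
    per_layer_scores = {l: np.zeros(len(subjects)) for l in range(1, N_LAYERS + 1)}
    layer_conf = {l: ConfusionCounts() for l in range(1, N_LAYERS + 1)}
    mv_conf = ConfusionCounts()

    for fold, (train_idx, test_idx) in enumerate(skf.split(subjects, y)):
        fold_of[test_idx] = fold
        train_subj = set(subjects[train_idx])
        train_feat = features[features["subject_id"].isin(train_subj)]
        test_feat = features[~features["subject_id"].isin(train_subj)]
        ensemble = train_ensemble(train_feat, ann_config, seed=seed * 1000 + fold)
        test_subjects, y_test, post = ensemble_posteriors(ensemble, test_feat)
        order = {s: i for i, s in enumerate(test_subjects)}
        for si, subj in enumerate(test_subjects):
            gidx = int(np.where(subjects == subj)[0][0])
            truth = y_test[si]
            for l in range(1, N_LAYERS + 1):
                p_dr = post[si, l - 1, 1]
                per_layer_scores[l][gidx] = p_dr
                _tally(layer_conf[l], int(p_dr > 0.5), truth)
            cls, _, _ = majority_vote(post[si])
            _tally(mv_conf, int(cls == "DR"), truth)

    rows = []
    confusion: dict[str, ConfusionCounts] = {}
    roc: dict[int, tuple] = {}
    for l in range(1, N_LAYERS + 1):
        acc, sens, spec = compute_metrics(layer_conf[l], convention)
        rows.append({"unit": f"layer_{l}", "accuracy": acc,
                     "sensitivity": sens, "specificity": spec})
        confusion[f"layer_{l}"] = layer_conf[l]
        roc[l] = roc_curve(per_layer_scores[l], y)
    acc, sens, spec = compute_metrics(mv_conf, convention)
    rows.append({"unit": "majority_vote", "accuracy": acc,
                 "sensitivity": sens, "specificity": spec})
    confusion["majority_vote"] = mv_conf
    table = pd.DataFrame(rows)
    fold_assignment = pd.DataFrame(
        {"subject_id": subjects,
         "class": np.where(y == 1, "DR", "healthy"),
         "fold": fold_of}
    )
    return EvalReport(table=table, confusion=confusion, roc=roc,
                      fold_assignment=fold_assignment)


def split_evaluate(
    features: pd.DataFrame,
    test_fraction: float = 0.3,
    seed: int = 0,
    ann_config: AnnConfig | None = None,
    convention: str = "standard",
) -> EvalReport:
    """Single stratified train/test split (default 70/30) evaluation."""
    subjects, y, _ = _pivot_features(features)
    subjects = np.asarray(subjects)
    train_subj, test_subj = train_test_split(
        subjects, test_size=test_fraction, random_state=seed, stratify=y
    )
    train_feat = features[features["subject_id"].isin(set(train_subj))]
    test_feat = features[features["subject_id"].isin(set(test_subj))]
    ensemble = train_ensemble(train_feat, ann_config, seed=seed)
    test_subjects, y_test, post = ensemble_posteriors(ensemble, test_feat)

    rows = []
    confusion: dict[str, ConfusionCounts] = {}
    roc: dict[int, tuple] = {}
    for l in range(1, N_LAYERS + 1):
        conf = ConfusionCounts()
        for si in range(len(test_subjects)):
            _tally(conf, int(post[si, l - 1, 1] > 0.5), y_test[si])
        acc, sens, spec = compute_metrics(conf, convention)
        rows.append({"unit": f"layer_{l}", "accuracy": acc,
                     "sensitivity": sens, "specificity": spec})
        confusion[f"layer_{l}"] = conf
        if len(np.unique(y_test)) == 2:
            roc[l] = roc_curve(post[:, l - 1, 1], y_test)
    mv_conf = ConfusionCounts()
    for si in range(len(test_subjects)):
        cls, _, _ = majority_vote(post[si])
        _tally(mv_conf, int(cls == "DR"), y_test[si])
    acc, sens, spec = compute_metrics(mv_conf, convention)
    rows.append({"unit": "majority_vote", "accuracy": acc,
                 "sensitivity": sens, "specificity": spec})
    confusion["majority_vote"] = mv_conf
    fold_assignment = pd.DataFrame(
        {"subject_id": test_subjects, "class": np.where(y_test == 1, "DR", "healthy"),
         "fold": 0}
    )
    return EvalReport(table=pd.DataFrame(rows), confusion=confusion, roc=roc,
                      fold_assignment=fold_assignment)


def _tally(conf: ConfusionCounts, predicted_dr: int, truth_dr: int) -> None:
    if predicted_dr and truth_dr:
        conf.tp += 1
    elif predicted_dr and not truth_dr:
        conf.fp += 1
    elif not predicted_dr and truth_dr:
        conf.fn += 1
    else:
        conf.tn += 1
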