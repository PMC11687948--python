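"""Training, evaluation, and leakage-safe cross-validation.

Training minimizes softmax cross-entropy with Adam, optional
inverse-frequency class weights, a stratified validation split, and early
stopping on validation loss (best-validation parameters are restored).
Cross-validation refits the whole representation per fold: taxa similarity,
embedding, pixel map, and the image normalization constant are computed
from training folds only and applied frozen to the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ..containers import AnnotationTable
from ..imaging import assign_pixels, embed_taxa, render_images
from ..similarity import build_feature_matrix, correlation_distance, cophenetic_distance
from .network import AttentionCNN, BlockSpec, build_model, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FittedModel",
    "train",
    "evaluate",
    "CVSettings",
    "cross_validate",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    patience: int = 10
    min_epochs: int = 25  # early stopping cannot fire before this epoch
    val_fraction: float = 0.15
    class_weights: bool = False
    input_transform: str = "sqrt"  # {"sqrt", "none"}
    standardize_input: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.val_fraction <= 0.5):
            raise ValueError("val_fraction must lie in (0, 0.5]")
        if min(self.epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FittedModel:
    network: AttentionCNN
    classes: np.ndarray
    history: pd.DataFrame
    config: TrainConfig
    norm_max: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(images)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.classes[self.predict_proba(images).argmax(axis=1)]


class Adam:
    """Adam with decoupled weight decay (AdamW when weight_decay > 0)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and not p.name.endswith((".gamma", ".beta", ".bias")):
                p.value -= self.lr * self.weight_decay * p.value


def _cross_entropy(logits, y_idx, weights):
    probs = softmax(logits)
    n = len(y_idx)
    w = weights[y_idx]
    log_p = np.log(np.maximum(probs[np.arange(n), y_idx], 1e-12))
    loss = -(w * log_p).sum() / w.sum()
    dlogits = probs.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits


def _stratified_split(y_idx, val_fraction, rng):
    train_idx, val_idx = [], []
    for cls in np.unique(y_idx):
        members = np.flatnonzero(y_idx == cls)
        members = rng.permutation(members)
        n_val = max(1, int(round(val_fraction * len(members))))
        if n_val >= len(members):
            raise ValueError("class too small for the validation split")
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def train(
    model: AttentionCNN, images: np.ndarray, labels, cfg: TrainConfig | None = None
) -> FittedModel:
    """Fit the network; returns the best-validation-loss parameters."""
    cfg = cfg or TrainConfig()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(images):
        raise ValueError("labels must align with images")
    classes, y_idx = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if len(classes) != model.n_classes:
        raise ValueError(
            f"model built for {model.n_classes} classes, labels have {len(classes)}"
        )
    weights = (
        counts.sum() / (len(counts) * counts.astype(float))
        if cfg.class_weights
        else np.ones(len(counts))
    )

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_split(y_idx, cfg.val_fraction, rng)
    x_train, y_train = images[train_idx], y_idx[train_idx]
    x_val, y_val = images[val_idx], y_idx[val_idx]

    if cfg.input_transform not in ("sqrt", "none"):
        raise ValueError(f"unknown input_transform {cfg.input_transform!r}")
    model.input_transform = cfg.input_transform
    if cfg.standardize_input:
        # per-pixel standardization fit on the training split only; lives on
        # the network so prediction and saliency apply the identical view
        viewed = np.sqrt(np.maximum(x_train, 0.0)) if cfg.input_transform == "sqrt" else x_train
        mean = viewed.mean(axis=0)
        std = viewed.std(axis=0)
        std[std == 0] = 1.0
        model.input_mean = mean.reshape(1, 1, *mean.shape[-2:])
        model.input_std = std.reshape(1, 1, *std.shape[-2:])

    optimizer = Adam(
        model.params(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    best_loss, best_state, best_epoch = np.inf, None, -1
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x_train[batch], train=True)
            loss, dlogits = _cross_entropy(logits, y_train[batch], weights)
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        val_logits = model.forward(x_val, train=False)
        val_loss, _ = _cross_entropy(val_logits, y_val, weights)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        improved = val_loss < best_loss
        if improved:
            best_loss, best_state, best_epoch = val_loss, model.state(), epoch
        rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": float(val_loss),
                "val_accuracy": val_acc,
                "best_so_far": float(best_loss),
            }
        )
        # the loss surface has a long initial plateau on sparse images, so
        # early stopping only arms after min_epochs
        if epoch >= cfg.min_epochs and epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state(best_state)
    model.is_trained = True
    history = pd.DataFrame(rows)
    logger.info(
        "trained %d epochs (best val loss %.4f at epoch %d)",
        len(rows),
        best_loss,
        best_epoch,
    )
    return FittedModel(network=model, classes=classes, history=history, config=cfg)


def evaluate(fitted: FittedModel, images: np.ndarray, labels) -> dict[str, Any]:
    """Accuracy, macro-F1, AUC (binary: class-1 prob; multiclass: macro OvR),
    plus the confusion matrix."""
    labels = np.asarray(labels)
    unseen = set(labels) - set(fitted.classes)
    if unseen:
        raise ValueError(f"labels outside the model's class set: {sorted(unseen)}")
    probs = fitted.predict_proba(np.asarray(images, dtype=float))
    predicted = fitted.classes[probs.argmax(axis=1)]
    class_index = {c: i for i, c in enumerate(fitted.classes)}
    y_idx = np.array([class_index[l] for l in labels])
    accuracy = float((predicted == labels).mean())
    macro_f1 = float(
        f1_score(y_idx, probs.argmax(axis=1), average="macro", zero_division=0)
    )
    try:
        if len(fitted.classes) == 2:
            auc = float(roc_auc_score(y_idx, probs[:, 1]))
        else:
            auc = float(
                roc_auc_score(
                    y_idx, probs, multi_class="ovr", average="macro",
                    labels=np.arange(len(fitted.classes)),
                )
            )
    except ValueError:  # a class absent from this evaluation set
        auc = float("nan")
    return {
        "accuracy": accuracy,
        "macro_f1": macro_f1,
        "auc": auc,
        "confusion_matrix": confusion_matrix(
            labels, predicted, labels=list(fitted.classes)
        ),
    }


@dataclass
class CVSettings:
    """Representation + model settings refit inside every fold."""

    similarity_mode: str = "metabolic"  # {metabolic, abundance, combined, pearson, spearman, cophenetic}
    embedding_method: str = "tsne"
    perplexity: float = 30.0
    n_neighbors: int = 15
    min_dist: float = 0.1
    tsne_max_iter: int = 500
    image_height: int = 32
    image_width: int = 32
    blocks: tuple = ((16, 3, 1), (32, 3, 2))
    train: TrainConfig = field(default_factory=TrainConfig)
    attention_kernel: int = 7


def _fold_embedding_input(settings, train_abund, annot, tree):
    mode = settings.similarity_mode
    if mode in ("pearson", "spearman"):
        return correlation_distance(train_abund, method=mode)
    if mode == "cophenetic":
        if tree is None:
            raise ValueError("cophenetic similarity requires a tree")
        return cophenetic_distance(tree)
    return build_feature_matrix(abund=train_abund, annot=annot, mode=mode)


def fit_fold(settings, train_abund, train_labels, annot=None, tree=None, seed=0):
    """Fit representation + model on training data; returns everything the
    held-out fold needs (pixel map, normalization constant, fitted model)."""
    emb_input = _fold_embedding_input(settings, train_abund, annot, tree)
    emb = embed_taxa(
        emb_input,
        method=settings.embedding_method,
        perplexity=settings.perplexity,
        n_neighbors=settings.n_neighbors,
        min_dist=settings.min_dist,
        seed=seed,
        max_iter=settings.tsne_max_iter,
    )
    pmap = assign_pixels(emb, settings.image_height, settings.image_width)
    stack = render_images(train_abund, pmap)
    classes = np.unique(np.asarray(train_labels))
    model = build_model(
        [BlockSpec(*b) for b in settings.blocks],
        n_classes=len(classes),
        height=settings.image_height,
        width=settings.image_width,
        seed=seed,
        attention_kernel=settings.attention_kernel,
    )
    cfg = replace(settings.train, seed=seed)
    fitted = train(model, stack.images, np.asarray(train_labels), cfg)
    fitted.norm_max = stack.norm_max
    fitted.metadata["pixel_map"] = pmap
    return fitted, pmap, stack.norm_max


def cross_validate(
    abund: pd.DataFrame,
    labels: pd.Series,
    settings: CVSettings | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    annot: AnnotationTable | None = None,
    tree: str | None = None,
    return_models: bool = False,
):
    """Repeated stratified k-fold CV with per-fold representation refit.

    ``abund`` is a taxa x samples relative-abundance table; ``labels`` is a
    per-sample series aligned with its columns.
    """
    settings = settings or CVSettings()
    labels = pd.Series(np.asarray(labels), index=abund.columns)
    counts = labels.value_counts()
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size ({int(counts.min())})"
        )
    rows, models, assignments = [], [], []
    for rep in range(repeats):
        rep_seed = (seed * 1009 + rep * 131) % (2**31 - 1)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(splitter.split(labels.index, labels.values)):
            fold_seed = (rep_seed + 7919 * (fold + 1)) % (2**31 - 1)
            train_cols = abund.columns[tr]
            test_cols = abund.columns[te]
            fitted, pmap, norm = fit_fold(
                settings,
                abund[train_cols],
                labels[train_cols].to_numpy(),
                annot=annot,
                tree=tree,
                seed=fold_seed,
            )
            test_stack = render_images(abund[test_cols], pmap, norm_max=norm)
            metrics = evaluate(fitted, test_stack.images, labels[test_cols].to_numpy())
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "accuracy": metrics["accuracy"],
                    "macro_f1": metrics["macro_f1"],
                    "auc": metrics["auc"],
                }
            )
            assignments.append(
                {"repeat": rep, "fold": fold, "test_samples": list(test_cols)}
            )
            if return_models:
                models.append(fitted)
    fold_metrics = pd.DataFrame(rows)
    aggregate = {
        m: float(fold_metrics[m].mean()) for m in ("accuracy", "macro_f1", "auc")
    }
    result = {
        "fold_metrics": fold_metrics,
        "aggregate": aggregate,
        "assignments": assignments,
    }
    if return_models:
        result["models"] = models
    return result
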