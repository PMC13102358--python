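"""Training and inference for the four-class window discriminator.

Training follows a fixed-steps-per-epoch regime: each epoch draws
``steps_per_epoch`` batches by shuffling the training pool and cycling
through it, computes the validation loss, and keeps the weights from the
best-validation-loss epoch.  Training stops at ``max_epochs`` or after
``patience`` consecutive epochs without the validation loss improving on the
best seen so far.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import CLASS_LABELS
from .nn import Adam, ResNetClassifier, build_network, softmax_cross_entropy


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 16
    max_epochs: int = 100
    steps_per_epoch: int = 1500
    patience: int = 10
    validation_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "max_epochs", "steps_per_epoch",
                     "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
            writer.writeheader()
            for row in self.epochs:
                writer.writerow(row)


def _validation_loss(net: ResNetClassifier, x_val, y_val, batch_size=64) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x_val), batch_size):
        xb = x_val[i : i + batch_size].astype(np.float32)
        logits = net.forward(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, y_val[i : i + batch_size])
        total += loss * len(xb)
        n += len(xb)
    return total / n


def stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Boolean validation mask with ceil(fraction * n_c) per class."""
    mask = np.zeros(len(y), dtype=bool)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        k = int(np.ceil(fraction * len(idx)))
        mask[rng.choice(idx, size=k, replace=False)] = True
    return mask


def train(
    x: np.ndarray,
    y: np.ndarray,
    net: ResNetClassifier | None = None,
    config: TrainConfig | None = None,
    val_mask: np.ndarray | None = None,
    preset: str = "desk",
) -> tuple[ResNetClassifier, TrainHistory]:
    """Fit the discriminator on labelled tensors.

    ``x``: (N, 2, H, W) array; ``y``: integer labels in class order
    :data:`introscan.CLASS_LABELS`.  ``val_mask`` marks the validation
    examples; when absent a stratified split of ``validation_fraction`` is
    drawn.  Returns the network carrying the best-validation-loss weights
    and the per-epoch history.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    y = np.asarray(y, dtype=np.int64)
    present = set(np.unique(y).tolist())
    if present != set(range(len(CLASS_LABELS))):
        missing = [CLASS_LABELS[i] for i in range(len(CLASS_LABELS)) if i not in present]
        raise ValueError(f"training data lacks examples for classes: {missing}")
    if val_mask is None:
        val_mask = stratified_split(y, config.validation_fraction, rng)
    x_train, y_train = x[~val_mask], y[~val_mask]
    x_val, y_val = x[val_mask], y[val_mask]
    if net is None:
        net = build_network(x.shape[1:], preset=preset, seed=config.seed)

    opt = Adam(learning_rate=config.learning_rate, betas=config.betas)
    history = TrainHistory()
    best_state = net.state_dict()
    order = np.empty(0, dtype=np.int64)
    cursor = 0
    epochs_since_best = 0
    for epoch in range(config.max_epochs):
        losses = []
        for _ in range(config.steps_per_epoch):
            if cursor + config.batch_size > len(order):
                order = rng.permutation(len(x_train))
                cursor = 0
            take = order[cursor : cursor + config.batch_size]
            cursor += config.batch_size
            xb = x_train[take].astype(np.float32)
            logits = net.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[take])
            net.backward(dlogits)
            opt.step(net.named_parameters())
            losses.append(loss)
        val_loss = _validation_loss(net, x_val, y_val)
        history.epochs.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = net.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break
    net.load_state_dict(best_state)
    return net, history


def predict(net: ResNetClassifier, tensors: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities per tensor, rows summing to 1, order preserved."""
    tensors = np.asarray(tensors)
    if tensors.ndim == 3:
        tensors = tensors[None]
    if tensors.shape[1:] != net.input_shape:
        raise ValueError(
            f"tensor shape {tensors.shape[1:]} does not match network input "
            f"{net.input_shape}"
        )
    return net.predict_proba(tensors.astype(np.float32), batch_size=batch_size)
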