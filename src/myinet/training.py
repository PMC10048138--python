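"""Optimisation loop: momentum SGD, step learning-rate decay, early stopping.

The regimen is a fixed-step schedule: the learning rate starts at 1e-3 and is
multiplied by the drop factor (default 1/3) every 10 epochs,

    lr(epoch) = initial_lr * factor ** floor(epoch / period).

Training runs momentum SGD (momentum 0.9) on the class-weighted pixel loss
over shuffled mini-batches of 10 and evaluates the validation split once per
epoch; it stops at ``max_epochs`` (default 50) or as soon as the validation
loss has failed to strictly improve for ``validation_patience`` (default 4)
consecutive evaluations.  The parameters returned are those of the best
validation epoch, not the last one.  All randomness (shuffling,
augmentation) descends from the single integer seed in the config.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import augment_pair
from .metrics import confusion_matrix, global_accuracy
from .model import SegmentationModel
from .nn import SGD
from .phantom import Cohort, LabeledImage, class_frequencies
from .weighting import ClassWeights, median_frequency_weights, weighted_pixel_loss

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "EarlyStopper", "lr_schedule", "train"]


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    lr_drop_period: int = 10
    lr_drop_factor: float = 1.0 / 3.0
    max_epochs: int = 50
    batch_size: int = 10
    validation_patience: int = 4
    momentum: float = 0.9
    seed: int = 0
    class_weights: ClassWeights | None = None
    balance: str = "median_frequency"  # or "none" for the unweighted ablation
    augment: bool = True

    def __post_init__(self):
        if not 0.0 < self.lr_drop_factor <= 1.0:
            raise ValueError("lr_drop_factor must be in (0, 1]")
        if self.validation_patience < 1:
            raise ValueError("validation patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.balance not in ("median_frequency", "none"):
            raise ValueError("balance must be 'median_frequency' or 'none'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_global_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1  # 0-based

    def __len__(self):
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self)),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_global_accuracy": self.val_global_accuracy,
            "learning_rate": self.learning_rate,
        })


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Stepwise-decayed learning rate at a 0-based epoch index."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.initial_lr * cfg.lr_drop_factor ** (epoch // cfg.lr_drop_period)


class EarlyStopper:
    """Stop after ``patience`` consecutive validations without strict
    improvement of the best validation loss seen so far."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.bad_count = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one validation; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad_count = 0
        else:
            self.bad_count += 1
        return self.bad_count >= self.patience


def _stack(images: list[LabeledImage]):
    pixels = np.stack([im.pixels for im in images])[:, None]
    labels = np.stack([im.labels for im in images])
    return pixels, labels


def _evaluate(model: SegmentationModel, images: list[LabeledImage],
              weights: ClassWeights, batch_size: int):
    model.eval()
    losses = []
    preds, gts = [], []
    for i in range(0, len(images), batch_size):
        pixels, labels = _stack(images[i:i + batch_size])
        out = model.forward(pixels)
        loss = weighted_pixel_loss(out, labels, weights)
        losses.append((loss.item(), labels.size))
        preds.extend(np.argmax(out.data, axis=1))
        gts.extend(labels)
    model.train()
    total = sum(n for _, n in losses)
    mean_loss = sum(v * n for v, n in losses) / total
    cm = confusion_matrix(gts, preds, model.spec.n_classes)
    return mean_loss, global_accuracy(cm), cm


def train(model: SegmentationModel, cohort: Cohort, cfg: TrainConfig,
          ) -> tuple[SegmentationModel, TrainHistory]:
    """Train a segmentation model on a cohort's train split.

    Validation runs once per epoch on the cohort's validation split; the
    returned model carries the parameters of the best validation epoch.
    """
    train_images = cohort.split("train")
    val_images = cohort.split("validation")
    if not train_images or not val_images:
        raise ValueError("cohort must have non-empty train and validation splits")

    if cfg.class_weights is not None:
        weights = cfg.class_weights
    elif cfg.balance == "median_frequency":
        freqs = class_frequencies(train_images, cfg_n_classes(model))
        weights = median_frequency_weights(freqs)
    else:
        weights = ClassWeights.uniform(cfg_n_classes(model))
    logger.info("class weights: %s", np.array2string(weights.weights, precision=4))

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    optimizer = SGD(model.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum)
    stopper = EarlyStopper(cfg.validation_patience)
    history = TrainHistory()
    best_state = None

    for epoch in range(cfg.max_epochs):
        lr = lr_schedule(epoch, cfg)
        optimizer.lr = lr
        order = rng.permutation(len(train_images))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_images[j] for j in order[i:i + cfg.batch_size]]
            if cfg.augment:
                batch = [augment_pair(im, rng) for im in batch]
            pixels, labels = _stack(batch)
            out = model.forward(pixels)
            loss = weighted_pixel_loss(out, labels, weights)
            value = loss.item()
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)

        val_loss, val_acc, _ = _evaluate(model, val_images, weights, cfg.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_global_accuracy.append(val_acc)
        history.learning_rate.append(lr)
        logger.info("epoch %d: lr=%.2e train=%.4f val=%.4f val_gAcc=%.4f "
                    "(patience %d/%d)", epoch, lr, history.train_loss[-1],
                    val_loss, val_acc, stopper.bad_count, cfg.validation_patience)

        if val_loss < stopper.best:
            best_state = copy.deepcopy(model.state_dict())
        if stopper.update(epoch, val_loss):
            history.stop_reason = "patience"
            break
    else:
        history.stop_reason = "max_epochs"

    history.best_epoch = stopper.best_epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def cfg_n_classes(model: SegmentationModel) -> int:
    return model.spec.n_classes
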