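"""Training loop and evaluation pipeline.

Training follows the published recipe: Adam, cosine-annealing learning-rate
schedule (period 10 epochs, floor 1e-4), BCE-Dice loss, batch size 4,
140 epochs, inputs resized to 576x576 and ImageNet-normalized.  The base
learning rate (not stated in the source protocol) defaults to the Adam
convention 1e-3.  Every run is reproducible from its seed on one machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .data import preprocess
from .losses import bce_dice_loss
from .metrics import binarize, metric_record, summarize
from .models import SegmentationModel, save_checkpoint
from .nn.optim import Adam, CosineAnnealingLR

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    base_lr: float = 1e-3
    min_lr: float = 1e-4          # scheduler floor
    scheduler_t_max: int = 10     # cosine period, in epochs
    epochs: int = 140
    batch_size: int = 4
    image_size: int = 576
    seed: int = 0
    augment: bool = False
    threshold: float = 0.5
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.min_lr > self.base_lr:
            raise ValueError("min_lr must not exceed base_lr")
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrainHistory:
    """Per-epoch record of the run."""

    loss: list = field(default_factory=list)
    bce: list = field(default_factory=list)
    dice_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)

    def __len__(self):
        return len(self.loss)


def _stack(samples, size):
    xs, ys = [], []
    for s in samples:
        img, mask = preprocess(s, size=size)
        xs.append(img)
        ys.append(mask[None].astype(np.float32))
    return np.stack(xs), np.stack(ys)


def _augment_batch(x, y, rng):
    for i in range(x.shape[0]):
        if rng.random() < 0.5:
            x[i] = x[i, :, :, ::-1]
            y[i] = y[i, :, :, ::-1]
        k = rng.integers(0, 4)
        if k:
            x[i] = np.rot90(x[i], k, axes=(1, 2))
            y[i] = np.rot90(y[i], k, axes=(1, 2))
    return x, y


def train(model: SegmentationModel, samples, config: TrainConfig,
          val_samples=None):
    """Optimize ``model`` on ``samples``; returns (model, TrainHistory).

    Runs epochs x ceil(n / batch_size) Adam steps on the BCE-Dice loss with
    the cosine-annealed learning rate stepped once per epoch.  A non-finite
    loss aborts the run, restoring the weights from the end of the previous
    epoch (and writing them to ``config.checkpoint_path`` if set).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("train requires at least one sample")
    logger.info("training: %d samples, %d epochs, batch %d, base_lr %g, "
                "cosine T_max %d floor %g, augment %s",
                len(samples), config.epochs, config.batch_size, config.base_lr,
                config.scheduler_t_max, config.min_lr, config.augment)
    x_all, y_all = _stack(samples, config.image_size)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.base_lr)
    sched = CosineAnnealingLR(opt, T_max=config.scheduler_t_max,
                              eta_min=config.min_lr)
    history = TrainHistory()
    last_good = None
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(samples))
        losses, bces, dices = [], [], []
        for start in range(0, len(samples), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_all[idx].copy(), y_all[idx].copy()
            if config.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            probs = model(xb)
            loss = bce_dice_loss(probs, yb)
            if not np.isfinite(loss.total):
                logger.error("non-finite loss at epoch %d; aborting", epoch)
                if last_good is not None:
                    model.load_state_dict(last_good)
                if config.checkpoint_path:
                    save_checkpoint(model, config.checkpoint_path)
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; restored last good weights")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.total)
            bces.append(loss.bce_part)
            dices.append(loss.dice_part)
        history.loss.append(float(np.mean(losses)))
        history.bce.append(float(np.mean(bces)))
        history.dice_loss.append(float(np.mean(dices)))
        history.lr.append(sched.get_lr())
        sched.step()
        last_good = {k: v.copy() for k, v in model.state_dict().items()}
        if val_samples:
            records, _ = evaluate(model, val_samples, threshold=config.threshold,
                                  size=config.image_size)
            history.val_dice.append(float(np.mean([r.dice for r in records])))
            logger.info("epoch %d: loss %.4f val dice %.4f", epoch,
                        history.loss[-1], history.val_dice[-1])
        else:
            logger.info("epoch %d: loss %.4f", epoch, history.loss[-1])
    if config.checkpoint_path:
        save_checkpoint(model, config.checkpoint_path)
    return model, history


def evaluate(model: SegmentationModel, samples, threshold=0.5, size=576):
    """Preprocess, predict, binarize at ``threshold`` and score each sample.

    Returns (list of MetricRecord, summary DataFrame).  Deterministic given
    fixed weights.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("evaluate requires at least one sample")
    was_training = model.training
    model.eval()
    records = []
    for s in samples:
        img, mask = preprocess(s, size=size)
        probs = model(img[None]).data[0, 0]
        records.append(metric_record(binarize(probs, threshold), mask,
                                     image_id=s.image_id))
    model.train(was_training)
    return records, summarize(records)
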