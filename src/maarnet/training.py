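"""Supervised training loop, loss with auxiliary deep supervision, prediction.

The loss is pixelwise cross-entropy over the two classes; during training
the auxiliary branch contributes a second cross-entropy term weighted by
``aux_weight`` (deep-supervision style):

    L = CE(main, mask) + aux_weight * CE(aux, mask)

At validation/inference the auxiliary branch is off and only the main term
remains.  The source task never published its training recipe, so the
optimizer (Adam), learning rate, batch size and loss here are
package-level defaults, all exposed in :class:`TrainConfig`.

Training is deterministic given ``TrainConfig.seed``: it seeds weight
initialization (via the model), data order and nothing else (no
augmentation is applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, no_grad
from .metrics import MetricReport, evaluate_dataset
from .model import MAARNet
from .synthetic import SamplePair

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "compute_loss", "train", "predict", "image_to_input"]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    aux_weight: float = 0.4
    seed: int = 0
    loss_name: str = "cross_entropy"
    # step learning-rate schedule: multiply by lr_decay every lr_decay_every
    # epochs (0 disables)
    lr_decay: float = 0.3
    lr_decay_every: int = 0
    # optional early stop: finish once training-set IoU reaches this level,
    # checked every `check_every` epochs (None disables the check)
    target_iou: float | None = None
    check_every: int = 10

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.aux_weight < 0:
            raise ValueError("aux_weight must be >= 0")
        if self.loss_name != "cross_entropy":
            raise ValueError(f"unknown loss '{self.loss_name}'")


def image_to_input(image: np.ndarray, dtype=np.float64) -> np.ndarray:
    """8-bit (H, W, 3) image -> (3, H, W) float in [0, 1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    return image.astype(dtype).transpose(2, 0, 1) / np.asarray(255.0, dtype)


def compute_loss(main_logits: Tensor, aux_logits: Tensor | None,
                 mask: np.ndarray, aux_weight: float) -> Tensor:
    """CE(main) + aux_weight * CE(aux); the aux term only when logits exist."""
    loss = nn.cross_entropy(main_logits, mask)
    if aux_logits is not None and aux_weight > 0:
        loss = loss + aux_weight * nn.cross_entropy(aux_logits, mask)
    return loss


def _stack_batch(samples: list[SamplePair], dtype=np.float32) -> tuple[Tensor, np.ndarray]:
    xs = np.stack([image_to_input(s.image, dtype) for s in samples])
    ys = np.stack([s.mask.astype(np.int64) for s in samples])
    return Tensor(xs), ys


def train(model: MAARNet, dataset: list[SamplePair], config: TrainConfig,
          val_dataset: list[SamplePair] | None = None):
    """Train ``model`` in place; returns a per-epoch history list.

    Each history entry holds the epoch's mean training loss and, when a
    validation set is given, a :class:`MetricReport` on it.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    model.astype(np.float32)  # single precision is ample for SGD training
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    n = len(dataset)
    for epoch in range(config.epochs):
        if config.lr_decay_every:
            optimizer.lr = config.learning_rate * (
                config.lr_decay ** (epoch // config.lr_decay_every))
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = [dataset[i] for i in order[start:start + config.batch_size]]
            x, y = _stack_batch(batch)
            out = model(x)
            loss = compute_loss(out.logits, out.aux_logits, y, config.aux_weight)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}, step "
                    f"{start // config.batch_size}; aborting")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(value)
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if val_dataset:
            entry["val"] = evaluate(model, val_dataset)
        history.append(entry)
        logger.info("epoch %d loss %.4f", epoch, entry["loss"])
        if config.target_iou is not None and (epoch + 1) % config.check_every == 0:
            report = evaluate(model, dataset)
            entry["train_iou"] = report.iou
            if report.iou >= config.target_iou:
                logger.info("target IoU %.3f reached at epoch %d",
                            config.target_iou, epoch)
                break
    return history


def predict(model: MAARNet, image: np.ndarray) -> np.ndarray:
    """Binary vessel mask (H, W) uint8 for an 8-bit RGB image."""
    model.eval()
    dtype = next((p.data.dtype for p in model.parameters()), np.float64)
    x = Tensor(image_to_input(image, dtype)[None])
    with no_grad():
        out = model(x)
    return np.argmax(out.logits.data[0], axis=0).astype(np.uint8)


def evaluate(model: MAARNet, dataset: list[SamplePair]) -> MetricReport:
    """Dataset metrics of the model's predictions (per-image aggregation)."""
    preds = [predict(model, s.image) for s in dataset]
    return evaluate_dataset(preds, [s.mask for s in dataset])
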