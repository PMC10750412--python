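"""Supervised training of the skull networks.

Recipe: voxelwise binary cross-entropy against the intact-skull
occupancy, Adadelta (rho 0.95, eps 1e-6, lr 1.0 — the optimiser's whole
point is not needing a tuned learning rate), per-epoch reshuffling of
the training set, and best-validation-loss checkpoint selection. The
reference batch sizes are 10 for the completion network and 4 for the
enhancement network; epochs and dataset sizes here default to desk
scale so a full run fits in CPU minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.engine import Adadelta
from .nn.networks import DEFAULT_THRESHOLD, ModelState
from .volume import BinaryVolume, ScalarVolume

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "bce_loss",
    "train_model",
    "select_best_checkpoint",
]

_CLIP = 1e-7


@dataclass
class TrainingConfig:
    batch_size: int = 10          # reference: 10 (completion) / 4 (enhancement)
    epochs: int = 50
    rho: float = 0.95
    eps: float = 1e-6
    lr: float = 1.0
    loss: str = "bce"
    shuffle_each_epoch: bool = True
    seed: int = 0
    validation_fraction: float = 0.2
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss != "bce":
            raise ValueError("only binary cross-entropy is supported")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """0-based argmin of the validation loss; ties -> earliest."""
        losses = self.val_loss if self.val_loss else self.train_loss
        if not losses:
            raise ValueError("empty history")
        return int(np.argmin(losses))


def _as_array(v) -> np.ndarray:
    if isinstance(v, (BinaryVolume, ScalarVolume)):
        return np.asarray(v.values, dtype=np.float32)[..., None]
    return np.asarray(v, dtype=np.float32)


def bce_loss(pred, target) -> float:
    """Mean voxelwise binary cross-entropy.

    ``pred`` is clipped to [1e-7, 1 - 1e-7] first (the stage-1 residual
    head can exceed 1 on bone voxels; clipping maps those to
    certainty).
    """
    p = np.asarray(pred.values if isinstance(pred, ScalarVolume) else pred, dtype=np.float64)
    t = np.asarray(
        target.values if isinstance(target, (BinaryVolume, ScalarVolume)) else target,
        dtype=np.float64,
    )
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


def _bce_grad(out: np.ndarray, t: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(out); zero where the prediction sits in the clip zone.

    Generic form for callers holding only the network output; the
    training loop instead uses the networks' fused ``loss_grad`` (BCE
    through the sigmoid), which stays informative at saturation.
    """
    p = np.clip(out, _CLIP, 1.0 - _CLIP)
    g = (p - t) / (p * (1.0 - p)) / p.size
    g[(out < _CLIP) | (out > 1.0 - _CLIP)] = 0.0
    return g.astype(np.float32)


def _stack(samples: list) -> tuple[list[np.ndarray], np.ndarray]:
    """Samples are (inputs..., target) tuples of volumes/arrays."""
    n_in = len(samples[0]) - 1
    inputs = [
        np.stack([_as_array(s[i]) for s in samples]) for i in range(n_in)
    ]
    targets = np.stack([_as_array(s[-1]) for s in samples])
    return inputs, targets


def _epoch_loss(net, samples, batch_size: int) -> float:
    total, nvox = 0.0, 0
    for i in range(0, len(samples), batch_size):
        inputs, t = _stack(samples[i : i + batch_size])
        out = net.forward(*inputs)
        total += bce_loss(out, t) * t.size
        nvox += t.size
    return total / nvox


def train_model(
    model: ModelState,
    datasets: list,
    config: TrainingConfig,
    validation: list | None = None,
) -> tuple[ModelState, TrainingHistory]:
    """Train ``model`` on ``datasets`` and return it at its
    best-validation-loss epoch, plus the full history.

    ``datasets`` is a list of sample tuples ``(input, target)`` for the
    completion network or ``(low_input, high_input, target)`` for the
    enhancement network; entries may be volumes or raw arrays. When
    ``validation`` is None the tail ``validation_fraction`` of the data
    is split off (disjointly) before training.
    """
    if not datasets:
        raise ValueError("empty training set")
    net = model.net
    samples = list(datasets)
    if validation is None:
        n_val = int(round(config.validation_fraction * len(samples)))
        validation = samples[len(samples) - n_val :]
        samples = samples[: len(samples) - n_val]
        if not samples:
            raise ValueError("validation split consumed every sample")
    rng = np.random.default_rng(config.seed)
    optimiser = Adadelta(net.parameters, rho=config.rho, eps=config.eps, lr=config.lr)
    history = TrainingHistory()
    best_params = net.copy_parameters()
    best_val = np.inf
    order = np.arange(len(samples))
    for _ in range(config.epochs):
        if config.shuffle_each_epoch:
            rng.shuffle(order)
        running, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = [samples[j] for j in order[i : i + config.batch_size]]
            inputs, t = _stack(batch)
            cache: dict = {}
            out = net.forward(*inputs, cache=cache)
            running += bce_loss(out, t) * t.size
            seen += t.size
            # BCE fused with the sigmoid head, summed over voxels and
            # averaged over the batch: keeps gradients well above
            # Adadelta's eps and informative at saturation
            gz = net.loss_grad(cache, inputs[-1], t, 1.0 / t.shape[0])
            grads = net.backward(cache, gz, from_logits=True)
            optimiser.step(grads)
        history.train_loss.append(running / seen)
        val = (
            _epoch_loss(net, validation, config.batch_size)
            if validation
            else history.train_loss[-1]
        )
        history.val_loss.append(val)
        if val < best_val:  # strict: ties keep the earliest epoch
            best_val = val
            best_params = net.copy_parameters()
    net.set_parameters(best_params)
    return model, history


def select_best_checkpoint(history: TrainingHistory, checkpoints: list):
    """Return the checkpoint at the minimal validation loss (one
    checkpoint per epoch); ties resolve to the earliest epoch."""
    if not history.val_loss:
        raise ValueError("empty history")
    if len(checkpoints) != len(history.val_loss):
        raise ValueError(
            f"{len(checkpoints)} checkpoints for {len(history.val_loss)} epochs"
        )
    return checkpoints[history.best_epoch]
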