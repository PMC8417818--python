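"""Unsupervised optimisation loop.

The networks are trained without ground truth by minimising
``L_sim + alpha*L_reg + beta*L_cons`` over simulated or acquired RF
sequences. The learning-rate schedule follows a reduce-on-plateau rule:
start at 1e-3, multiply by 0.8 whenever the best validation loss has not
improved for 10 consecutive epochs, and stop once the difference between
consecutive learning rates falls below 1e-8.

Variant handling: the feed-forward network trains on random frame pairs
whose interframe interval is drawn uniformly from the sequence (beta is
forced to zero — there is no temporal stream); the recurrent network
consumes whole sequences (optionally split into fixed-length windows)
with full backpropagation through time, and the consistency term applies
from the second pair of each sequence onward.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .losses import (LossWeights, similarity_loss, smoothness_loss,
                     consistency_loss, total_loss)
from .networks import USENet
from .strain import lsq_matrix
from ._autodiff import Tensor

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "make_training_batches",
    "lr_schedule_step",
    "should_stop",
    "train",
]


@dataclass
class TrainConfig:
    lr_init: float = 1e-3
    plateau_factor: float = 0.8
    plateau_patience: int = 10
    stop_delta: float = 1e-8
    weights: LossWeights = field(default_factory=LossWeights)
    max_epochs: int = 500
    seed: int = 0
    validation_fraction: float = 0.2
    variant: str = "reusenet"
    optimizer: str = "adam"
    strain_window: int = 13
    sequence_window: int | None = None
    pairs_per_sequence: int | None = None
    warmup_steps: int = 50
    grad_clip: float = 1.0

    def __post_init__(self):
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.stop_delta <= 0:
            raise ValueError("stop_delta must be positive")
        if self.variant not in ("usenet", "reusenet"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)

    def append(self, **kwargs):
        if self.epochs and kwargs["lr"] > self.epochs[-1]["lr"] + 1e-15:
            raise ValueError("learning rate must be non-increasing")
        kwargs["epoch"] = len(self.epochs)
        self.epochs.append(kwargs)

    @property
    def val_losses(self):
        return [e["val_loss"] for e in self.epochs]

    def as_rows(self):
        return list(self.epochs)


def _frames_of(seq):
    return seq.frames if hasattr(seq, "frames") else np.asarray(seq)


def make_training_batches(sequences, variant: str, seed: int,
                          window: int | None = None,
                          pairs_per_sequence: int | None = None):
    """Build one epoch's worth of training items.

    * ``usenet``: random ``(pre, post)`` frame pairs per sequence, the
      interframe interval uniform on ``[1, len-1]``;
    * ``reusenet``: whole sequences, or consecutive non-overlapping
      ``window``-frame chunks for long acquisitions.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no training sequences")
    rng = np.random.default_rng(seed)
    items = []
    if variant == "usenet":
        for seq in sequences:
            frames = _frames_of(seq)
            n = len(frames)
            if n < 2:
                raise ValueError("sequence shorter than 2 frames")
            draws = pairs_per_sequence or (n - 1)
            for _ in range(draws):
                gap = int(rng.integers(1, n))
                start = int(rng.integers(0, n - gap))
                items.append((frames[start], frames[start + gap]))
        order = rng.permutation(len(items))
        return [items[i] for i in order]
    for seq in sequences:
        frames = _frames_of(seq)
        n = len(frames)
        if n < 2:
            raise ValueError("sequence shorter than 2 frames")
        if window is None or n <= window:
            items.append(frames)
        else:
            for start in range(0, n - window + 1, window):
                items.append(frames[start:start + window])
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def lr_schedule_step(history: TrainHistory, current_lr: float,
                     config: TrainConfig) -> float:
    """Reduce-on-plateau: cut the rate when the best validation loss has
    not improved for ``plateau_patience`` consecutive epochs."""
    losses = history.val_losses
    if not losses:
        raise ValueError("history must contain at least one epoch")
    best_epoch = int(np.argmin(losses))  # first occurrence of the best value
    lrs = [e["lr"] for e in history.epochs]
    last_cut = 0
    for i in range(1, len(lrs)):
        if lrs[i] < lrs[i - 1] - 1e-18:
            last_cut = i
    stagnant = len(losses) - 1 - max(best_epoch, last_cut)
    if stagnant >= config.plateau_patience:
        return current_lr * config.plateau_factor
    return current_lr


def should_stop(lr_prev: float, lr_new: float, config: TrainConfig) -> bool:
    """Stop once a reduction happened but was smaller than ``stop_delta``."""
    diff = lr_prev - lr_new
    return 0 < diff < config.stop_delta


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._bwd = bwd
    return out


def strain_from_field(field: Tensor, window: int) -> Tensor:
    """LSQSE strain (2D tensor) from a (2, H, W) displacement tensor."""
    k = Tensor(lsq_matrix(field.shape[-2], window).astype(field.dtype))
    return _matmul(k, field[0])


def _pair_loss(model, pre, post, weights: LossWeights, strain_prev,
               strain_window: int, state=None):
    """Forward one pair and assemble the loss graph.

    Returns ``(breakdown, strain_tensor, new_state)``; ``strain_prev`` is
    ``None`` for the first pair (the consistency term is then skipped).
    """
    if state is not None:
        field, state = model.forward_step(pre, post, state)
    else:
        field = model.forward_pair(pre, post)
    pre_n = (pre - pre.mean()) / (pre.std() + 1e-8)
    post_n = (post - post.mean()) / (post.std() + 1e-8)
    sim = similarity_loss(Tensor(pre_n.astype(np.float32)),
                          Tensor(post_n.astype(np.float32)), field, weights)
    reg = smoothness_loss(field, weights)
    strain = strain_from_field(field, strain_window)
    cons = None
    if strain_prev is not None and weights.beta > 0:
        try:
            cons = consistency_loss(strain_prev, strain, field, weights)
        except ValueError:
            # near-constant strain (e.g. the identity-initialised model):
            # the consistency score is undefined, so the term is skipped
            cons = None
    eff = weights if cons is not None else \
        LossWeights(weights.alpha, 0.0, weights.lncc_window, weights.epsilon,
                    weights.regularize_lateral)
    breakdown = total_loss(sim, reg, cons, eff)
    return breakdown, strain, state


def _evaluate(model, sequences, config: TrainConfig) -> float:
    """Mean total loss over validation items (no gradient step)."""
    model.eval()
    weights = config.weights
    totals = []
    for item in sequences:
        frames = _frames_of(item)
        if config.variant == "usenet":
            for t in range(1, len(frames)):
                b, _, _ = _pair_loss(model, frames[t - 1], frames[t],
                                     LossWeights(weights.alpha, 0.0,
                                                 weights.lncc_window,
                                                 weights.epsilon),
                                     None, config.strain_window)
                totals.append(b.total.item())
        else:
            state = model.init_state(frames[0].shape)
            strain_prev = None
            for t in range(1, len(frames)):
                b, strain_prev, state = _pair_loss(
                    model, frames[t - 1], frames[t], weights,
                    strain_prev, config.strain_window, state)
                strain_prev = strain_prev.detach()
                state = [(h.detach(), c.detach()) for h, c in state]
                totals.append(b.total.item())
    model.train()
    return float(np.mean(totals))


def train(model, sequences, config: TrainConfig, verbose: bool = False,
          callback=None):
    """Optimise ``model`` on RF sequences; returns ``(model, history)``.

    ``sequences`` is a list of :class:`~elastonet.containers.RFSequence`
    or plain ``(T, H, W)`` arrays. The data is split into training and
    validation subsets with ``validation_fraction`` (at least one
    sequence each) using ``config.seed``.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no training data")
    is_usenet = isinstance(model, USENet)
    if is_usenet != (config.variant == "usenet"):
        raise ValueError("model class does not match config.variant")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(sequences))
    n_val = max(1, int(round(config.validation_fraction * len(sequences)))) \
        if len(sequences) > 1 else 0
    val = [sequences[i] for i in order[:n_val]]
    tr = [sequences[i] for i in order[n_val:]] or list(sequences)

    weights = config.weights
    if is_usenet and weights.beta != 0.0:
        weights = LossWeights(weights.alpha, 0.0, weights.lncc_window,
                              weights.epsilon, weights.regularize_lateral)
    opt_cls = nn.Adam if config.optimizer == "adam" else nn.SGD
    opt = opt_cls(model.parameters(), lr=config.lr_init)
    history = TrainHistory()
    lr = config.lr_init
    global_step = 0
    model.train()

    for epoch in range(config.max_epochs):
        t0 = time.time()
        items = make_training_batches(
            sequences=tr, variant=config.variant,
            seed=config.seed + 1000 + epoch,
            window=config.sequence_window,
            pairs_per_sequence=config.pairs_per_sequence)
        sims, regs, conss, tots = [], [], [], []
        for item in items:
            opt.zero_grad()
            if config.variant == "usenet":
                pre, post = item
                b, _, _ = _pair_loss(model, pre, post, weights, None,
                                     config.strain_window)
                loss = b.total
            else:
                frames = item
                state = model.init_state(frames[0].shape)
                strain_prev = None
                loss = None
                parts = []
                for t in range(1, len(frames)):
                    b, strain_prev, state = _pair_loss(
                        model, frames[t - 1], frames[t], weights,
                        strain_prev, config.strain_window, state)
                    parts.append(b)
                    loss = b.total if loss is None else loss + b.total
                loss = loss * (1.0 / (len(frames) - 1))
                b = parts[-1]
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: "
                    f"sim={b.sim.item() if b.sim is not None else None} "
                    f"reg={b.reg.item() if b.reg is not None else None}")
            loss.backward()
            if config.grad_clip:
                norm = np.sqrt(sum(float((p.grad ** 2).sum())
                                   for p in model.parameters()
                                   if p.grad is not None))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            global_step += 1
            warm = min(1.0, global_step / config.warmup_steps) \
                if config.warmup_steps else 1.0
            opt.lr = lr * warm
            opt.step()
            fb = b.as_floats()
            sims.append(fb.sim)
            regs.append(fb.reg)
            conss.append(fb.cons)
            tots.append(lv)
        val_loss = _evaluate(model, val or tr, config)
        history.append(train_loss=float(np.mean(tots)),
                       sim=float(np.mean(sims)), reg=float(np.mean(regs)),
                       cons=float(np.mean(conss)), val_loss=val_loss, lr=lr,
                       wall_time=time.time() - t0)
        if verbose:
            print(f"epoch {epoch:3d}  train {np.mean(tots):+.4f}  "
                  f"val {val_loss:+.4f}  lr {lr:.2e}", flush=True)
        if callback is not None:
            callback(epoch, model, history)
        new_lr = lr_schedule_step(history, lr, config)
        if should_stop(lr, new_lr, config):
            break
        lr = new_lr
    return model, history
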