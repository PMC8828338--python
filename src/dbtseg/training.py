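"""Training loop: balanced patch epochs, Adagrad on the f_alpha loss,
and the by-volume k-fold cross-validation split.

Each epoch draws a class-balanced patch sample (fresh per-epoch seed
derived from the master seed), expands it by the four right-angle
rotations, shuffles, and runs minibatch Adagrad steps on the
1 - f_alpha loss computed over all pixels of the batch (batch-global
pooling — the stabler choice when masses occupy a small fraction of any
single patch).  Everything is seeded and bit-deterministic on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TrainingGroup
from .losses import f_alpha_loss_grad
from .network import DilatedFCN, softmax_channels
from .patches import Patch, augment_rotations, balanced_epoch_sample


@dataclass
class FoldSplit:
    """Assignment of volume ids to k cross-validation folds (by volume,
    never by patch)."""

    folds: list[list[int]]

    def train_test(self, k: int) -> tuple[list[int], list[int]]:
        test = self.folds[k]
        train = [v for i, f in enumerate(self.folds) if i != k for v in f]
        return train, test


def make_folds(volume_ids: list[int], k: int = 10, seed: int = 0) -> FoldSplit:
    """Partition volumes into k near-equal folds (sizes differ by <= 1)."""
    if len(volume_ids) < k:
        raise ValueError(f"need at least {k} volumes for {k}-fold CV, got {len(volume_ids)}")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(volume_ids)))
    folds: list[list[int]] = [[] for _ in range(k)]
    for i, idx in enumerate(perm):
        folds[i % k].append(volume_ids[idx])
    return FoldSplit(folds=[sorted(f) for f in folds])


class Adagrad:
    """Adagrad: per-parameter accumulated squared gradients.

    Uses the Keras-style initial accumulator value of 0.1 and eps 1e-7,
    matching the optimizer convention of the framework the published
    settings were tuned with.
    """

    def __init__(self, params: list[tuple[object, str]], lr: float = 0.01,
                 initial_accumulator: float = 0.1, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.eps = eps
        self.accum = [
            np.full_like(getattr(obj, name), initial_accumulator, dtype=np.float32)
            for obj, name in params
        ]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        for (obj, name), acc in zip(self.params, self.accum):
            g = getattr(obj, "d" + name)
            acc += g * g
            new = getattr(obj, name) - self.lr * g / (np.sqrt(acc) + self.eps)
            setattr(obj, name, new.astype(np.float32))


def _batch_step(
    model: DilatedFCN,
    opt: Adagrad,
    batch: list[Patch],
    alpha: float,
    eps: float,
) -> float:
    x = np.stack([p.pixels for p in batch])[:, None, :, :].astype(np.float32)
    t = np.stack([p.mask for p in batch]).astype(np.float64)
    logits = model.forward(x, train=True)
    probs = softmax_channels(logits)
    s = probs[:, 1].astype(np.float64)
    loss, ds = f_alpha_loss_grad(s, t, alpha=alpha, eps=eps)
    # chain through the two-channel softmax: upstream only on the mass channel
    s32 = probs[:, 1]
    g1 = ds.astype(np.float32) * s32 * (1.0 - s32)
    dlogits = np.stack([-g1, g1], axis=1)
    model.backward(dlogits)
    opt.step()
    return float(loss)


def train(
    model: DilatedFCN,
    patches: list[Patch],
    cfg: TrainingGroup,
    seed: int = 0,
    augment: bool = True,
    callback=None,
) -> list[float]:
    """Train in place; returns the per-epoch mean loss trace.

    Per epoch: a class-balanced draw of ``batch_size * batches_per_epoch
    / (2 * n_rotations)`` patches per class, rotation augmentation,
    shuffle, Adagrad minibatch steps.  A non-finite loss aborts with the
    epoch and batch index.
    """
    cfg.validate()
    opt = Adagrad(model.parameters(), lr=cfg.learning_rate)
    ss = np.random.SeedSequence(seed)
    epoch_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.epochs)]
    n_rot = 4 if augment else 1
    per_class = max(cfg.batch_size * cfg.batches_per_epoch // (2 * n_rot), 1)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(epoch_seeds[epoch])
        sample = balanced_epoch_sample(patches, per_class, epoch_seeds[epoch])
        if augment:
            sample = [q for p in sample for q in augment_rotations(p)]
        order = rng.permutation(len(sample))
        losses = []
        for b in range(cfg.batches_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            if idx.size == 0:
                break
            batch = [sample[i] for i in idx]
            loss = _batch_step(model, opt, batch, cfg.alpha, cfg.smooth_eps)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {b}"
                )
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if callback is not None:
            callback(epoch, trace[-1])
    return trace
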