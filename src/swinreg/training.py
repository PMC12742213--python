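"""Unsupervised training: Adam optimisation of the multi-resolution NCC
objective, seeded data splitting, model selection and logging.

Model selection: training is label-free, so the checkpoint with the lowest
mean validation *similarity* loss is retained (ties resolve to the earliest
epoch).  A divergence guard aborts after 10 consecutive non-finite losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _tensor
from .loss import DEFAULT_LAMBDA, DEFAULT_WINDOW, similarity_loss_t, training_loss_t
from .network import MultiStageAffineNetwork, build_pyramid
from .warp import downsample_half_t, warp_volume_t


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 300
    seed: int = 0
    lam: float = DEFAULT_LAMBDA
    ncc_window: int = DEFAULT_WINDOW
    validation_fraction: float = 0.2
    split_repeats: int = 5
    patience: int = 30              # early stop: epochs without val improvement
    max_iterations: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class DatasetSplit:
    """80/20 outer train/test split with five seeded train/val resamples of
    the outer-training set."""

    test: list
    outer_train: list
    resamples: list  # list of (train, val) tuples


def split_dataset(ids, seed: int, repeats: int = 5,
                  test_fraction: float = 0.2,
                  validation_fraction: float = 0.2) -> DatasetSplit:
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 subjects to split")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(test_fraction * len(ids)))
    test, outer = order[:n_test], order[n_test:]
    resamples = []
    for _ in range(repeats):
        perm = [outer[i] for i in rng.permutation(len(outer))]
        n_val = int(round(validation_fraction * len(outer)))
        resamples.append((perm[n_val:], perm[:n_val]))
    return DatasetSplit(test=test, outer_train=outer, resamples=resamples)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def validation_similarity(network: MultiStageAffineNetwork, pairs,
                          window: int = DEFAULT_WINDOW) -> float:
    """Mean similarity loss over pairs (no gradient, eval mode)."""
    if not pairs:
        return float("nan")
    network.eval()
    total = 0.0
    levels = network.config.levels
    with _tensor.no_grad():
        for pair in pairs:
            res = network.forward(pair.fixed, pair.moving)
            f_pyr = build_pyramid(pair.fixed, levels)
            warped = warp_volume_t(pair.moving, res.transform_t, pair.fixed.shape)
            w_pyr = [warped]
            for _ in range(levels - 1):
                w_pyr.append(downsample_half_t(w_pyr[-1]))
            total += float(similarity_loss_t(f_pyr, w_pyr[::-1], window).item())
    return total / len(pairs)


@dataclass
class TrainResult:
    network: MultiStageAffineNetwork
    history: pd.DataFrame            # per-iteration sim/reg/total
    val_history: list                # per-epoch mean validation sim loss
    best_val: float
    best_epoch: int
    iterations: int

    def save_log(self, path) -> None:
        self.history.to_csv(path, index=False)


def train(pairs, cfg: TrainConfig,
          network: MultiStageAffineNetwork | None = None,
          val_pairs=None) -> TrainResult:
    """Optimise the network on (fixed, moving) pairs.

    ``pairs`` are objects with ``fixed``/``moving`` arrays (``swinreg.synthetic``
    pairs work directly).  If ``val_pairs`` is None a validation split of
    ``cfg.validation_fraction`` is carved out of ``pairs`` (seeded).
    """
    rng = np.random.default_rng(cfg.seed)
    if network is None:
        network = MultiStageAffineNetwork(seed=cfg.seed)
    if val_pairs is None:
        pairs = list(pairs)
        order = rng.permutation(len(pairs))
        n_val = max(1, int(round(cfg.validation_fraction * len(pairs)))) if len(pairs) > 1 else 0
        val_pairs = [pairs[i] for i in order[:n_val]]
        train_pairs = [pairs[i] for i in order[n_val:]]
    else:
        train_pairs = list(pairs)
        val_pairs = list(val_pairs)

    levels = network.config.levels
    pyramid_cache: dict[int, list] = {}

    def fixed_pyramid(arr: np.ndarray) -> list:
        key = id(arr)
        if key not in pyramid_cache:
            pyramid_cache[key] = build_pyramid(arr, levels)
        return pyramid_cache[key]

    opt = Adam(network.parameters(), lr=cfg.learning_rate)
    rows = []
    val_history = []
    best_val = np.inf
    best_epoch = -1
    best_state = network.state_dict()
    iteration = 0
    bad_streak = 0
    stale_epochs = 0

    for epoch in range(cfg.epochs):
        network.train()
        for idx in rng.permutation(len(train_pairs)):
            if cfg.max_iterations is not None and iteration >= cfg.max_iterations:
                break
            pair = train_pairs[idx]
            res = network.forward(pair.fixed, pair.moving)
            loss, sim, reg = training_loss_t(
                pair.fixed, fixed_pyramid(pair.fixed), pair.moving,
                res.transform_t, res.stage_params_t,
                lam=cfg.lam, window=cfg.ncc_window)
            if not np.isfinite(loss.item()):
                bad_streak += 1
                if bad_streak >= 10:
                    raise RuntimeError("training diverged: 10 consecutive non-finite losses")
                continue
            bad_streak = 0
            network.zero_grad()
            loss.backward()
            opt.step()
            iteration += 1
            rows.append({"iteration": iteration, "epoch": epoch,
                         "sim": sim, "reg": reg, "total": float(loss.item())})

        val = validation_similarity(network, val_pairs, cfg.ncc_window)
        val_history.append(val)
        if np.isfinite(val) and val < best_val:
            best_val = val
            best_epoch = epoch
            best_state = network.state_dict()
            stale_epochs = 0
        else:
            stale_epochs += 1
        if cfg.max_iterations is not None and iteration >= cfg.max_iterations:
            break
        if cfg.patience and stale_epochs >= cfg.patience:
            break

    if np.isfinite(best_val):
        network.load_state_dict(best_state)
    history = pd.DataFrame(rows, columns=["iteration", "epoch", "sim", "reg", "total"])
    return TrainResult(network=network, history=history, val_history=val_history,
                       best_val=float(best_val), best_epoch=best_epoch,
                       iterations=iteration)
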