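"""Composite dice+focal loss, training-time augmentation, and the
optimization loop.

The loss is 0.5 * dice + 0.5 * focal.  Dice is averaged unweighted over
the three classes (background, normal, PVC); the focal term carries
per-class alpha weights (1, 1, 1.5) so the PVC class — rare but the
clinical point of the exercise — contributes more per sample, with the
usual focusing exponent gamma = 2.  Optimization is Adam at learning
rate 0.001 (betas 0.9/0.999, no weight decay) over 30 s windows drawn
with PVC-oversampling weights.

Augmentation applies, each with probability 0.75: amplitude scaling by
U[0.6, 1.4]; a constant offset U[-0.2, 0.2] mV; additive gaussian, pink
or brown noise at a standard deviation drawn from U[0, 0.2] times the
window's own standard deviation.  Label masks are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import oversample_pvc
from .nn import Adam
from .synthetic import NOISE_COLORS, generate_noise

EPS_DICE = 1e-6
PROB_FLOOR = 1e-8


@dataclass
class TrainConfig:
    dice_weight: float = 0.5
    focal_weight: float = 0.5
    focal_alpha: tuple = (1.0, 1.0, 1.5)
    focal_gamma: float = 2.0
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.0
    batch_size: int = 32
    epochs: int = 30
    target_pvc_window_frac: float = 0.5
    seed: int = 0

    def validate(self):
        if abs(self.dice_weight + self.focal_weight - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")
        if min(self.focal_alpha) <= 0 or self.focal_gamma < 0:
            raise ValueError("alpha must be positive and gamma >= 0")


@dataclass
class AugmentConfig:
    p_scale: float = 0.75
    scale_range: tuple = (0.6, 1.4)
    p_offset: float = 0.75
    offset_range_mv: tuple = (-0.2, 0.2)
    p_noise: float = 0.75
    noise_level_range: tuple = (0.0, 0.2)   # relative to window std
    noise_colors: tuple = NOISE_COLORS

    def validate(self):
        for p in (self.p_scale, self.p_offset, self.p_noise):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (self.scale_range, self.offset_range_mv, self.noise_level_range):
            if r[0] > r[1]:
                raise ValueError("ranges must be ordered")


# ---------------------------------------------------------------------------
# losses

def _check_probs(probs, target):
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=int)
    if probs.ndim != 2 or probs.shape[0] != target.shape[0]:
        raise ValueError("probs must be L x C with one target label per row")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1")
    return probs, target


def dice_loss(probs, target, n_classes: int = 3) -> float:
    """Soft-dice loss, mean over classes, in [0, 1]."""
    probs, target = _check_probs(probs, target)
    onehot = np.eye(n_classes)[target]
    num = 2.0 * (probs * onehot).sum(axis=0) + EPS_DICE
    den = probs.sum(axis=0) + onehot.sum(axis=0) + EPS_DICE
    return float(np.mean(1.0 - num / den))


def focal_loss(probs, target, alpha=(1.0, 1.0, 1.5), gamma: float = 2.0) -> float:
    """Mean focal loss: -alpha_g (1 - p_g)^gamma log p_g."""
    probs, target = _check_probs(probs, target)
    p_g = np.maximum(probs[np.arange(len(target)), target], PROB_FLOOR)
    a_g = np.asarray(alpha, dtype=np.float64)[target]
    return float(np.mean(-a_g * (1.0 - p_g) ** gamma * np.log(p_g)))


def composite_loss(probs, target, cfg: TrainConfig | None = None) -> float:
    cfg = cfg or TrainConfig()
    return (cfg.dice_weight * dice_loss(probs, target)
            + cfg.focal_weight * focal_loss(probs, target,
                                            cfg.focal_alpha, cfg.focal_gamma))


def composite_loss_grad(logits, target, cfg: TrainConfig):
    """Loss and gradient w.r.t. logits for a batch.

    logits: (N, C, L) float; target: (N, L) int.  Dice is computed over
    the flattened batch.  Returns (total, dice, focal, dlogits).
    """
    N, C, L = logits.shape
    z = logits.astype(np.float64).transpose(0, 2, 1).reshape(N * L, C)
    t = np.asarray(target, dtype=int).reshape(N * L)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    onehot = np.eye(C)[t]
    # dice
    num = 2.0 * (p * onehot).sum(axis=0) + EPS_DICE
    den = p.sum(axis=0) + onehot.sum(axis=0) + EPS_DICE
    dice = float(np.mean(1.0 - num / den))
    ddice_dp = -(2.0 * onehot * den - num) / den ** 2 / C
    # focal
    a = np.asarray(cfg.focal_alpha, dtype=np.float64)[t]
    g = cfg.focal_gamma
    p_g = np.maximum(p[np.arange(len(t)), t], PROB_FLOOR)
    one_m = 1.0 - p_g
    focal = float(np.mean(-a * one_m ** g * np.log(p_g)))
    dfocal_pg = a * (g * np.where(one_m > 0, one_m ** max(g - 1, 0), 0.0)
                     * np.log(p_g) - one_m ** g / p_g) / len(t)
    dfocal_dp = np.zeros_like(p)
    dfocal_dp[np.arange(len(t)), t] = dfocal_pg
    dl_dp = cfg.dice_weight * ddice_dp + cfg.focal_weight * dfocal_dp
    # back through softmax
    dot = (dl_dp * p).sum(axis=1, keepdims=True)
    dz = p * (dl_dp - dot)
    total = cfg.dice_weight * dice + cfg.focal_weight * focal
    dlogits = dz.reshape(N, L, C).transpose(0, 2, 1).astype(np.float32)
    return total, dice, focal, dlogits


# ---------------------------------------------------------------------------
# augmentation

def augment(samples: np.ndarray, cfg: AugmentConfig, rng) -> np.ndarray:
    """One augmented copy of a window; the label mask is unchanged."""
    cfg.validate()
    x = np.array(samples, dtype=np.float64)
    if rng.random() < cfg.p_scale:
        x = x * rng.uniform(*cfg.scale_range)
    if rng.random() < cfg.p_offset:
        x = x + rng.uniform(*cfg.offset_range_mv)
    if rng.random() < cfg.p_noise:
        color = cfg.noise_colors[rng.integers(len(cfg.noise_colors))]
        rel = rng.uniform(*cfg.noise_level_range)
        level = rel * float(np.std(x))
        x = x + generate_noise(color, len(x), level, fs=125.0, rng=rng)
    return x


# ---------------------------------------------------------------------------
# training loop

def train(model, windows, masks, cfg: TrainConfig | None = None,
          augment_cfg: AugmentConfig | None = None, verbose: bool = False):
    """Train the model in place; returns the per-epoch loss history.

    windows: (Nw, L) float array of preprocessed 30 s windows;
    masks: (Nw, L) integer labels.  Windows are drawn with replacement
    using PVC-oversampling weights, so each epoch sees len(windows)
    draws with an even PVC/normal window split in expectation.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    windows = np.asarray(windows, dtype=np.float32)
    masks = np.asarray(masks)
    if windows.shape != masks.shape:
        raise ValueError("windows and masks must align")
    has_pvc = (masks == 2).any(axis=1)
    if not has_pvc.any():
        import warnings
        warnings.warn("training set has no PVC windows; sampling uniformly")
        weights = np.full(len(windows), 1.0 / len(windows))
    else:
        weights = oversample_pvc(has_pvc, cfg.target_pvc_window_frac)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), model.gradients(), lr=cfg.learning_rate,
               beta1=cfg.beta1, beta2=cfg.beta2, weight_decay=cfg.weight_decay)
    model.train(True)
    history = []
    n = len(windows)
    for epoch in range(cfg.epochs):
        order = rng.choice(n, size=n, replace=True, p=weights)
        tot = dc = fc = 0.0
        steps = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            if augment_cfg is not None:
                xb = np.stack([augment(windows[i], augment_cfg, rng)
                               for i in idx]).astype(np.float32)
            else:
                xb = windows[idx]
            yb = masks[idx]
            model.zero_grad()
            logits = model.forward(xb[:, None, :])
            loss, dice, focal, dlogits = composite_loss_grad(logits, yb, cfg)
            if not np.isfinite(loss):
                raise RuntimeError(f"loss diverged (NaN/inf) at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            tot += loss
            dc += dice
            fc += focal
            steps += 1
        history.append({"epoch": epoch, "loss": tot / steps,
                        "dice": dc / steps, "focal": fc / steps})
        if verbose:
            print(f"epoch {epoch}: loss={tot / steps:.4f} "
                  f"dice={dc / steps:.4f} focal={fc / steps:.4f}")
    model.train(False)
    return history
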