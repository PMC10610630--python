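"""Seeded synthetic Holter-style ECG with ground-truth beat annotations.

The generator schedules a jittered sinus beat train and replaces beats
at random with premature ventricular contractions.  A PVC arrives early
(at a fraction of the running RR interval), has a wide (~140 ms)
dominant deflection of opposite polarity with an inverted T wave and no
P wave, and is followed by a full compensatory pause that restores the
sinus timing grid.  Normal beats are P-QRS-T composites of Gaussian
bumps.  Records can be contaminated with white/pink/brown noise and
sinusoidal baseline drift, and emitted on several leads with per-lead
amplitude scaling.

Morphology is deliberately a closed-form Gaussian-bump composition
rather than a dynamical-system model: it is fast, exactly reproducible,
and sufficient to exercise segmentation, labeling and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BeatAnnotation, BeatClass, ECGRecord

NOISE_COLORS = ("gaussian", "pink", "brown")


@dataclass
class SyntheticConfig:
    duration_s: float = 60.0
    fs: float = 360.0              # generated above 125 Hz so resampling is exercised
    mean_rr_s: float = 0.8
    rr_jitter_s: float = 0.04
    pvc_probability: float = 0.1
    coupling_fraction: float = 0.6
    noise_color: str = "pink"
    noise_level_mv: float = 0.05
    baseline_amp_mv: float = 0.1
    baseline_freq_hz: float = 0.3
    n_channels: int = 1
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.pvc_probability <= 1:
            raise ValueError("pvc_probability must lie in [0, 1]")
        if not 0 < self.coupling_fraction < 1:
            raise ValueError("coupling_fraction must lie in (0, 1)")
        if self.noise_color not in NOISE_COLORS:
            raise ValueError(f"unknown noise color {self.noise_color!r}")
        if self.noise_level_mv < 0:
            raise ValueError("noise level must be >= 0")


@dataclass
class SyntheticRecord:
    record: ECGRecord
    truth: list            # BeatAnnotation at the record's fs


# (amplitude mV, center offset s, width s) per wave
_NORMAL_WAVES = (
    (0.15, -0.20, 0.025),   # P
    (-0.10, -0.040, 0.010),  # Q
    (1.00, 0.0, 0.012),      # R
    (-0.20, 0.040, 0.012),   # S
    (0.30, 0.30, 0.060),     # T
)
_PVC_WAVES = (
    (-1.20, 0.0, 0.035),     # wide dominant deflection, opposite polarity
    (0.45, 0.32, 0.080),     # discordant T
)


def _add_beat(sig, fs, t_r, waves):
    for amp, off, width in waves:
        c = t_r + off
        lo = max(int((c - 5 * width) * fs), 0)
        hi = min(int((c + 5 * width) * fs) + 1, len(sig))
        if hi <= lo:
            continue
        t = np.arange(lo, hi) / fs
        sig[lo:hi] += amp * np.exp(-0.5 * ((t - c) / width) ** 2)


def generate_noise(color: str, length: int, level: float, fs: float,
                   seed=None, rng=None) -> np.ndarray:
    """Zero-mean noise of a given spectral color, scaled to std = level.

    gaussian is white (flat PSD), pink has PSD ~ 1/f, brown ~ 1/f^2
    (generated as the cumulative sum of white noise).
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if color not in NOISE_COLORS:
        raise ValueError(f"unknown noise color {color!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if length == 0 or level == 0:
        rng.standard_normal(length)  # keep stream position deterministic
        return np.zeros(length)
    white = rng.standard_normal(length)
    if color == "gaussian":
        x = white
    elif color == "brown":
        x = np.cumsum(white)
    else:  # pink: shape the amplitude spectrum by f^(-1/2)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(length, d=1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** -0.5
        x = np.fft.irfft(spec * shape, n=length)
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x * (level / sd)
    return x


def _schedule_beats(cfg: SyntheticConfig, rng):
    """Beat times and classes on the jittered sinus grid with PVCs.

    A PVC fires early, at coupling_fraction of the running RR after the
    previous beat, and suppresses the sinus beat it replaces; the next
    normal lands two RR intervals after the previous beat, so the RR
    pair around the PVC sums to 2 RR (full compensatory pause).  Each
    PVC event emits a PVC plus the pause-ending normal, so the internal
    event probability q solving q / (1 + q) = p, i.e. q = p / (1 - p),
    makes the expected PVC *beat* fraction equal pvc_probability.
    """
    times, classes = [], []
    t = 0.0
    end = cfg.duration_s - 0.3   # keep the T wave inside the record
    p = cfg.pvc_probability
    q = min(p / (1.0 - p), 1.0) if p < 1.0 else 1.0
    while True:
        rr = cfg.mean_rr_s + cfg.rr_jitter_s * rng.standard_normal()
        rr = max(rr, 0.3)
        if rng.random() < q:
            t_pvc = t + cfg.coupling_fraction * rr
            if t_pvc >= end:
                break
            times.append(t_pvc)
            classes.append(BeatClass.PVC)
            t = t + 2.0 * rr
            if t >= end:
                break
            times.append(t)
            classes.append(BeatClass.NORMAL)
        else:
            t = t + rr
            if t >= end:
                break
            times.append(t)
            classes.append(BeatClass.NORMAL)
    return times, classes


def generate_ecg(cfg: SyntheticConfig | None = None) -> SyntheticRecord:
    """Generate one seeded multi-lead record with ground truth."""
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    times, classes = _schedule_beats(cfg, rng)
    clean = np.zeros(n)
    truth = []
    for t_r, cls in zip(times, classes):
        idx = int(round(t_r * cfg.fs))
        if not 0 <= idx < n:
            continue
        waves = _PVC_WAVES if cls is BeatClass.PVC else _NORMAL_WAVES
        # place the apex exactly on a sample so truth indices are exact
        _add_beat(clean, cfg.fs, idx / cfg.fs, waves)
        truth.append(BeatAnnotation(idx, cls))
    gains = np.concatenate([[1.0], rng.uniform(0.6, 1.1, size=max(cfg.n_channels - 1, 0))])
    chans = np.empty((cfg.n_channels, n))
    t = np.arange(n) / cfg.fs
    for ch in range(cfg.n_channels):
        sig = gains[ch] * clean
        if cfg.baseline_amp_mv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + cfg.baseline_amp_mv * np.sin(
                2 * np.pi * cfg.baseline_freq_hz * t + phase)
        sig = sig + generate_noise(cfg.noise_color, n, cfg.noise_level_mv,
                                   cfg.fs, rng=rng)
        chans[ch] = sig
    rec = ECGRecord(samples=chans, fs=cfg.fs,
                    lead_names=[f"CH{i + 1}" for i in range(cfg.n_channels)],
                    record_id=f"syn{cfg.seed}")
    return SyntheticRecord(record=rec, truth=sorted(truth))
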