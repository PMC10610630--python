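"""Signal conditioning for Holter ECG.

The chain applied to every record, in order and on the whole record
before any windowing:

1. zero-phase (forward-backward) Butterworth high-pass at 0.5 Hz to
   remove baseline wander;
2. zero-phase IIR notch at the mains frequency (50 or 60 Hz);
3. linear-interpolation resampling to the working rate of 125 Hz;
4. division into non-overlapping 30 s windows, the last zero-padded.

No amplitude normalization is performed anywhere: the filters are
linear, so scaling the input scales the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

TARGET_FS = 125.0
WINDOW_SECONDS = 30.0
HIGHPASS_CUTOFF_HZ = 0.5
HIGHPASS_ORDER = 2          # per pass; forward-backward doubles the effective order
NOTCH_Q = 30.0


@dataclass
class Window:
    """One fixed-length analysis window cut from a preprocessed record."""

    samples: np.ndarray
    source_record: str = ""
    start_sample: int = 0
    pad_len: int = 0

    def __post_init__(self):
        if not (0 <= self.pad_len <= len(self.samples)):
            raise ValueError("pad_len out of range")


def _check_finite(x):
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")


def highpass_baseline(signal: np.ndarray, fs: float,
                      cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
                      order: int = HIGHPASS_ORDER) -> np.ndarray:
    """Zero-phase Butterworth high-pass; removes DC and baseline wander."""
    if fs <= 1.0:
        raise ValueError("sampling rate must exceed 1 Hz")
    signal = np.asarray(signal, dtype=np.float64)
    _check_finite(signal)
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if len(signal) <= padlen:
        import warnings
        warnings.warn("signal shorter than filter warm-up; returned unfiltered")
        return signal.copy()
    return sps.sosfiltfilt(sos, signal)


def powerline_notch(signal: np.ndarray, fs: float, mains_freq: float = 50.0,
                    q: float = NOTCH_Q) -> np.ndarray:
    """Zero-phase second-order IIR notch at the mains frequency."""
    if mains_freq >= fs / 2:
        raise ValueError("mains frequency must be below Nyquist")
    signal = np.asarray(signal, dtype=np.float64)
    _check_finite(signal)
    b, a = sps.iirnotch(mains_freq, q, fs=fs)
    padlen = 3 * max(len(b), len(a))
    if len(signal) <= padlen:
        return signal.copy()
    return sps.filtfilt(b, a, signal)


def resample_linear(signal: np.ndarray, fs_in: float,
                    fs_out: float = TARGET_FS) -> np.ndarray:
    """Resample by linear interpolation on a t=0-anchored grid.

    Output sample k sits at time k / fs_out; output length is
    round(n_in * fs_out / fs_in).  Positions beyond the final input
    sample clamp to its value.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    signal = np.asarray(signal, dtype=np.float64)
    n_in = len(signal)
    if fs_in == fs_out or n_in == 0:
        return signal.copy()
    n_out = int(round(n_in * fs_out / fs_in))
    t_out = np.arange(n_out) / fs_out
    t_in = np.arange(n_in) / fs_in
    return np.interp(t_out, t_in, signal)


def resample_index(idx, fs_in: float, fs_out: float = TARGET_FS):
    """Map sample indices through :func:`resample_linear`'s time grid."""
    return np.rint(np.asarray(idx) * fs_out / fs_in).astype(int)


def window_30s(signal: np.ndarray, fs: float = TARGET_FS,
               window_seconds: float = WINDOW_SECONDS,
               source_record: str = "") -> list[Window]:
    """Cut into non-overlapping fixed windows; only the last is padded."""
    signal = np.asarray(signal, dtype=np.float64)
    wlen = int(round(window_seconds * fs))
    n = len(signal)
    if n == 0:
        return []
    out = []
    for start in range(0, n, wlen):
        chunk = signal[start:start + wlen]
        pad = wlen - len(chunk)
        if pad:
            chunk = np.pad(chunk, (0, pad))
        out.append(Window(samples=chunk, source_record=source_record,
                          start_sample=start, pad_len=pad))
    return out


def preprocess_signal(signal: np.ndarray, fs: float, mains_freq: float = 50.0,
                      target_fs: float = TARGET_FS) -> np.ndarray:
    """Full conditioning chain on one lead; returns the 125 Hz signal."""
    x = highpass_baseline(signal, fs)
    x = powerline_notch(x, fs, mains_freq)
    return resample_linear(x, fs, target_fs)
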