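"""Record, annotation and configuration I/O.

Reads and writes the PhysioBank WFDB conventions this package needs:
format-16 signal files (little-endian int16, interleaved), the plain-text
header format, and the MIT annotation format with the standard beat codes
(N = normal, V = premature ventricular contraction).  Beat lists travel
as CSV with columns record_id, time_s, sample_index, beat_class.

Only the subset of WFDB actually used by Holter beat files is supported;
anything else raises :class:`FormatError`.
"""

from __future__ import annotations

import dataclasses
import enum
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised for unreadable or inconsistent WFDB files."""


class BeatClass(enum.Enum):
    NORMAL = "NORMAL"
    PVC = "PVC"


# MIT annotation codes <-> PhysioBank symbols (beat subset + a few others
# that occur in arrhythmia databases; unknown codes round-trip by number)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 38: "f",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

SYMBOL_MAP = {"N": BeatClass.NORMAL, "V": BeatClass.PVC}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass(frozen=True, order=True)
class BeatAnnotation:
    """One beat event: 0-based sample index at the record's rate."""

    sample_index: int
    beat_class: BeatClass = field(compare=False)


@dataclass
class ECGRecord:
    """Multi-lead sample matrix in millivolts."""

    samples: np.ndarray          # (n_leads, n_samples), mV
    fs: float
    lead_names: list[str]
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("amplitudes must be finite")
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError("lead_names length must match lead count")

    @property
    def n_leads(self):
        return self.samples.shape[0]

    @property
    def n_samples(self):
        return self.samples.shape[1]

    @property
    def duration_s(self):
        return self.n_samples / self.fs


@dataclass
class RunConfig:
    """All tunables of the detection pipeline in one place."""

    target_fs: float = 125.0
    window_seconds: float = 30.0
    mains_freq: float = 50.0
    # label windows (ms)
    normal_pre_ms: float = 100.0
    normal_post_ms: float = 100.0
    pvc_pre_ms: float = 100.0
    pvc_post_ms: float = 150.0
    # post-processing
    threshold: float = 0.5
    termination_gap: int = 2
    min_run: int = 5
    merge_window_ms: float = 150.0
    flatline_window_s: float = 1.0
    flatline_floor_mv: float = 0.05
    vote_tolerance_ms: float = 150.0
    # evaluation
    match_tolerance_ms: float = 75.0
    edge_exclude_s: float = 0.2
    # training
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# WFDB records

def write_wfdb_record(record: ECGRecord, directory) -> Path:
    """Write a format-16 WFDB record (.hea + .dat); returns the header path.

    Samples are quantized at 200 adu/mV with baseline 0, the classic
    PhysioBank default gain.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gain, baseline = 200.0, 0
    name = record.record_id or "record"
    adc = np.clip(np.rint(record.samples * gain) + baseline, -32768, 32767)
    adc = adc.astype("<i2")
    dat = directory / f"{name}.dat"
    adc.T.reshape(-1).tofile(dat)
    lines = [f"{name} {record.n_leads} {_fmt_num(record.fs)} {record.n_samples}"]
    for lead in record.lead_names:
        lines.append(f"{name}.dat 16 {_fmt_num(gain)}({baseline})/mV 16 0 0 0 0 {lead}")
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def _fmt_num(x):
    return f"{x:g}"


def read_wfdb_record(path) -> ECGRecord:
    """Read a format-16 WFDB record given its .hea path (or stem)."""
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FormatError(f"missing header file {path}")
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError("malformed header record line")
    name, n_sig = head[0].split("/")[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3]) if len(head) > 3 else None
    if n_sig < 1:
        raise FormatError("record declares no signals")
    if len(lines) - 1 < n_sig:
        raise FormatError("header lists fewer signal lines than declared")
    gains, baselines, leads, fnames = [], [], [], []
    for spec in lines[1:1 + n_sig]:
        f = spec.split()
        if len(f) < 2:
            raise FormatError("malformed signal specification")
        fnames.append(f[0])
        if f[1].split("x")[0] != "16":
            raise FormatError(f"unsupported signal format {f[1]} (only 16)")
        gain, baseline = 200.0, None
        if len(f) > 2:
            gspec = f[2].split("/")[0]
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                baseline = int(bpart.rstrip(")"))
                gspec = gpart
            if gspec:
                gain = float(gspec)
        if gain == 0:
            raise FormatError("ADC gain of 0")
        adc_zero = int(f[4]) if len(f) > 4 else 0
        gains.append(gain)
        baselines.append(adc_zero if baseline is None else baseline)
        leads.append(f[8] if len(f) > 8 else f"lead{len(leads)}")
    if len(set(fnames)) != 1:
        raise FormatError("multi-file records are not supported")
    dat = path.parent / fnames[0]
    if not dat.exists():
        raise FormatError(f"missing signal file {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if n_samples is not None:
        if raw.size != n_samples * n_sig:
            raise FormatError(
                f"signal file holds {raw.size} values, header implies "
                f"{n_samples * n_sig}")
    elif raw.size % n_sig:
        raise FormatError("signal file length not a multiple of lead count")
    mat = raw.reshape(-1, n_sig).T.astype(np.float64)
    mv = (mat - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    return ECGRecord(samples=mv, fs=fs, lead_names=leads, record_id=name)


# ---------------------------------------------------------------------------
# WFDB annotations (MIT format)

def write_wfdb_annotations(beats, path, symbols=None):
    """Write beats to a MIT-format annotation file.

    ``symbols`` may override the per-beat symbol (default N/V from the
    beat class); use it to write non-beat symbols in fixtures.
    """
    beats = list(beats)
    if symbols is None:
        symbols = ["N" if b.beat_class is BeatClass.NORMAL else "V" for b in beats]
    prev = 0
    out = bytearray()
    for beat, sym in zip(beats, symbols):
        delta = beat.sample_index - prev
        if delta < 0:
            raise ValueError("beats must be sorted by sample index")
        code = _SYMBOL_TO_CODE.get(sym, 13)
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
            out += struct.pack("<H", (code << 10) | delta)
        else:
            out += struct.pack("<H", (code << 10) | delta)
        prev = beat.sample_index
    out += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(out))
    return Path(path)


def read_wfdb_annotations(path, keep_classes=("N", "V")):
    """Read a MIT-format annotation file; returns (beats, dropped_counts).

    Only symbols in ``keep_classes`` become :class:`BeatAnnotation`s
    (N -> NORMAL, V -> PVC); every other symbol is dropped and tallied in
    the returned dict.
    """
    raw = Path(path).read_bytes()
    if len(raw) % 2:
        raise FormatError("annotation file has odd byte length")
    words = struct.unpack(f"<{len(raw) // 2}H", raw)
    beats, dropped = [], {}
    t = 0
    i = 0
    pending_skip = 0
    while i < len(words):
        w = words[i]
        code, delta = w >> 10, w & 0x3FF
        if w == 0:
            break
        if code == _SKIP:
            if i + 2 >= len(words):
                raise FormatError("truncated SKIP annotation")
            pending_skip = (words[i + 1] << 16) | words[i + 2]
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            i += 1 + (delta + 1) // 2
            continue
        t += delta + pending_skip
        pending_skip = 0
        sym = _CODE_TO_SYMBOL.get(code, "Q")
        if sym in keep_classes and sym in SYMBOL_MAP:
            beats.append(BeatAnnotation(t, SYMBOL_MAP[sym]))
        else:
            dropped[sym] = dropped.get(sym, 0) + 1
        i += 1
    else:
        raise FormatError("annotation file missing end marker")
    return beats, dropped


def read_wfdb_symbols(path):
    """All (sample_index, symbol) pairs of an annotation file, unfiltered."""
    beats, _ = read_wfdb_annotations(path, keep_classes=())
    # re-read keeping everything by reconstructing from raw symbols
    raw = Path(path).read_bytes()
    words = struct.unpack(f"<{len(raw) // 2}H", raw)
    out = []
    t, i, pending = 0, 0, 0
    while i < len(words) and words[i] != 0:
        w = words[i]
        code, delta = w >> 10, w & 0x3FF
        if code == _SKIP:
            pending = (words[i + 1] << 16) | words[i + 2]
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            i += 1 + (delta + 1) // 2
            continue
        t += delta + pending
        pending = 0
        out.append((t, _CODE_TO_SYMBOL.get(code, "Q")))
        i += 1
    return out


# ---------------------------------------------------------------------------
# beat-list CSV

def write_beatlist(beats, fs: float, path, record_id: str = ""):
    """Write a sorted beat list as CSV; round-trips losslessly."""
    beats = list(beats)
    idx = [b.sample_index for b in beats]
    if any(b > a for a, b in zip(idx[1:], idx)):
        raise ValueError("beat list must be sorted by sample index")
    df = pd.DataFrame({
        "record_id": [record_id] * len(beats),
        "time_s": [round(i / fs, 6) for i in idx],
        "sample_index": idx,
        "beat_class": [b.beat_class.value for b in beats],
    })
    df.to_csv(path, index=False)
    return Path(path)


def read_beatlist(path):
    """Read a beat-list CSV back into BeatAnnotation objects."""
    df = pd.read_csv(path)
    required = {"sample_index", "beat_class"}
    if not required.issubset(df.columns):
        raise FormatError(f"beat list must have columns {sorted(required)}")
    return [BeatAnnotation(int(r.sample_index), BeatClass(r.beat_class))
            for r in df.itertuples()]
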