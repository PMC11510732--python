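"""Reading, segmenting and gain-normalising multichannel EEG.

The canonical in-memory layout is channels x samples everywhere.  Two disk
formats are supported: continuous EDF (European Data Format, 16-bit) and
delimited text with one sample per row and a header of channel names.
EDF support is implemented here directly because no EDF library is part of
the runtime environment; only the continuous (EDF, not EDF+D) flavour is
handled, which is all the pipeline needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    ConfigurationError,
    DegenerateSignalError,
    InputError,
    ParseError,
)

#: 19-electrode labels of the 10-20 placement system, in conventional order.
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Frontal channels that receive ocular (blink) artefact in the generator.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")


def _default_labels(n_channels: int) -> tuple[str, ...]:
    if n_channels == len(TEN_TWENTY_19):
        return TEN_TWENTY_19
    return tuple(f"ch{i + 1}" for i in range(n_channels))


@dataclass
class Recording:
    """A continuous multichannel recording: channels x samples plus metadata."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParseError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ParseError(
                f"recording needs >=1 channel and >=2 samples, got {self.data.shape}"
            )
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ParseError("recording contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = _default_labels(self.data.shape[0])
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ParseError("channel label count does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One fixed-length window of a recording, optionally labelled."""

    data: np.ndarray
    fs: float
    label: str = "unknown"
    subject_id: str = ""
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParseError("epoch data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ParseError("epoch contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = _default_labels(self.data.shape[0])
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """An ordered collection of epochs sharing geometry and sampling rate."""

    epochs: list[Epoch]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.epochs:
            first = self.epochs[0]
            for ep in self.epochs[1:]:
                if ep.fs != first.fs or ep.n_channels != first.n_channels:
                    raise ParseError("epochs in a set must share fs and channel count")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    def stack(self) -> np.ndarray:
        """Return epochs as one array (n_epochs, n_channels, n_samples)."""
        return np.stack([ep.data for ep in self.epochs])

    @property
    def labels(self) -> list[str]:
        return [ep.label for ep in self.epochs]

    @property
    def subject_ids(self) -> list[str]:
        return [ep.subject_id for ep in self.epochs]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt_num(x: float, width: int) -> str:
    """Render a number inside an EDF fixed-width ASCII field."""
    if float(x) == int(x) and abs(x) < 10 ** (width - 1):
        return str(int(x))
    s = f"{x:.{width}g}"
    return s[:width]


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a continuous EDF file (16-bit samples).

    Uses 1-second data records when the sampling rate is integral and the
    length divides evenly; otherwise the whole signal forms one record.
    """
    path = Path(path)
    n_ch, n_samp = rec.data.shape
    fs = rec.fs
    if fs == int(fs) and n_samp % int(fs) == 0:
        spr = int(fs)  # samples per record
        n_records = n_samp // spr
        rec_dur = 1.0
    else:
        spr = n_samp
        n_records = 1
        rec_dur = n_samp / fs

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X", 80))
        fh.write(_edf_field("synthetic", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field(_fmt_num(rec_dur, 8), 8))
        fh.write(_edf_field(str(n_ch), 4))
        for lab in rec.channel_labels:
            fh.write(_edf_field(lab, 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for v in pmin:
            fh.write(_edf_field(_fmt_num(v, 8), 8))
        for v in pmax:
            fh.write(_edf_field(_fmt_num(v, 8), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))
        for _ in range(n_ch):
            fh.write(_edf_field(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))

        scale = (pmax - pmin) / (dmax - dmin)
        digital = np.rint((rec.data - pmin[:, None]) / scale[:, None]) + dmin
        digital = np.clip(digital, dmin, dmax).astype("<i2")
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # per-signal contiguous within a record


def read_edf(path: str | Path) -> Recording:
    """Read a continuous EDF file into a Recording (physical units)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ParseError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ParseError(f"{path}: malformed EDF header") from exc
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ParseError(f"{path}: truncated EDF signal headers")

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        # byte offsets of the field groups within the signal-header block
        off = 0
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        groups = []
        for w in widths:
            groups.append((off, w))
            off += w
        labels = fields(groups[0][0], 16)
        pmin = np.array([float(v) for v in fields(groups[3][0], 8)])
        pmax = np.array([float(v) for v in fields(groups[4][0], 8)])
        dmin = np.array([float(v) for v in fields(groups[5][0], 8)])
        dmax = np.array([float(v) for v in fields(groups[6][0], 8)])
        spr = [int(v) for v in fields(groups[8][0], 8)]
        if len(set(spr)) != 1:
            raise ParseError(f"{path}: signals with differing sample rates")
        spr0 = spr[0]
        payload = fh.read()

    expected = n_records * n_ch * spr0 * 2
    if len(payload) < expected:
        raise ParseError(f"{path}: truncated EDF payload")
    raw = np.frombuffer(payload[:expected], dtype="<i2")
    raw = raw.reshape(n_records, n_ch, spr0)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]
    fs = spr0 / rec_dur
    return Recording(data=data, fs=fs, channel_labels=tuple(labels))


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def write_delimited(rec: Recording, path: str | Path, sep: str = ",") -> None:
    """Write samples-per-row delimited text with a channel-name header."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, sep=sep, index=False)


def read_delimited(path: str | Path, fs: float, sep: str | None = None) -> Recording:
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse delimited file: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        raise ParseError(f"{path}: non-numeric or missing cells in delimited file")
    return Recording(
        data=numeric.to_numpy().T,
        fs=fs,
        channel_labels=tuple(str(c) for c in df.columns),
    )


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    fs_override: float | None = None,
) -> Recording:
    """Load a recording from EDF or delimited text.

    ``fmt`` is inferred from the suffix when omitted.  Delimited input carries
    no sampling rate, so ``fs_override`` is required for it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        rec = read_edf(path)
        if fs_override is not None:
            rec = Recording(rec.data, fs_override, rec.channel_labels)
        return rec
    if fmt == "delimited":
        if fs_override is None:
            raise ConfigurationError("delimited input requires fs_override (Hz)")
        return read_delimited(path, fs=fs_override)
    raise ConfigurationError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Segmentation and gain normalisation
# ---------------------------------------------------------------------------

def segment(
    rec: Recording,
    window_s: float = 20.0,
    drop_partial: bool = True,
    label: str = "unknown",
    subject_id: str = "",
) -> EpochSet:
    """Cut a recording into consecutive non-overlapping windows.

    The default 20 s window at 250 Hz yields 5000-sample epochs.  A trailing
    partial window is dropped unless ``drop_partial`` is false.
    """
    win = int(round(window_s * rec.fs))
    if win < 2:
        raise ConfigurationError(
            f"window of {window_s} s at {rec.fs} Hz yields fewer than 2 samples"
        )
    n_full = rec.n_samples // win
    if n_full == 0 and drop_partial:
        raise InputError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{win}-sample window"
        )
    epochs = []
    for i in range(n_full):
        epochs.append(
            Epoch(
                data=rec.data[:, i * win:(i + 1) * win].copy(),
                fs=rec.fs,
                label=label,
                subject_id=subject_id,
                channel_labels=rec.channel_labels,
            )
        )
    if not drop_partial and rec.n_samples % win:
        epochs.append(
            Epoch(
                data=rec.data[:, n_full * win:].copy(),
                fs=rec.fs,
                label=label,
                subject_id=subject_id,
                channel_labels=rec.channel_labels,
            )
        )
    return EpochSet(epochs=epochs, provenance=f"segment(window_s={window_s})")


def normalize_gain(epoch: Epoch) -> Epoch:
    """Z-score each channel (mean 0, population SD 1) to remove gain/offset."""
    data = epoch.data
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)  # population convention
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        names = ", ".join(epoch.channel_labels[i] for i in flat)
        raise DegenerateSignalError(f"constant channel(s) cannot be normalised: {names}")
    return Epoch(
        data=(data - mu) / sd,
        fs=epoch.fs,
        label=epoch.label,
        subject_id=epoch.subject_id,
        channel_labels=epoch.channel_labels,
    )


class GainNormalizer(TransformerMixin, BaseEstimator):
    """Per-channel, per-epoch z-scoring transformer (stateless).

    Accepts a 2-D array (channels x samples) or a 3-D stack
    (epochs x channels x samples) and returns the same shape.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        mu = X.mean(axis=2, keepdims=True)
        sd = X.std(axis=2, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateSignalError("constant channel(s) cannot be normalised")
        out = (X - mu) / sd
        return out[0] if single else out


# ---------------------------------------------------------------------------
# Epoch-set serialisation: binary array container + JSON sidecar
# ---------------------------------------------------------------------------

def save_epochs(eset: EpochSet, path: str | Path) -> None:
    """Save an EpochSet as ``<path>.npz`` plus ``<path>.json`` metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), data=eset.stack())
    first = eset.epochs[0]
    meta = {
        "fs": first.fs,
        "channel_labels": list(first.channel_labels),
        "labels": eset.labels,
        "subject_ids": eset.subject_ids,
        "provenance": eset.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    arr = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    epochs = [
        Epoch(
            data=arr[i],
            fs=meta["fs"],
            label=meta["labels"][i],
            subject_id=meta["subject_ids"][i],
            channel_labels=tuple(meta["channel_labels"]),
        )
        for i in range(arr.shape[0])
    ]
    return EpochSet(epochs=epochs, provenance=meta.get("provenance", ""))
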