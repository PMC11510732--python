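"""Automated log-energy-based mode selection and signal reconstruction.

After the empirical wavelet decomposition, each sub-band mode is scored by
its log energy LE = ln(sum of squared samples).  Log energies are min-max
normalised to [0, 1] and modes reaching the selection threshold (default
0.10, i.e. at least 10% of the observed log-energy range above the minimum)
are summed to form the preprocessed signal.  The log compresses the dynamic
range, so weak but structured modes survive selection — the point of scoring
energy on a log scale.  The argmax mode is always kept, so the selection is
never empty.

An alternative basis, ``energy-share``, normalises raw (linear) mode
energies by their total instead; it is one flag away for users who read the
10% rule as a share of total energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidRequestError, ParameterError
from .ewt import ModeSet, ewt
from .io import Epoch

_ENERGY_FLOOR = 1e-300


@dataclass
class ModeEnergy:
    """Log energies of a mode set with the selection they induce."""

    log_energies: np.ndarray
    normalized: np.ndarray
    selected: frozenset[int]
    threshold: float
    basis: str = "minmax"
    floored: frozenset[int] = field(default_factory=frozenset)


def log_energy(mode: np.ndarray) -> float:
    """Natural log of the mode's energy (sum of squared samples).

    Energies below 1e-300 are floored before the log so an all-zero mode
    yields a finite (very negative) score instead of -inf.
    """
    mode = np.asarray(mode, dtype=float)
    energy = float(np.sum(mode ** 2))
    return float(np.log(max(energy, _ENERGY_FLOOR)))


def select_modes(
    energies,
    threshold: float = 0.10,
    basis: str = "minmax",
) -> ModeEnergy:
    """Normalise log energies and select every mode reaching the threshold.

    ``minmax`` basis: normalized_i = (LE_i - min) / (max - min); when all
    energies are equal every mode is normalised to 1 (and hence selected).
    ``energy-share`` basis: normalized_i = exp(LE_i) / sum_j exp(LE_j).
    The argmax mode is always selected.
    """
    le = np.asarray(energies, dtype=float)
    if le.size < 1:
        raise ParameterError("need at least one mode energy")
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    if basis == "minmax":
        span = le.max() - le.min()
        if span == 0:
            norm = np.ones_like(le)
        else:
            norm = (le - le.min()) / span
    elif basis == "energy-share":
        e = np.exp(le - le.max())  # stable: relative linear energies
        norm = e / e.sum()
    else:
        raise ParameterError(f"unknown basis {basis!r}")
    selected = set(np.nonzero(norm >= threshold)[0].tolist())
    selected.add(int(np.argmax(le)))
    floored = frozenset(
        int(i) for i in np.nonzero(le <= np.log(_ENERGY_FLOOR) + 1)[0]
    )
    if floored:
        warnings.warn(f"modes {sorted(floored)} had floored (near-zero) energy")
    return ModeEnergy(
        log_energies=le,
        normalized=norm,
        selected=frozenset(int(i) for i in selected),
        threshold=threshold,
        basis=basis,
        floored=floored,
    )


def reconstruct(modes: ModeSet, selected) -> np.ndarray:
    """Sum the selected modes into a single preprocessed signal."""
    selected = sorted(set(int(i) for i in selected))
    if not selected:
        raise InvalidRequestError("cannot reconstruct from an empty mode selection")
    if selected[0] < 0 or selected[-1] >= modes.n_modes:
        raise InvalidRequestError(
            f"mode indices {selected} out of range for {modes.n_modes} modes"
        )
    return modes.modes[selected].sum(axis=0)


@dataclass
class ChannelSelectionReport:
    """What was kept for one channel: boundaries, energies, selection."""

    channel: str
    n_modes: int
    boundaries_hz: list[float]
    log_energies: list[float]
    normalized: list[float]
    selected: list[int]


def aleewr_channel(
    x: np.ndarray,
    fs: float,
    n_peaks: int = 5,
    gamma: float | str = "auto",
    smooth_width: int = 5,
    threshold: float = 0.10,
    basis: str = "minmax",
    channel_name: str = "",
) -> tuple[np.ndarray, ChannelSelectionReport]:
    """Run the full decompose / score / select / sum chain on one channel.

    An all-zero channel short-circuits to an all-zero output with a warning;
    every other degenerate condition propagates from the stage that hit it.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        warnings.warn(f"channel {channel_name or '?'} is all zero; passed through")
        report = ChannelSelectionReport(
            channel=channel_name, n_modes=0, boundaries_hz=[],
            log_energies=[], normalized=[], selected=[],
        )
        return np.zeros_like(x), report
    mset = ewt(x, fs, n_peaks=n_peaks, gamma=gamma, smooth_width=smooth_width)
    le = np.array([log_energy(m) for m in mset.modes])
    me = select_modes(le, threshold=threshold, basis=basis)
    out = reconstruct(mset, me.selected)
    report = ChannelSelectionReport(
        channel=channel_name,
        n_modes=mset.n_modes,
        boundaries_hz=[float(b) for b in mset.boundaries.phis],
        log_energies=[float(v) for v in le],
        normalized=[float(v) for v in me.normalized],
        selected=sorted(me.selected),
    )
    return out, report


def aleewr_process(
    epoch: Epoch,
    n_peaks: int = 5,
    gamma: float | str = "auto",
    smooth_width: int = 5,
    threshold: float = 0.10,
    basis: str = "minmax",
) -> tuple[Epoch, list[ChannelSelectionReport]]:
    """Apply the log-energy empirical wavelet reconstruction channel-wise.

    Expects a gain-normalised epoch; returns an epoch of identical shape plus
    one selection report per channel.
    """
    out = np.empty_like(epoch.data)
    reports = []
    for c in range(epoch.n_channels):
        out[c], rep = aleewr_channel(
            epoch.data[c], epoch.fs,
            n_peaks=n_peaks, gamma=gamma, smooth_width=smooth_width,
            threshold=threshold, basis=basis,
            channel_name=epoch.channel_labels[c],
        )
        reports.append(rep)
    processed = Epoch(
        data=out, fs=epoch.fs, label=epoch.label,
        subject_id=epoch.subject_id, channel_labels=epoch.channel_labels,
    )
    return processed, reports


class Aleewr(TransformerMixin, BaseEstimator):
    """Stateless transformer running the log-energy wavelet reconstruction.

    Operates on 2-D (channels x samples) or 3-D (epochs x channels x samples)
    arrays at sampling rate ``fs``; shape is preserved.
    """

    def __init__(
        self,
        fs: float = 250.0,
        n_peaks: int = 5,
        gamma: float | str = "auto",
        smooth_width: int = 5,
        threshold: float = 0.10,
        basis: str = "minmax",
    ):
        self.fs = fs
        self.n_peaks = n_peaks
        self.gamma = gamma
        self.smooth_width = smooth_width
        self.threshold = threshold
        self.basis = basis

    def fit(self, X, y=None):
        return self

    def _one(self, slab: np.ndarray) -> np.ndarray:
        ep = Epoch(data=slab, fs=self.fs)
        processed, _ = aleewr_process(
            ep, n_peaks=self.n_peaks, gamma=self.gamma,
            smooth_width=self.smooth_width, threshold=self.threshold,
            basis=self.basis,
        )
        return processed.data

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return self._one(X)
        return np.stack([self._one(x) for x in X])
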