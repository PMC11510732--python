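"""Empirical Wavelet Transform: data-driven spectral segmentation.

The transform partitions the Fourier spectrum of a signal at boundaries
placed midway between dominant spectral maxima, builds a Meyer-type filter
bank (one low-pass scaling filter plus band-pass wavelets with smooth
polynomial transitions), and extracts one band-limited time-domain mode per
segment.  The squared filter responses form a partition of unity, so the sum
of all modes reconstructs the input exactly.

Conventions
-----------
* Boundaries and peak frequencies are in Hz on (0, Nyquist).
* The transition half-width of a boundary phi is gamma * phi; a single
  parameter gamma governs every transition and must satisfy the strict
  no-overlap bound  gamma < min_i (phi_{i+1} - phi_i) / (phi_{i+1} + phi_i).
* Modes are produced by multiplying the spectrum with the *squared* response,
  so that plain summation of modes is exact reconstruction.  This is the
  self-adjoint (analysis followed by synthesis) application of the bank and
  is what the downstream log-energy reconstruction assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateSignalError, ParameterError, ShapeError


@dataclass
class SpectrumPeaks:
    """Selected local maxima of a magnitude spectrum, in frequency order."""

    freqs: np.ndarray  # Hz, strictly increasing, inside (0, fs/2)
    mags: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.mags = np.asarray(self.mags, dtype=float)
        if self.m < 1 or len(self.freqs) != self.m:
            raise ParameterError("peak set must contain m >= 1 frequencies")
        if np.any(np.diff(self.freqs) <= 0):
            raise ParameterError("peak frequencies must be strictly increasing")


@dataclass
class BoundarySet:
    """Segment boundaries (Hz), each the midpoint of two adjacent maxima."""

    phis: np.ndarray

    def __post_init__(self) -> None:
        self.phis = np.asarray(self.phis, dtype=float)
        if self.phis.size and np.any(np.diff(self.phis) <= 0):
            raise ParameterError("boundaries must be strictly increasing")

    def __len__(self) -> int:
        return self.phis.size


@dataclass
class EWTFilterBank:
    """Sampled Meyer-type filter bank on a one-sided frequency grid."""

    scaling: np.ndarray          # rho_1, the low-pass response
    wavelets: list[np.ndarray]   # Psi_i, band-pass responses, low -> high
    gamma: float
    grid: np.ndarray             # one-sided frequency grid (Hz), len n_fft//2+1
    n_fft: int
    fs: float
    phis: np.ndarray = None      # boundary frequencies the bank was built from

    @property
    def responses(self) -> list[np.ndarray]:
        return [self.scaling, *self.wavelets]

    @property
    def n_modes(self) -> int:
        return 1 + len(self.wavelets)

    def partition_error(self) -> float:
        """Max deviation of sum of squared responses from 1 over the grid."""
        total = sum(r ** 2 for r in self.responses)
        return float(np.max(np.abs(total - 1.0)))


@dataclass
class ModeSet:
    """Time-domain sub-band modes of one signal, low to high frequency."""

    modes: np.ndarray  # (n_modes, n_samples)
    boundaries: BoundarySet
    bank: EWTFilterBank

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


# ---------------------------------------------------------------------------
# Step 1: spectral maxima
# ---------------------------------------------------------------------------

def _smooth(mag: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return mag
    kernel = np.ones(width) / width
    return np.convolve(mag, kernel, mode="same")


def detect_spectral_maxima(
    signal: np.ndarray,
    fs: float,
    n_peaks: int,
    smooth_width: int = 5,
    min_mag_rel: float = 1e-8,
) -> SpectrumPeaks:
    """Locate the ``n_peaks`` largest local maxima of the magnitude spectrum.

    The spectrum is the one-sided FFT magnitude, optionally smoothed by a
    short moving average (``smooth_width`` bins; 1 disables smoothing) to
    suppress noise-induced micro-maxima.  DC and Nyquist are excluded.  Ties
    in magnitude keep the lower frequency.  If fewer maxima exist than
    requested, all are returned and a warning is emitted; a spectrum with no
    interior maximum falls back to its largest interior bin.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 4:
        raise ShapeError("signal must have at least 4 samples")
    if n_peaks < 1:
        raise ParameterError("n_peaks must be >= 1")
    if not np.any(signal):
        raise DegenerateSignalError("all-zero signal has no spectral maxima")

    mag = np.abs(np.fft.rfft(signal))
    mag = _smooth(mag, smooth_width)
    freqs = np.fft.rfftfreq(signal.size, d=1.0 / fs)

    interior = slice(1, mag.size - 1)  # exclude DC and Nyquist bins
    idx, _ = find_peaks(mag[interior])
    idx = idx + 1
    # drop numerical-noise-floor maxima (spectral leakage residue)
    idx = idx[mag[idx] >= min_mag_rel * mag.max()]
    if idx.size == 0:
        warnings.warn("no interior local maximum; using the largest interior bin")
        idx = np.array([1 + int(np.argmax(mag[interior]))])
    if idx.size < n_peaks:
        warnings.warn(
            f"only {idx.size} spectral maxima available, {n_peaks} requested"
        )
    # largest magnitudes first; ties keep the lower frequency (stable sort)
    order = np.argsort(-mag[idx], kind="stable")
    keep = np.sort(idx[order[:n_peaks]])
    return SpectrumPeaks(freqs=freqs[keep], mags=mag[keep], m=keep.size)


# ---------------------------------------------------------------------------
# Step 2: boundaries
# ---------------------------------------------------------------------------

def compute_boundaries(peaks: SpectrumPeaks) -> BoundarySet:
    """Midpoints between consecutive maxima; empty when only one peak."""
    if peaks.m == 1:
        return BoundarySet(phis=np.empty(0))
    phis = 0.5 * (peaks.freqs[:-1] + peaks.freqs[1:])
    return BoundarySet(phis=phis)


# ---------------------------------------------------------------------------
# Step 3: Meyer-type filter bank
# ---------------------------------------------------------------------------

def meyer_beta(x: np.ndarray) -> np.ndarray:
    """Meyer transition polynomial x^4 (35 - 84x + 70x^2 - 20x^3), clipped.

    Satisfies beta(x) = 0 for x <= 0, 1 for x >= 1 and
    beta(x) + beta(1 - x) = 1 on (0, 1).
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)


def gamma_bound(boundaries: BoundarySet, fs: float) -> float:
    """Strict upper bound on gamma: no two transition bands may overlap.

    Takes the minimum of (phi_{i+1}-phi_i)/(phi_{i+1}+phi_i) over consecutive
    boundaries together with the Nyquist headroom term
    (fs/2 - phi_last)/(fs/2 + phi_last), which keeps the last transition on
    the sampled grid.
    """
    phis = boundaries.phis
    if phis.size == 0:
        return 1.0
    nyq = fs / 2.0
    terms = [(nyq - phis[-1]) / (nyq + phis[-1])]
    if phis.size > 1:
        terms.append(float(np.min((phis[1:] - phis[:-1]) / (phis[1:] + phis[:-1]))))
    return min(min(terms), 1.0)


def build_filter_bank(
    boundaries: BoundarySet,
    n_fft: int,
    fs: float,
    gamma: float | str = "auto",
) -> EWTFilterBank:
    """Construct the sampled scaling + wavelet responses on the rfft grid.

    ``gamma='auto'`` uses 0.9 x the strict bound.  The last wavelet's upper
    transition is replaced by a flat response of 1 up to Nyquist.  The squared
    responses sum to 1 at every grid point (partition of unity).
    """
    grid = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    phis = boundaries.phis

    if phis.size == 0:
        return EWTFilterBank(
            scaling=np.ones_like(grid), wavelets=[], gamma=0.0,
            grid=grid, n_fft=n_fft, fs=fs, phis=phis.copy(),
        )

    bound = gamma_bound(boundaries, fs)
    if gamma == "auto":
        g = 0.9 * bound
    else:
        g = float(gamma)
        if not 0.0 < g < bound:
            raise ParameterError(
                f"gamma={g} violates the strict no-overlap bound {bound:.6g}"
            )

    def up(phi: float) -> np.ndarray:
        """0 below (1-g)phi, sin(pi/2 beta) across the transition, 1 above."""
        x = (np.abs(grid) - (1.0 - g) * phi) / (2.0 * g * phi)
        return np.sin(0.5 * np.pi * meyer_beta(x))

    def down(phi: float) -> np.ndarray:
        x = (np.abs(grid) - (1.0 - g) * phi) / (2.0 * g * phi)
        return np.cos(0.5 * np.pi * meyer_beta(x))

    scaling = down(phis[0])
    wavelets = []
    for i in range(phis.size - 1):
        wavelets.append(up(phis[i]) * down(phis[i + 1]))
    wavelets.append(up(phis[-1]))  # flat to Nyquist

    return EWTFilterBank(
        scaling=scaling, wavelets=wavelets, gamma=g,
        grid=grid, n_fft=n_fft, fs=fs, phis=phis.copy(),
    )


# ---------------------------------------------------------------------------
# Step 4: sub-band extraction
# ---------------------------------------------------------------------------

def decompose(signal: np.ndarray, bank: EWTFilterBank) -> ModeSet:
    """Split a signal into band-limited modes using the bank.

    Each mode is irfft(rfft(signal) * response^2); squaring makes the
    analysis-synthesis pair self-adjoint so that the plain sum of the modes
    equals the input (see module docstring).  Responses are real and applied
    conjugate-symmetrically, hence modes are real.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size != bank.n_fft:
        raise ShapeError(
            f"signal length {signal.size} does not match bank n_fft {bank.n_fft}"
        )
    spectrum = np.fft.rfft(signal)
    modes = np.stack([
        np.fft.irfft(spectrum * r ** 2, n=bank.n_fft) for r in bank.responses
    ])
    phis = bank.phis if bank.phis is not None else np.empty(0)
    return ModeSet(modes=modes, boundaries=BoundarySet(phis=phis), bank=bank)


def ewt(
    signal: np.ndarray,
    fs: float,
    n_peaks: int = 5,
    gamma: float | str = "auto",
    smooth_width: int = 5,
) -> ModeSet:
    """Full empirical wavelet decomposition of one signal."""
    peaks = detect_spectral_maxima(signal, fs, n_peaks, smooth_width=smooth_width)
    boundaries = compute_boundaries(peaks)
    bank = build_filter_bank(boundaries, n_fft=len(signal), fs=fs, gamma=gamma)
    return decompose(signal, bank)
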