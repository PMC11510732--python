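"""Real cepstrum and cepstral Hjorth descriptors.

The real cepstrum of a signal x is the inverse Fourier transform of the log
magnitude of its spectrum; its independent variable is quefrency.  Periodic
spectral structure (harmonic envelopes, resonances) shows up as localised
cepstral peaks, which makes the cepstrum a compact summary of the spectral
*shape* independent of overall gain (gain only shifts quefrency 0).

Three Hjorth-style descriptors are computed on the cepstral sequence c:

* activity      A = Var(c)                 (population variance)
* mobility      M = sqrt(Var(dc) / Var(c)) with dc the first difference
* complexity    C = M(dc) / M(c)

For a pure sinusoidal c the complexity is 1 — the Hjorth reference case.
The printed definition of mobility sometimes omits the radical; the square
root is the standard convention and is the default here (``sqrt_mobility``
switches to the literal ratio-of-variances reading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateSignalError, ShapeError
from .io import Epoch, _default_labels


@dataclass
class Cepstrum:
    """Real cepstral coefficients of one signal."""

    coeffs: np.ndarray
    eps_floor: float

    def __len__(self) -> int:
        return self.coeffs.size


@dataclass
class CepstralFeatures:
    activity: float
    mobility: float
    complexity: float


def real_cepstrum(signal: np.ndarray, eps_rel: float = 1e-12) -> Cepstrum:
    """c = Re(ifft(log(max(|fft(x)|, eps)))).

    The magnitude floor is ``eps_rel`` times the peak spectral magnitude, so
    spectral nulls cannot drive the log to -inf; the floor is relative
    because the inputs are z-scored and an absolute floor would not scale.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 4:
        raise ShapeError("cepstrum needs at least 4 samples")
    if not np.any(signal):
        raise DegenerateSignalError("all-zero signal has no cepstrum")
    spectrum = np.abs(np.fft.fft(signal))
    floor = eps_rel * spectrum.max()
    c = np.fft.ifft(np.log(np.maximum(spectrum, floor)))
    return Cepstrum(coeffs=np.real(c), eps_floor=floor)


def _variance(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.mean((x - x.mean()) ** 2))


def cepstral_activity(c: Cepstrum | np.ndarray) -> float:
    """Population variance of the cepstral coefficients."""
    coeffs = c.coeffs if isinstance(c, Cepstrum) else np.asarray(c, dtype=float)
    if coeffs.size < 2:
        raise ShapeError("activity needs at least 2 coefficients")
    return _variance(coeffs)


def cepstral_mobility(c: Cepstrum | np.ndarray, sqrt_mobility: bool = True) -> float:
    """sqrt of the variance ratio of the differenced cepstrum to the cepstrum.

    The first difference uses unit spacing; any constant quefrency step
    cancels in the ratio.  ``sqrt_mobility=False`` gives the plain ratio.
    """
    coeffs = c.coeffs if isinstance(c, Cepstrum) else np.asarray(c, dtype=float)
    if coeffs.size < 3:
        raise ShapeError("mobility needs at least 3 coefficients")
    a = _variance(coeffs)
    if a == 0:
        raise DegenerateSignalError("constant cepstrum: mobility undefined")
    ratio = _variance(np.diff(coeffs)) / a
    return float(np.sqrt(ratio)) if sqrt_mobility else float(ratio)


def cepstral_complexity(c: Cepstrum | np.ndarray, sqrt_mobility: bool = True) -> float:
    """Mobility of the differenced cepstrum divided by mobility of the cepstrum."""
    coeffs = c.coeffs if isinstance(c, Cepstrum) else np.asarray(c, dtype=float)
    if coeffs.size < 4:
        raise ShapeError("complexity needs at least 4 coefficients")
    m = cepstral_mobility(coeffs, sqrt_mobility=sqrt_mobility)
    if m == 0:
        raise DegenerateSignalError("zero mobility: complexity undefined")
    md = cepstral_mobility(np.diff(coeffs), sqrt_mobility=sqrt_mobility)
    return md / m


def cepstral_features(
    signal: np.ndarray, sqrt_mobility: bool = True, eps_rel: float = 1e-12
) -> CepstralFeatures:
    c = real_cepstrum(signal, eps_rel=eps_rel)
    return CepstralFeatures(
        activity=cepstral_activity(c),
        mobility=cepstral_mobility(c, sqrt_mobility=sqrt_mobility),
        complexity=cepstral_complexity(c, sqrt_mobility=sqrt_mobility),
    )


@dataclass
class FeatureVector:
    """Per-epoch feature vector: (A, M, C) per channel, channel-major."""

    values: np.ndarray
    names: tuple[str, ...]
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ShapeError("feature values and names differ in length")


def feature_names(channel_labels) -> tuple[str, ...]:
    """A<ch>, M<ch>, C<ch> per channel (e.g. APz, MPz, CPz)."""
    names = []
    for ch in channel_labels:
        names.extend((f"A{ch}", f"M{ch}", f"C{ch}"))
    return tuple(names)


def extract_features(
    epoch: Epoch, sqrt_mobility: bool = True, eps_rel: float = 1e-12
) -> FeatureVector:
    """Cepstral activity/mobility/complexity for every channel of an epoch.

    A 19-channel epoch yields the 57-element vector (3 features x 19
    channels); the layout generalises to any channel count.
    """
    values = np.empty(3 * epoch.n_channels)
    for ci in range(epoch.n_channels):
        try:
            f = cepstral_features(
                epoch.data[ci], sqrt_mobility=sqrt_mobility, eps_rel=eps_rel
            )
        except (DegenerateSignalError, ShapeError) as exc:
            raise DegenerateSignalError(
                f"channel {epoch.channel_labels[ci]}: {exc}"
            ) from exc
        values[3 * ci:3 * ci + 3] = (f.activity, f.mobility, f.complexity)
    return FeatureVector(
        values=values,
        names=feature_names(epoch.channel_labels),
        label=epoch.label,
        subject_id=epoch.subject_id,
    )


class CepstralHjorth(TransformerMixin, BaseEstimator):
    """Transformer: epoch stack -> feature matrix.

    Input is (n_epochs, n_channels, n_samples); output is
    (n_epochs, 3 * n_channels) with columns ordered channel-major (A, M, C).
    """

    def __init__(
        self,
        sqrt_mobility: bool = True,
        eps_rel: float = 1e-12,
        channel_labels: tuple[str, ...] | None = None,
    ):
        self.sqrt_mobility = sqrt_mobility
        self.eps_rel = eps_rel
        self.channel_labels = channel_labels

    def fit(self, X, y=None):
        X = np.asarray(X)
        n_channels = X.shape[-2]
        labels = self.channel_labels or _default_labels(n_channels)
        self.feature_names_ = feature_names(labels)
        self.n_features_out_ = 3 * n_channels
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ShapeError("expected (n_epochs, n_channels, n_samples)")
        n_epochs, n_channels, _ = X.shape
        out = np.empty((n_epochs, 3 * n_channels))
        for e in range(n_epochs):
            for ci in range(n_channels):
                f = cepstral_features(
                    X[e, ci], sqrt_mobility=self.sqrt_mobility, eps_rel=self.eps_rel
                )
                out[e, 3 * ci:3 * ci + 3] = (f.activity, f.mobility, f.complexity)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
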