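"""FastICA decomposition, artefact-component flagging and reconstruction.

EEG channels are modelled as linear mixtures ``y = A z`` of statistically
independent sources ``z``; FastICA estimates the unmixing matrix ``W``
(``z = W y``) by maximising non-Gaussianity with the log-cosh contrast and
symmetric decorrelation.  Ocular and muscle artefacts concentrate in a few
sources with heavy-tailed amplitude distributions, so components whose excess
kurtosis is a robust outlier across sources are flagged and zeroed before the
signal is re-mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import DegenerateSignalError, InputError, InvalidRequestError
from .io import Epoch, Recording


@dataclass
class ICAModel:
    """A fitted FastICA decomposition of one epoch or recording.

    ``unmixing`` maps centred observations to sources (k x n_channels);
    ``mixing`` maps sources back to observations.  ``rotation`` is the
    square unmixing matrix expressed in whitened coordinates, whose rows are
    orthonormal by construction of the symmetric fixed-point update.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    whitener: np.ndarray
    rotation: np.ndarray
    mean: np.ndarray
    seed: int
    converged: bool
    n_iter: int
    fs: float
    channel_labels: tuple[str, ...]
    original_label: str = "unknown"
    original_subject: str = ""
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def fit_fastica(
    epoch: Epoch | Recording,
    n_components: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    fit_stride: int = 1,
) -> ICAModel:
    """Fit symmetric log-cosh FastICA to a channels x samples signal.

    Deterministic for a fixed ``seed``.  Sources come out with unit variance.
    If the fixed-point iteration does not reach ``tol`` within ``max_iter``,
    the model is still returned with ``converged=False`` and a warning record.

    ``fit_stride > 1`` estimates the unmixing matrix on every ``fit_stride``-th
    sample (mixing statistics of long recordings are stable under decimation)
    and then applies it to the full signal; sources are then unit-variance on
    the strided fit set rather than exactly on the full signal.
    """
    data = epoch.data
    n_channels = data.shape[0]
    if n_components is None:
        n_components = n_channels
    if n_components > n_channels:
        raise InputError(
            f"n_components={n_components} exceeds channel count {n_channels}"
        )
    if not np.all(np.isfinite(data)):
        raise InputError("epoch contains non-finite values")
    rank_view = data[:, :: max(fit_stride, 1)]
    # rank check before whitening: FastICA silently misbehaves on rank-deficient data
    if np.linalg.matrix_rank(
        rank_view - rank_view.mean(axis=1, keepdims=True)
    ) < n_components:
        raise DegenerateSignalError(
            "data rank is below the requested number of components; whitening fails"
        )

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    fit_data = data[:, ::fit_stride] if fit_stride > 1 else data
    records: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        # sklearn wants samples x features
        sources = ica.fit_transform(fit_data.T).T
    if fit_stride > 1:
        sources = ica.transform(data.T).T
    converged = True
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            records.append(str(w.message))

    # sklearn rescales the fixed-point rotation rows by 1/std(source) to give
    # unit-variance sources; the rows of the underlying rotation had unit norm,
    # so row-normalising recovers the orthonormal matrix exactly.
    raw = ica._unmixing
    rotation = raw / np.linalg.norm(raw, axis=1, keepdims=True)

    label = getattr(epoch, "label", "unknown")
    subject = getattr(epoch, "subject_id", "")
    return ICAModel(
        unmixing=ica.components_,
        mixing=ica.mixing_,
        sources=sources,
        whitener=ica.whitening_,
        rotation=rotation,
        mean=ica.mean_,
        seed=seed,
        converged=converged,
        n_iter=ica.n_iter_,
        fs=epoch.fs,
        channel_labels=tuple(epoch.channel_labels),
        original_label=label,
        original_subject=subject,
        warnings_=records,
    )


def _excess_kurtosis(sources: np.ndarray) -> np.ndarray:
    return stats.kurtosis(sources, axis=1, fisher=True, bias=True)


def flag_artifact_components(model: ICAModel, kurtosis_z: float = 3.0) -> set[int]:
    """Flag sources whose excess kurtosis is a robust outlier.

    The robust z-score is (kurtosis - median) / (1.4826 * MAD).  Components
    scoring above ``kurtosis_z`` are flagged; the set may be empty and is
    never allowed to cover every component.
    """
    if model.n_components < 2:
        raise InputError("artifact flagging needs at least 2 components")
    kurt = _excess_kurtosis(model.sources)
    med = np.median(kurt)
    mad = np.median(np.abs(kurt - med))
    if mad == 0:
        # fall back to SD scale so identical-kurtosis banks yield no flags
        scale = kurt.std() or 1.0
    else:
        scale = 1.4826 * mad
    z = (kurt - med) / scale
    flagged = {int(i) for i in np.nonzero(z > kurtosis_z)[0]}
    if len(flagged) == model.n_components:
        # keep the least extreme component
        keep = int(np.argmin(z))
        flagged.discard(keep)
    return flagged


def component_report(model: ICAModel, flagged: set[int]) -> list[dict]:
    """Per-component kurtosis/flag summary for the sidecar report."""
    kurt = _excess_kurtosis(model.sources)
    return [
        {"component": i, "excess_kurtosis": float(kurt[i]), "flagged": i in flagged}
        for i in range(model.n_components)
    ]


def remove_components(model: ICAModel, drop: set[int] | frozenset[int]) -> Epoch:
    """Re-mix the sources with the dropped components zeroed.

    Channel means removed during whitening are restored, so with an empty
    ``drop`` the reconstruction equals the input (full-rank case).
    """
    drop = set(drop)
    if drop and not drop.issubset(range(model.n_components)):
        raise InvalidRequestError(f"component indices out of range: {drop}")
    if len(drop) >= model.n_components:
        raise InvalidRequestError("cannot drop every component")
    sources = model.sources.copy()
    if drop:
        sources[sorted(drop), :] = 0.0
    data = model.mixing @ sources + model.mean[:, None]
    return Epoch(
        data=data,
        fs=model.fs,
        label=model.original_label,
        subject_id=model.original_subject,
        channel_labels=model.channel_labels,
    )


def clean(
    signal: Epoch | Recording,
    kurtosis_z: float = 3.0,
    seed: int = 0,
    n_components: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    fit_stride: int = 1,
) -> tuple[Epoch, ICAModel, set[int]]:
    """Fit, flag and reconstruct in one call; returns (cleaned, model, flagged)."""
    model = fit_fastica(
        signal, n_components=n_components, seed=seed, tol=tol,
        max_iter=max_iter, fit_stride=fit_stride,
    )
    flagged = flag_artifact_components(model, kurtosis_z=kurtosis_z)
    return remove_components(model, flagged), model, flagged


class IcaArtifactRemover(TransformerMixin, BaseEstimator):
    """Stateless transformer: FastICA cleanup of channels x samples signals.

    Accepts 2-D (channels x samples) or 3-D (epochs x channels x samples)
    arrays; each 2-D slab is decomposed, kurtosis-flagged and re-mixed
    independently.  ``enabled=False`` turns the stage into the identity.
    """

    def __init__(
        self,
        kurtosis_z: float = 3.0,
        seed: int = 0,
        n_components: int | None = None,
        tol: float = 1e-6,
        max_iter: int = 500,
        fit_stride: int = 1,
        enabled: bool = True,
    ):
        self.kurtosis_z = kurtosis_z
        self.seed = seed
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.fit_stride = fit_stride
        self.enabled = enabled

    def fit(self, X, y=None):
        return self

    def _clean_one(self, slab: np.ndarray, fs: float) -> np.ndarray:
        ep = Epoch(data=slab, fs=fs)
        cleaned, _, _ = clean(
            ep,
            kurtosis_z=self.kurtosis_z,
            seed=self.seed,
            n_components=self.n_components,
            tol=self.tol,
            max_iter=self.max_iter,
            fit_stride=self.fit_stride,
        )
        return cleaned.data

    def transform(self, X, fs: float = 250.0):
        X = np.asarray(X, dtype=float)
        if not self.enabled:
            return X
        if X.ndim == 2:
            return self._clean_one(X, fs)
        return np.stack([self._clean_one(x, fs) for x in X])
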