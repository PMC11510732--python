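"""Seeded two-class synthetic EEG generator with ground truth.

The generator emulates the geometry of a resting-state clinical recording
set: 19 channels of the 10-20 system at 250 Hz, 14 subjects per class, and
enough duration per subject for 36 twenty-second epochs (504 epochs per
class after segmentation).

Each channel is the sum of three parts:

* a class-dependent resonant process — a second-order autoregressive
  oscillation with pole frequency 10 Hz for the healthy class versus
  ``10 + 2 * class_effect`` Hz with a broader bandwidth plus a harmonic
  ripple (a second resonance at twice the pole frequency) for the
  schizophrenia class, so the spectral envelopes and hence the cepstral
  descriptors differ by construction;
* 1/f^slope background noise (the characteristic EEG spectral tilt);
* blink artefacts: smooth ~0.4 s bumps at a Poisson rate, one shared blink
  train per recording projected onto the frontal channels with a fixed
  topography — exactly the structure an ICA cleanup can find and remove.

Per-channel random gains in [0.5, 2] exercise the gain normalisation.
Ground truth (blink train, blink times, topography, gains, class
parameters) is returned alongside every recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ParameterError
from .io import FRONTAL_CHANNELS, TEN_TWENTY_19, Recording, segment

#: Fixed blink projection weights onto the frontal channels.
BLINK_TOPOGRAPHY = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.6, "F3": 0.7, "Fz": 0.6, "F4": 0.7, "F8": 0.6,
}

#: Relative amplitudes of the generative parts (AR part is unit variance).
NOISE_SD = 0.5
BLINK_AMPLITUDE = 5.0
HARMONIC_GAIN = 0.4


@dataclass
class SynthConfig:
    """Stated world of the generator; defaults mirror the clinical geometry."""

    n_subjects_per_class: int = 14
    epochs_per_subject: int = 36
    fs: float = 250.0
    n_channels: int = 19
    window_s: float = 20.0
    class_effect: float = 1.0
    artifact_rate: float = 4.0      # blinks per minute
    noise_slope: float = 1.0        # 1/f exponent
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_class, self.epochs_per_subject,
               self.n_channels) < 1:
            raise ParameterError("all counts must be >= 1")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.class_effect < 0:
            raise ParameterError("class_effect must be >= 0")
        if self.artifact_rate < 0:
            raise ParameterError("artifact_rate must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.epochs_per_subject * self.window_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels == len(TEN_TWENTY_19):
            return TEN_TWENTY_19
        return tuple(f"ch{i + 1}" for i in range(self.n_channels))


@dataclass
class RecordingTruth:
    """Ground truth retained for one generated recording."""

    label: str
    subject_id: str
    blink_times_s: np.ndarray
    blink_train: np.ndarray
    blink_topography: np.ndarray       # per-channel projection weights
    channel_gains: np.ndarray
    ar_part: np.ndarray                # channels x samples, pre-gain
    pole_hz: float
    pole_radius: float


@dataclass
class SynthDataset:
    recordings: list[Recording]
    truths: list[RecordingTruth]
    config: SynthConfig = None

    def __len__(self) -> int:
        return len(self.recordings)


def _ar2_coeffs(pole_hz: float, radius: float, fs: float) -> np.ndarray:
    """Denominator of a 2nd-order resonator with poles at r e^{+-i 2 pi f/fs}."""
    theta = 2.0 * np.pi * pole_hz / fs
    return np.array([1.0, -2.0 * radius * np.cos(theta), radius ** 2])


def _ar2_series(rng: np.random.Generator, n: int, pole_hz: float,
                radius: float, fs: float) -> np.ndarray:
    burn = 500
    x = lfilter([1.0], _ar2_coeffs(pole_hz, radius, fs),
                rng.standard_normal(n + burn))[burn:]
    return x / x.std()


def _pink_noise(
    rng: np.random.Generator, n: int, slope: float,
    fs: float = 250.0, highpass_hz: float = 0.5,
) -> np.ndarray:
    """1/f^slope noise via spectral shaping of white noise.

    Shaped noise is high-passed at ``highpass_hz`` (the usual EEG acquisition
    high-pass).  Without it the realised variance is dominated by a handful
    of near-DC Fourier modes, so normalising by the total SD would make the
    in-band noise level a per-realisation random quantity — i.e. every
    recording would carry an identifiable noise signature.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    band = f >= highpass_hz
    shaping[band] = f[band] ** (-slope / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd else x


def _blink_bump(fs: float, width_s: float = 0.4) -> np.ndarray:
    """A smooth non-negative bump (Hann squared) of ~width_s seconds."""
    n = max(int(round(width_s * fs)), 4)
    return np.hanning(n) ** 2


def _blink_train(rng: np.random.Generator, n: int, fs: float,
                 rate_per_min: float) -> tuple[np.ndarray, np.ndarray]:
    train = np.zeros(n)
    duration_min = n / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    bump = _blink_bump(fs)
    starts = np.sort(rng.integers(0, max(n - bump.size, 1), size=n_events))
    for s in starts:
        seg = train[s:s + bump.size]
        seg += bump[: seg.size] * (0.8 + 0.4 * rng.random())
    return train, starts / fs


def class_parameters(label: str, class_effect: float) -> dict:
    """Generative spectral parameters for one class.

    Every class difference scales with ``class_effect`` so that at 0 the two
    classes are exchangeable: the schizophrenia resonance shifts up by
    2 * class_effect Hz, broadens (smaller pole radius) and acquires a
    harmonic ripple in the spectral envelope.
    """
    if label == "healthy" or class_effect == 0:
        return {"pole_hz": 10.0, "pole_radius": 0.98, "harmonic_gain": 0.0}
    return {
        "pole_hz": 10.0 + 2.0 * class_effect,
        "pole_radius": max(0.98 - 0.015 * class_effect, 0.90),
        "harmonic_gain": HARMONIC_GAIN * min(class_effect, 1.0),
    }


def generate_recording(
    cfg: SynthConfig, class_label: str, subject_seed: int,
    subject_id: str = "",
) -> tuple[Recording, RecordingTruth]:
    """Generate one subject's recording plus its ground truth."""
    rng = np.random.default_rng(subject_seed)
    n = cfg.n_samples
    labels = cfg.channel_labels()
    params = class_parameters(class_label, cfg.class_effect)

    ar = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        x = _ar2_series(rng, n, params["pole_hz"], params["pole_radius"], cfg.fs)
        if params["harmonic_gain"]:
            x = x + params["harmonic_gain"] * _ar2_series(
                rng, n, 2.0 * params["pole_hz"], params["pole_radius"], cfg.fs
            )
        ar[c] = x

    noise = np.stack([
        NOISE_SD * _pink_noise(rng, n, cfg.noise_slope, fs=cfg.fs)
        for _ in range(cfg.n_channels)
    ])

    blink_train, blink_times = _blink_train(rng, n, cfg.fs, cfg.artifact_rate)
    topo = np.array([
        BLINK_TOPOGRAPHY.get(lab, 0.0) if lab in FRONTAL_CHANNELS else 0.0
        for lab in labels
    ])
    gains = rng.uniform(0.5, 2.0, size=cfg.n_channels)

    data = gains[:, None] * (
        ar + noise + BLINK_AMPLITUDE * topo[:, None] * blink_train[None, :]
    )
    rec = Recording(data=data, fs=cfg.fs, channel_labels=labels)
    truth = RecordingTruth(
        label=class_label,
        subject_id=subject_id or f"{class_label}-{subject_seed}",
        blink_times_s=blink_times,
        blink_train=blink_train,
        blink_topography=topo,
        channel_gains=gains,
        ar_part=ar,
        pole_hz=params["pole_hz"],
        pole_radius=params["pole_radius"],
    )
    return rec, truth


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Balanced two-class dataset: one recording per subject, seeded.

    Subject seeds derive from ``cfg.seed`` via a SeedSequence spawn, so the
    dataset is reproducible as a whole and each subject independently.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.n_subjects_per_class)
    recordings, truths = [], []
    i = 0
    for label in ("healthy", "schizophrenia"):
        for s in range(cfg.n_subjects_per_class):
            seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            rec, truth = generate_recording(
                cfg, label, seed, subject_id=f"{label[:2]}{s + 1:02d}"
            )
            recordings.append(rec)
            truths.append(truth)
            i += 1
    return SynthDataset(recordings=recordings, truths=truths, config=cfg)


def segment_dataset(ds: SynthDataset, window_s: float | None = None):
    """Segment every recording; returns a list of labelled Epochs."""
    window = window_s if window_s is not None else ds.config.window_s
    epochs = []
    for rec, truth in zip(ds.recordings, ds.truths):
        eset = segment(rec, window_s=window, label=truth.label,
                       subject_id=truth.subject_id)
        epochs.extend(eset.epochs)
    return epochs
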