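"""Empirical wavelet transform: maxima, boundaries, filter bank, modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aleewr.errors import DegenerateSignalError, ParameterError, ShapeError
from aleewr.ewt import (
    BoundarySet,
    SpectrumPeaks,
    build_filter_bank,
    compute_boundaries,
    decompose,
    detect_spectral_maxima,
    ewt,
    gamma_bound,
    meyer_beta,
)
from conftest import ar2


def band_energy_fraction(signal, fs, lo, hi):
    """Oracle: share of spectral energy inside [lo, hi] Hz."""
    spec = np.abs(np.fft.rfft(signal)) ** 2
    freqs = np.fft.rfftfreq(len(signal), d=1.0 / fs)
    total = spec.sum()
    mask = (freqs >= lo) & (freqs <= hi)
    return spec[mask].sum() / total


class TestDetectSpectralMaxima:
    def test_two_tone_peaks(self, two_tone):
        signal, fs = two_tone
        peaks = detect_spectral_maxima(signal, fs, n_peaks=2)
        bin_hz = fs / len(signal)
        assert peaks.m == 2
        assert abs(peaks.freqs[0] - 5.0) <= bin_hz + 1e-9
        assert abs(peaks.freqs[1] - 40.0) <= bin_hz + 1e-9

    def test_clipping_with_warning(self, two_tone):
        signal, fs = two_tone
        with pytest.warns(UserWarning, match="maxima"):
            peaks = detect_spectral_maxima(signal, fs, n_peaks=200)
        assert peaks.m <= 200

    def test_matches_exhaustive_scan(self, rng):
        """Brute-force oracle: enumerate every interior local maximum of the
        smoothed magnitude spectrum, keep the top 3 by magnitude."""
        x = ar2(rng, 2048, 30.0, 0.9, 250.0)
        fs = 250.0
        width = 5
        mag = np.abs(np.fft.rfft(x))
        kernel = np.ones(width) / width
        sm = np.convolve(mag, kernel, mode="same")
        locals_ = [
            i for i in range(1, sm.size - 1)
            if sm[i] > sm[i - 1] and sm[i] > sm[i + 1]
        ]
        expected = sorted(sorted(locals_, key=lambda i: -sm[i])[:3])
        freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)

        peaks = detect_spectral_maxima(x, fs, n_peaks=3, smooth_width=width)
        np.testing.assert_allclose(peaks.freqs, freqs[expected])

    def test_all_zero_signal(self):
        with pytest.raises(DegenerateSignalError):
            detect_spectral_maxima(np.zeros(100), 250.0, n_peaks=1)


class TestComputeBoundaries:
    @pytest.mark.parametrize("freqs,expected", [
        ([10.0, 20.0], [15.0]),
        ([5.0, 40.0, 60.0], [22.5, 50.0]),
        ([12.0], []),
    ])
    def test_midpoints(self, freqs, expected):
        peaks = SpectrumPeaks(freqs=np.array(freqs),
                              mags=np.ones(len(freqs)), m=len(freqs))
        bset = compute_boundaries(peaks)
        np.testing.assert_allclose(bset.phis, expected)

    def test_count_is_peaks_minus_one(self, rng):
        for m in range(1, 9):
            freqs = np.sort(rng.uniform(1, 120, size=m))
            while np.any(np.diff(freqs) <= 0):
                freqs = np.sort(rng.uniform(1, 120, size=m))
            peaks = SpectrumPeaks(freqs=freqs, mags=np.ones(m), m=m)
            assert len(compute_boundaries(peaks)) == m - 1


class TestMeyerBeta:
    def test_endpoint_and_symmetry_constraints(self):
        x = np.linspace(0.0, 1.0, 101)
        np.testing.assert_allclose(meyer_beta(x) + meyer_beta(1 - x), 1.0,
                                   atol=1e-12)
        assert meyer_beta(np.array([-1.0]))[0] == 0.0
        assert meyer_beta(np.array([2.0]))[0] == 1.0


class TestBuildFilterBank:
    def test_partition_of_unity_single_boundary(self):
        bank = build_filter_bank(BoundarySet(phis=np.array([15.0])),
                                 n_fft=5000, fs=250.0)
        assert bank.partition_error() < 1e-10

    def test_gamma_above_bound_rejected(self):
        bset = BoundarySet(phis=np.array([22.5, 50.0]))
        bad = 2.0 * gamma_bound(bset, fs=250.0)
        with pytest.raises(ParameterError):
            build_filter_bank(bset, n_fft=5000, fs=250.0, gamma=bad)

    def test_auto_gamma_endpoint_values(self):
        bank = build_filter_bank(BoundarySet(phis=np.array([22.5, 50.0])),
                                 n_fft=5000, fs=250.0, gamma="auto")
        assert bank.scaling[0] == pytest.approx(1.0)
        assert bank.wavelets[-1][-1] == pytest.approx(1.0)
        for resp in bank.responses:
            assert np.all(resp >= 0.0) and np.all(resp <= 1.0 + 1e-12)

    def test_empty_boundaries_all_pass(self):
        bank = build_filter_bank(BoundarySet(phis=np.empty(0)),
                                 n_fft=512, fs=250.0)
        np.testing.assert_array_equal(bank.scaling, 1.0)
        assert bank.wavelets == []

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_partition_of_unity_random_boundaries(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 7)
        phis = np.sort(rng.uniform(2.0, 110.0, size=m))
        phis = phis[np.concatenate(([True], np.diff(phis) > 1.0))]
        bank = build_filter_bank(BoundarySet(phis=phis), n_fft=1024, fs=250.0)
        assert bank.partition_error() < 1e-10


class TestDecompose:
    def test_zero_signal_zero_modes(self):
        bank = build_filter_bank(BoundarySet(phis=np.array([15.0])),
                                 n_fft=512, fs=250.0)
        mset = decompose(np.zeros(512), bank)
        np.testing.assert_array_equal(mset.modes, 0.0)

    def test_two_tone_band_separation(self, two_tone):
        signal, fs = two_tone
        bank = build_filter_bank(BoundarySet(phis=np.array([15.0])),
                                 n_fft=len(signal), fs=fs)
        mset = decompose(signal, bank)
        assert band_energy_fraction(mset.modes[0], fs, 0.0, 15.0) >= 0.99
        assert band_energy_fraction(mset.modes[1], fs, 15.0, 125.0) >= 0.99

    def test_length_mismatch(self, two_tone):
        signal, fs = two_tone
        bank = build_filter_bank(BoundarySet(phis=np.array([15.0])),
                                 n_fft=100, fs=fs)
        with pytest.raises(ShapeError):
            decompose(signal, bank)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_perfect_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(1024)
        mset = ewt(x, fs=250.0, n_peaks=int(rng.integers(1, 7)))
        rel = np.linalg.norm(mset.modes.sum(axis=0) - x) / np.linalg.norm(x)
        assert rel < 1e-6

    def test_linearity(self, rng):
        x = rng.standard_normal(512)
        y = rng.standard_normal(512)
        bank = build_filter_bank(BoundarySet(phis=np.array([20.0, 60.0])),
                                 n_fft=512, fs=250.0)
        a, b = 2.5, -1.25
        lhs = decompose(a * x + b * y, bank).modes
        rhs = a * decompose(x, bank).modes + b * decompose(y, bank).modes
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)
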