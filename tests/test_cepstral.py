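"""Real cepstrum and cepstral Hjorth descriptors."""

import numpy as np
import pytest

from aleewr.cepstral import (
    cepstral_activity,
    cepstral_complexity,
    cepstral_mobility,
    extract_features,
    real_cepstrum,
)
from aleewr.errors import DegenerateSignalError
from aleewr.io import TEN_TWENTY_19, Epoch


def naive_real_cepstrum(x):
    """O(N^2) oracle: explicit DFT sums, log magnitude, explicit inverse DFT."""
    n = len(x)
    spectrum = np.empty(n, dtype=complex)
    for k in range(n):
        spectrum[k] = sum(
            x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)
        )
    logmag = np.log(np.maximum(np.abs(spectrum), 1e-12 * np.abs(spectrum).max()))
    c = np.empty(n, dtype=complex)
    for t in range(n):
        c[t] = sum(
            logmag[k] * np.exp(2j * np.pi * k * t / n) for k in range(n)
        ) / n
    return np.real(c)


class TestRealCepstrum:
    def test_unit_impulse_has_flat_spectrum(self):
        c = real_cepstrum(np.array([1.0, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(c.coeffs, 0.0, atol=1e-12)

    @pytest.mark.parametrize("signal", [
        np.array([1.0, 0.5, 0.0, 0.0]),
        None,  # random case filled in below
    ])
    def test_matches_naive_dft_oracle(self, signal, rng):
        if signal is None:
            signal = rng.standard_normal(64)
        c = real_cepstrum(signal)
        np.testing.assert_allclose(c.coeffs, naive_real_cepstrum(signal),
                                   atol=1e-10)

    def test_gain_moves_only_quefrency_zero(self, rng):
        x = rng.standard_normal(256)
        a = 3.5
        c1 = real_cepstrum(x).coeffs
        c2 = real_cepstrum(a * x).coeffs
        assert c2[0] - c1[0] == pytest.approx(np.log(a), abs=1e-9)
        np.testing.assert_allclose(c2[1:], c1[1:], atol=1e-9)

    def test_circular_shift_invariance(self, rng):
        x = rng.standard_normal(512)
        c1 = real_cepstrum(x).coeffs
        c2 = real_cepstrum(np.roll(x, 123)).coeffs
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSignalError):
            real_cepstrum(np.zeros(16))


class TestActivity:
    def test_constant_sequence_is_zero(self):
        assert cepstral_activity(np.full(10, 2.5)) == 0.0

    def test_alternating_unit_sequence(self):
        assert cepstral_activity(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0

    def test_matches_two_pass_loop(self, rng):
        c = rng.standard_normal(5000)
        mean = sum(c) / len(c)           # brute-force two-pass oracle
        var = sum((v - mean) ** 2 for v in c) / len(c)
        assert cepstral_activity(c) == pytest.approx(var, rel=1e-12)

    def test_quadratic_scaling(self, rng):
        c = rng.standard_normal(100)
        assert cepstral_activity(3.0 * c) == pytest.approx(
            9.0 * cepstral_activity(c), rel=1e-10)


class TestMobility:
    def test_linear_ramp_is_zero(self):
        assert cepstral_mobility(np.array([0.0, 1.0, 2.0, 3.0, 4.0])) == 0.0

    def test_scale_invariance(self, rng):
        c = rng.standard_normal(200)
        assert cepstral_mobility(-7.0 * c) == pytest.approx(
            cepstral_mobility(c), abs=1e-9)

    def test_matches_variance_ratio_oracle(self):
        c = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        dc = np.diff(c)
        expected = np.sqrt(np.var(dc) / np.var(c))
        assert cepstral_mobility(c) == pytest.approx(expected, rel=1e-12)

    def test_no_sqrt_reading(self, rng):
        c = rng.standard_normal(100)
        assert cepstral_mobility(c, sqrt_mobility=False) == pytest.approx(
            cepstral_mobility(c) ** 2, rel=1e-10)

    def test_constant_sequence_rejected(self):
        with pytest.raises(DegenerateSignalError):
            cepstral_mobility(np.full(10, 1.0))


class TestComplexity:
    def test_scale_invariance(self, rng):
        c = rng.standard_normal(300)
        assert cepstral_complexity(2.5 * c) == pytest.approx(
            cepstral_complexity(c), abs=1e-9)

    def test_sinusoid_reference_case(self):
        # Hjorth reference: a pure sinusoid over whole periods has complexity 1
        n = 1000
        c = np.sin(2 * np.pi * 7 * np.arange(n) / n)
        assert cepstral_complexity(c) == pytest.approx(1.0, rel=0.05)

    def test_white_noise_vs_random_walk_ordering(self, rng):
        """Direct-evaluation ordering oracle: a random walk is smooth but its
        derivative is rough, so its complexity (mobility ratio) far exceeds
        white noise's, while its mobility is far lower."""
        white = rng.standard_normal(2000)
        walk = np.cumsum(rng.standard_normal(2000))
        assert cepstral_complexity(walk) > cepstral_complexity(white)
        assert cepstral_mobility(white) > cepstral_mobility(walk)


class TestExtractFeatures:
    def test_19_channels_give_57_named_features(self, noise_epoch):
        fv = extract_features(noise_epoch)
        assert len(fv.values) == 57
        assert np.all(np.isfinite(fv.values))
        expected = []
        for ch in TEN_TWENTY_19:
            expected += [f"A{ch}", f"M{ch}", f"C{ch}"]
        assert list(fv.names) == expected
        assert "APz" in fv.names and "MPz" in fv.names and "CPz" in fv.names

    def test_generalises_to_2_channels(self, rng):
        ep = Epoch(data=rng.standard_normal((2, 512)), fs=250.0,
                   channel_labels=("X", "Y"))
        fv = extract_features(ep)
        assert len(fv.values) == 6
        assert list(fv.names) == ["AX", "MX", "CX", "AY", "MY", "CY"]

    def test_duplicated_channel_duplicates_features(self, rng):
        x = rng.standard_normal(512)
        ep = Epoch(data=np.vstack([x, x]), fs=250.0)
        fv = extract_features(ep)
        np.testing.assert_array_equal(fv.values[:3], fv.values[3:])

    def test_degenerate_channel_error_names_it(self, rng):
        data = rng.standard_normal((2, 512))
        data[1] = 0.0
        ep = Epoch(data=data, fs=250.0, channel_labels=("Ok", "Bad"))
        with pytest.raises(DegenerateSignalError, match="Bad"):
            extract_features(ep)

    def test_gain_invariance_end_to_end(self, rng):
        """Input gain moves only quefrency 0 of the cepstrum, which still
        enters the Hjorth variances at O(ln^2 a / N); with gain
        normalisation applied upstream (as the pipeline does) all three
        features are exactly gain- and offset-invariant."""
        from aleewr.io import normalize_gain

        x = rng.standard_normal((1, 1024))
        a, b = 40.0, 3.0
        f1 = extract_features(normalize_gain(Epoch(data=x, fs=250.0))).values
        f2 = extract_features(
            normalize_gain(Epoch(data=a * x + b, fs=250.0))).values
        np.testing.assert_allclose(f2, f1, atol=1e-9)
        # without normalisation the invariance is approximate, not exact
        g1 = extract_features(Epoch(data=x, fs=250.0)).values
        g2 = extract_features(Epoch(data=a * x, fs=250.0)).values
        np.testing.assert_allclose(g2[1:], g1[1:], rtol=0.05)
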