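"""Statistical and spectral feature contracts against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdkin.errors import InvalidArgumentError, ValidationError
from pdkin.features import (FEATURE_NAMES, central_frequency,
                            dominant_frequency, extract_window_features,
                            feature_names, freezing_index, power_spectrum,
                            statistical_features, wavelet_mean)
from pdkin.mocap import AXES, CANONICAL_MARKERS, Window

RATE = 120.0


def tone(freq, seconds=4.0, rate=RATE, amp=1.0, phase=0.0):
    t = np.arange(int(seconds * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


# ---------------------------------------------------------------------------
# db4 DWT oracle: straight-line convolution + downsampling, independent of
# PyWavelets. Filter taps are the published Daubechies-4 constants.
# ---------------------------------------------------------------------------
DB4_DEC_LO = np.array([
    -0.0105974017850690, 0.0328830116668852, 0.0308413818355608,
    -0.1870348117190931, -0.0279837694168599, 0.6308807679298589,
    0.7148465705529157, 0.2303778133088965])
DB4_DEC_HI = np.array([
    -0.2303778133088965, 0.7148465705529157, -0.6308807679298589,
    -0.0279837694168599, 0.1870348117190931, 0.0308413818355608,
    -0.0328830116668852, -0.0105974017850690])


def dwt_oracle(x, levels=4):
    """Pooled |detail| mean via explicit symmetric-padded convolution."""
    details = []
    a = np.asarray(x, dtype=float)
    L = len(DB4_DEC_LO)
    for _ in range(levels):
        ext = np.concatenate([a[:L - 1][::-1], a, a[-(L - 1):][::-1]])
        d = np.convolve(ext, DB4_DEC_HI, mode="valid")[1::2]
        a = np.convolve(ext, DB4_DEC_LO, mode="valid")[1::2]
        details.append(np.abs(d))
    return float(np.concatenate(details).mean())


class TestStatisticalFeatures:
    def test_hand_arithmetic(self):
        assert statistical_features(np.array([1.0, 2, 3, 4])) == (2.5, 1, 4, 1.25)

    def test_constant_signal(self):
        assert statistical_features(np.full(10, 7.0)) == (7.0, 7.0, 7.0, 0.0)

    def test_negation_symmetry(self):
        x = np.array([0.5, -1.0, 2.0, 3.5])
        m, lo, hi, v = statistical_features(x)
        m2, lo2, hi2, v2 = statistical_features(-x)
        assert (m2, lo2, hi2) == (-m, -hi, -lo)
        assert v2 == v

    def test_empty_signal_raises(self):
        with pytest.raises(InvalidArgumentError):
            statistical_features(np.array([]))


class TestPowerSpectrum:
    def test_pure_tone_peak_location(self):
        f, p = power_spectrum(tone(2.0), RATE)
        assert f[np.argmax(p)] == pytest.approx(2.0, abs=0.25)
        assert f[0] > 0 and f[-1] == pytest.approx(RATE / 2)

    def test_constant_signal_zero_power(self):
        f, p = power_spectrum(np.full(480, 3.0), RATE)
        assert p.sum() == pytest.approx(0.0, abs=1e-20)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2**14)
        f, p = power_spectrum(x, RATE)
        df = f[1] - f[0]
        assert p.sum() * df == pytest.approx(x.var(), rel=0.05)

    def test_too_short_raises(self):
        with pytest.raises(InvalidArgumentError):
            power_spectrum(np.ones(4), RATE)


class TestFreezingIndex:
    def test_freeze_band_tone_dominates(self):
        assert freezing_index(tone(5.0), RATE) > 10

    def test_locomotor_tone_small(self):
        assert freezing_index(tone(1.0), RATE) < 0.1

    def test_white_noise_bandwidth_ratio(self):
        # flat spectrum: fi -> (8-3)/(3-0.5) = 2
        rng = np.random.default_rng(5)
        x = rng.normal(size=2**15)
        assert freezing_index(x, RATE) == pytest.approx(2.0, rel=0.2)

    def test_amplitude_invariance(self):
        x = tone(4.0) + 0.3 * tone(1.2, phase=1.0)
        assert freezing_index(7.5 * x, RATE) == pytest.approx(
            freezing_index(x, RATE), rel=1e-9)

    def test_invalid_bands_raise(self):
        with pytest.raises(InvalidArgumentError):
            freezing_index(tone(5.0), RATE, freeze_band=(8.0, 3.0))
        with pytest.raises(InvalidArgumentError):
            freezing_index(tone(5.0), RATE, freeze_band=(2.0, 8.0),
                           locomotor_band=(0.5, 3.0))


class TestCentralFrequency:
    def test_pure_tone(self):
        assert central_frequency(tone(2.0), RATE) == pytest.approx(2.0, abs=0.25)

    def test_centroid_of_equal_tones(self):
        x = tone(2.0) + tone(6.0, phase=0.7)
        assert central_frequency(x, RATE) == pytest.approx(4.0, abs=0.25)

    def test_constant_signal_returns_zero(self):
        assert central_frequency(np.full(480, 1.0), RATE) == 0.0


class TestDominantFrequency:
    def test_dominant_tone_wins(self):
        x = tone(2.5) + 0.1 * tone(7.0)
        assert dominant_frequency(x, RATE) == pytest.approx(2.5, abs=0.25)

    def test_high_band_tone(self):
        assert dominant_frequency(tone(7.0), RATE) == pytest.approx(7.0, abs=0.25)

    def test_equal_tones_pick_one_peak_deterministically(self):
        # equal-amplitude tones: the result is one of the two peaks and is
        # independent of summation order (ties break to the lower bin)
        a = dominant_frequency(tone(2.0) + tone(6.0), RATE)
        b = dominant_frequency(tone(6.0) + tone(2.0), RATE)
        assert a == b
        assert min(abs(a - 2.0), abs(a - 6.0)) < 0.25


class TestWaveletMean:
    def test_constant_signal_zero(self):
        assert wavelet_mean(np.full(480, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=480)
        assert wavelet_mean(2 * x) == pytest.approx(2 * wavelet_mean(x),
                                                    rel=1e-12)

    def test_matches_convolution_oracle(self):
        rng = np.random.default_rng(11)
        for n in (64, 480, 481):
            x = rng.normal(size=n)
            assert wavelet_mean(x) == pytest.approx(dwt_oracle(x), rel=1e-10)

    def test_too_short_raises(self):
        with pytest.raises(InvalidArgumentError):
            wavelet_mean(np.ones(8))


def _window(data):
    return Window(data=data, start_time=0.0, window_index=0,
                  sampling_rate=RATE, marker_names=list(CANONICAL_MARKERS))


class TestExtractWindowFeatures:
    def test_shape_names_and_order(self):
        rng = np.random.default_rng(1)
        fv = extract_window_features(_window(rng.normal(size=(480, 11, 3))))
        assert len(fv.values) == 264
        assert len(set(fv.names)) == 264
        # marker-major, then axis, then feature
        i = fv.names.index("fi-L.Thigh_Z")
        mi = list(CANONICAL_MARKERS).index("L.Thigh")
        assert i == (mi * 3 + AXES.index("Z")) * len(FEATURE_NAMES) + \
            FEATURE_NAMES.index("fi")

    def test_all_zero_window_is_all_zero(self):
        fv = extract_window_features(_window(np.zeros((480, 11, 3))))
        np.testing.assert_allclose(fv.values, 0.0)

    def test_matches_per_channel_functions(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(480, 11, 3))
        fv = extract_window_features(_window(data))
        s = fv.to_series()
        x = data[:, list(CANONICAL_MARKERS).index("R.Shank"), 2]
        assert s["fi-R.Shank_Z"] == pytest.approx(freezing_index(x, RATE))
        assert s["cenfreq-R.Shank_Z"] == pytest.approx(
            central_frequency(x, RATE))
        assert s["domfreq-R.Shank_Z"] == pytest.approx(
            dominant_frequency(x, RATE))
        assert s["wav-R.Shank_Z"] == pytest.approx(wavelet_mean(x))
        assert s["variance-R.Shank_Z"] == pytest.approx(x.var())

    def test_time_reversal_leaves_features_unchanged(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(480, 11, 3))
        a = extract_window_features(_window(data)).values
        b = extract_window_features(_window(data[::-1].copy())).values
        names = feature_names()
        keep = [i for i, n in enumerate(names) if not n.startswith("wav-")]
        np.testing.assert_allclose(a[keep], b[keep], rtol=1e-8, atol=1e-10)

    def test_missing_marker_named_in_error(self):
        w = Window(data=np.zeros((480, 10, 3)), start_time=0.0,
                   window_index=0, sampling_rate=RATE,
                   marker_names=[m for m in CANONICAL_MARKERS
                                 if m != "L.Shank"])
        with pytest.raises(ValidationError, match="L.Shank"):
            extract_window_features(w)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.6, 10.0))
def test_spectral_scale_invariance_property(seed, freq):
    """fi is amplitude-invariant; wav scales linearly; domfreq unchanged."""
    rng = np.random.default_rng(seed)
    x = tone(freq, phase=rng.uniform(0, 6.28)) + 0.05 * rng.normal(size=480)
    a = rng.uniform(0.1, 50.0)
    assert freezing_index(a * x, RATE) == pytest.approx(
        freezing_index(x, RATE), rel=1e-9)
    assert dominant_frequency(a * x, RATE) == dominant_frequency(x, RATE)
    assert wavelet_mean(a * x) == pytest.approx(a * wavelet_mean(x), rel=1e-9)
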