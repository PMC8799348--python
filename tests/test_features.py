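"""The 14 per-channel features against brute-force oracles and hand values."""

import math
import warnings

import numpy as np
import pytest

from emgcaps import (
    FEATURE_NAMES,
    SpectralConfig,
    build_feature_vector,
    evaluate_feature,
    power_spectrum,
)

CFG = SpectralConfig(fs=1000.0)


# -- independent brute-force evaluations of every feature formula -----------

def oracle(name, s, cfg=CFG):
    s = list(map(float, s))
    w = len(s)
    if name == "RMS":
        return math.sqrt(sum(x * x for x in s) / w)
    if name == "MAV":
        return sum(abs(x) for x in s) / w
    if name == "WL":
        return sum(abs(s[i + 1] - s[i]) for i in range(w - 1))
    if name == "ZC":
        return sum(
            1
            for i in range(w - 1)
            if s[i] * s[i + 1] < 0 and abs(s[i] - s[i + 1]) >= cfg.zc_threshold
        )
    if name == "DASDV":
        return math.sqrt(sum((s[i + 1] - s[i]) ** 2 for i in range(w - 1)) / (w - 1))
    if name == "LOG":
        return math.exp(sum(s) / w)
    if name == "SSI":
        return sum(x * x for x in s)
    if name in ("TM3", "TM4", "TM5"):
        p = int(name[2])
        return abs(sum(x**p for x in s) / w)
    if name == "IEMG":
        return sum(abs(x) for x in s)
    # spectral features from the one-sided |FFT|^2
    power = np.abs(np.fft.rfft(s)) ** 2
    freqs = np.fft.rfftfreq(w, d=1.0 / cfg.fs)
    if name == "FR":
        low = sum(p for f, p in zip(freqs, power) if cfg.fr_low_band[0] <= f < cfg.fr_low_band[1])
        high = sum(p for f, p in zip(freqs, power) if cfg.fr_high_band[0] <= f < cfg.fr_high_band[1])
        return low / high
    if name == "MFMN":
        return sum(f * p for f, p in zip(freqs, power)) / sum(power)
    if name == "MFMD":
        half = sum(power) / 2.0
        acc = 0.0
        for f, p in zip(freqs, power):
            acc += p
            if acc >= half:
                return f
    raise KeyError(name)


class TestAgainstOracles:
    def test_all_features_on_random_signals(self, rng):
        for _ in range(100):
            s = rng.standard_normal(rng.integers(10, 301))
            for name in FEATURE_NAMES:
                got = evaluate_feature(name, s, CFG)
                want = oracle(name, s)
                assert got == pytest.approx(want, rel=1e-9), name


class TestHandComputedValues:
    @pytest.mark.parametrize(
        "name,signal,expected",
        [
            ("MAV", [1, -1, 1, -1], 1.0),
            ("RMS", [3, 4], math.sqrt(25 / 2)),
            ("WL", [0, 1, 0, 1], 3.0),
            ("SSI", [1, 2], 5.0),
            ("IEMG", [1, -2, 3], 6.0),
            ("ZC", [1, -1, 1], 2.0),
        ],
    )
    def test_toy_values(self, name, signal, expected):
        assert evaluate_feature(name, signal, CFG) == pytest.approx(expected)

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            evaluate_feature("NOPE", [1, 2, 3], CFG)


class TestPowerSpectrum:
    def test_sinusoid_concentrates_at_its_frequency(self):
        t = np.arange(300) / 1000.0
        s = np.sin(2 * np.pi * 100.0 * t)
        ps = power_spectrum(s, CFG)
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(100.0, abs=ps.freqs[1])

    def test_zero_signal_zero_power(self):
        ps = power_spectrum(np.zeros(300), CFG)
        assert np.all(ps.power == 0)

    def test_parseval(self, rng):
        s = rng.standard_normal(300)
        two_sided = np.abs(np.fft.fft(s)) ** 2
        assert two_sided.sum() / s.size == pytest.approx(np.sum(s**2), rel=1e-12)
        # the one-sided spectrum holds the matching bins
        ps = power_spectrum(s, CFG)
        np.testing.assert_allclose(ps.power, two_sided[: ps.power.size], rtol=1e-9)

    def test_mfmn_mfmd_of_pure_tone(self):
        t = np.arange(300) / 1000.0
        s = np.sin(2 * np.pi * 100.0 * t)
        # 100 Hz sits exactly on the 300-sample grid (bin 30)
        assert evaluate_feature("MFMN", s, CFG) == pytest.approx(100.0, abs=0.5)
        assert evaluate_feature("MFMD", s, CFG) == pytest.approx(100.0, abs=0.5)

    def test_mfmd_splits_cumulative_power(self, rng):
        s = rng.standard_normal(300)
        ps = power_spectrum(s, CFG)
        md = evaluate_feature("MFMD", s, CFG)
        below = ps.power[ps.freqs < md].sum()
        at_or_below = ps.power[ps.freqs <= md].sum()
        assert below <= ps.total / 2.0 <= at_or_below


class TestFeatureVector:
    def test_length_and_leading_one(self, rng):
        fv = build_feature_vector(rng.standard_normal(300), CFG)
        assert fv.values.shape == (15,)
        assert fv.values[0] == 1.0
        assert fv.m == 14

    def test_zero_signal_pattern(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fv = build_feature_vector(np.zeros(300), CFG)
        # [1, RMS..TM5, FR, IEMG, MFMN, MFMD]; LOG = exp(0) = 1, FR undefined
        expected = [1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, np.nan, 0, 0, 0]
        for got, want in zip(fv.values, expected):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_fr_warns_on_zero_high_band(self):
        with pytest.warns(RuntimeWarning, match="FR undefined"):
            out = evaluate_feature("FR", np.zeros(300), CFG)
        assert np.isnan(out)

    def test_scaling_homogeneity(self, rng):
        s = rng.standard_normal(300)
        c = 3.7
        linear = ("RMS", "MAV", "WL", "DASDV", "IEMG")
        invariant = ("ZC", "MFMN", "MFMD", "FR")
        for name in linear:
            assert evaluate_feature(name, c * s, CFG) == pytest.approx(
                c * evaluate_feature(name, s, CFG), rel=1e-9
            )
        for name in invariant:
            assert evaluate_feature(name, c * s, CFG) == pytest.approx(
                evaluate_feature(name, s, CFG), rel=1e-9
            )

    def test_nonnegative_features(self, rng):
        s = rng.standard_normal(300)
        for name in ("RMS", "MAV", "WL", "DASDV", "SSI", "IEMG", "TM4"):
            assert evaluate_feature(name, s, CFG) >= 0

    def test_log_conventional_variant(self, rng):
        s = rng.standard_normal(50)
        got = evaluate_feature("LOG", s, CFG, log_variant="conventional")
        assert got == pytest.approx(np.exp(np.mean(np.log(np.abs(s)))), rel=1e-12)
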