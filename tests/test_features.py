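"""Unit and property tests for the 23 EHG window parameters."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehgpred import features as ft

from .oracles import fuzzyen_brute, lz76_parse, sampen_brute

FS = 20.0


def _sine(freq, duration=120.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# PSD


class TestPSD:
    def test_pure_tone_dominant_bin(self):
        psd = ft.estimate_psd(_sine(0.5), FS)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(0.5, abs=1 / 120)
        # resolution matches the window length
        assert np.diff(psd.freqs)[0] == pytest.approx(1 / 120)

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(2400)
        psd = ft.estimate_psd(x, FS)
        df = psd.freqs[1] - psd.freqs[0]
        # integrated density equals the tapered time-domain power
        from scipy.signal import get_window

        w = get_window("hamming", 2400)
        xc = x - x.mean()
        tapered_power = np.sum((xc * w) ** 2) / np.sum(w**2)
        assert psd.power.sum() * df == pytest.approx(tapered_power, rel=0.01)
        assert np.ptp(psd.power[(psd.freqs > 1) & (psd.freqs < 9)]) < 30 * np.median(
            psd.power
        )  # approximately flat spectrum

    def test_two_equal_tones_equal_peaks(self):
        x = _sine(0.25) + _sine(0.6)
        psd = ft.estimate_psd(x, FS)
        p1 = psd.power[np.argmin(np.abs(psd.freqs - 0.25))]
        p2 = psd.power[np.argmin(np.abs(psd.freqs - 0.6))]
        assert p1 == pytest.approx(p2, rel=0.05)

    def test_constant_window_zero_psd(self):
        psd = ft.estimate_psd(np.ones(2400), FS)
        assert np.all(psd.power == 0)


# ---------------------------------------------------------------------------
# spectral features


class TestSpectralFeatures:
    def test_pure_tone_degenerate_spectrum(self):
        psd = ft.estimate_psd(_sine(0.5), FS)
        f = ft.spectral_features(psd)
        assert f["df1"] == pytest.approx(0.5, abs=1 / 120)
        assert f["df2"] == pytest.approx(0.5, abs=1 / 120)
        for k in range(1, 10):
            assert f[f"d{k}"] == pytest.approx(0.5, abs=2 / 120)

    def test_equal_power_tones_hl_ratio_one(self):
        # equal-power tones on either side of the 0.34 Hz band split
        psd = ft.estimate_psd(_sine(0.25) + _sine(0.6), FS)
        f = ft.spectral_features(psd)
        assert f["hl_ratio"] == pytest.approx(1.0, rel=0.05)

    def test_flat_psd_deciles_evenly_spaced(self):
        freqs = np.arange(0.0, 4.0, 1 / 1200)  # fine grid for a sharp answer
        power = np.where((freqs >= 0.2) & (freqs <= 1.0), 1.0, 0.0)
        f = ft.spectral_features(ft.PSD(freqs=freqs, power=power))
        assert f["d5"] == pytest.approx(0.6, abs=0.005)
        deciles = [f[f"d{k}"] for k in range(1, 10)]
        assert np.allclose(np.diff(deciles), 0.08, atol=0.005)

    def test_zero_low_band_gives_nan_hl(self):
        freqs = np.arange(0.0, 4.0, 1 / 120)
        power = np.where(freqs >= 0.5, 1.0, 0.0)
        f = ft.spectral_features(ft.PSD(freqs=freqs, power=power))
        assert math.isnan(f["hl_ratio"])


# ---------------------------------------------------------------------------
# temporal / nonlinear features


class TestPeakToPeak:
    def test_constant_and_sine(self):
        assert ft.peak_to_peak(np.full(100, 3.7)) == 0.0
        assert ft.peak_to_peak(_sine(0.5)) == pytest.approx(2.0, rel=1e-3)

    def test_matches_scan_oracle(self, rng):
        x = rng.standard_normal(500)
        assert ft.peak_to_peak(x) == max(x) - min(x)


class TestLempelZiv:
    def test_constant_sequence_minimal_value(self):
        x = np.zeros(2400)
        # a single-symbol sequence parses into exactly 2 phrases
        assert ft.lempel_ziv(x, 2) == pytest.approx(2 * math.log2(2400) / 2400)

    def test_alternating_binary_matches_hand_parse(self):
        from ehgpred._kernels import lz76_phrase_count

        for n in (16, 24, 32):
            sym = np.array([0, 1] * (n // 2), dtype=np.int64)
            assert lz76_parse(sym) == 3
            assert lz76_phrase_count(sym) == 3

    def test_phrase_counts_match_oracle_random(self, rng):
        from ehgpred._kernels import lz76_phrase_count

        for _ in range(20):
            n = int(rng.integers(10, 60))
            sym = rng.integers(0, 2, n)
            assert lz76_phrase_count(sym.astype(np.int64)) == lz76_parse(sym)

    def test_noise_more_complex_than_sine(self, rng):
        sine = ft.lempel_ziv(_sine(0.3), 2)
        for _ in range(20):
            noise = ft.lempel_ziv(rng.uniform(size=2400), 2)
            assert noise > sine
            assert 0.8 < noise < 1.2


class TestSampleEntropy:
    def test_pure_ramp_zero(self):
        assert ft.sample_entropy(np.arange(300.0)) == 0.0

    def test_matches_quadratic_oracle(self, short_windows):
        for w in short_windows[:30]:
            got = ft.sample_entropy(w)
            want = sampen_brute(w)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_noise_exceeds_sine_at_matched_sd(self, rng):
        sine = _sine(0.3, duration=15.0)
        sine_se = ft.sample_entropy(sine / np.std(sine))
        for _ in range(20):
            x = rng.standard_normal(300)
            assert ft.sample_entropy(x / np.std(x)) > sine_se

    def test_constant_window_sentinel(self):
        assert math.isnan(ft.sample_entropy(np.full(300, 2.0)))


class TestFuzzyEntropy:
    def test_matches_quadratic_oracle(self, short_windows):
        for w in short_windows[:30]:
            assert ft.fuzzy_entropy(w) == pytest.approx(fuzzyen_brute(w), abs=1e-10)

    def test_constant_window_sentinel(self):
        assert math.isnan(ft.fuzzy_entropy(np.full(300, 1.0)))

    def test_finite_where_sampen_undefined(self):
        # alternating spikes: m+1 templates never match exactly within r
        x = np.tile([0.0, 10.0, -10.0], 100) + np.linspace(0, 1, 300)
        if math.isnan(ft.sample_entropy(x)):
            assert math.isfinite(ft.fuzzy_entropy(x))
        else:  # construction failed to kill A; fuzzy must still be finite
            assert math.isfinite(ft.fuzzy_entropy(x))

    def test_nondefault_gradient_matches_oracle(self, short_windows):
        w = short_windows[1]
        got = ft.fuzzy_entropy(w, grad=3.0)
        assert got == pytest.approx(fuzzyen_brute(w, grad=3.0), abs=1e-10)


class TestSpectralEntropy:
    def test_delta_spectrum_zero(self):
        freqs = np.arange(0.0, 4.0, 1 / 120)
        power = np.zeros_like(freqs)
        power[np.argmin(np.abs(freqs - 0.5))] = 5.0
        assert ft.spectral_entropy(ft.PSD(freqs=freqs, power=power)) == 0.0

    def test_uniform_spectrum_one(self):
        freqs = np.arange(0.0, 4.0, 1 / 120)
        power = np.ones_like(freqs)
        assert ft.spectral_entropy(ft.PSD(freqs=freqs, power=power)) == pytest.approx(1.0)

    def test_noise_exceeds_tone(self, rng):
        tone = ft.spectral_entropy(ft.estimate_psd(_sine(0.5), FS))
        noise = ft.spectral_entropy(ft.estimate_psd(rng.standard_normal(2400), FS))
        assert noise > tone


class TestTimeReversibility:
    def test_sine_near_zero(self):
        # 2401 samples -> the 2400 lag-1 differences span 60 whole cycles
        t = np.arange(2401) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        assert abs(ft.time_reversibility(x)) < 1e-12

    def test_exact_antisymmetry(self, rng):
        x = rng.standard_normal(400)
        assert ft.time_reversibility(x[::-1]) == pytest.approx(
            -ft.time_reversibility(x), rel=1e-12
        )

    def test_sawtooth_negative_matches_direct_sum(self):
        # slow rise, fast fall
        x = np.tile(np.concatenate([np.linspace(0, 1, 20), [0.5]]), 20)
        got = ft.time_reversibility(x)
        d = x[1:] - x[:-1]
        assert got == pytest.approx(np.sum(d**3) / (x.size - 1))
        assert got < 0


class TestPoincare:
    def test_constant_window(self):
        sd1, sd2, ratio = ft.poincare(np.full(300, 1.0))
        assert sd1 == 0 and sd2 == 0 and math.isnan(ratio)

    def test_iid_noise_lag_covariance_identity(self, rng):
        x = rng.standard_normal(20000)
        sd1, sd2, ratio = ft.poincare(x)
        var = np.var(x)
        cov = np.mean((x[1:] - x[1:].mean()) * (x[:-1] - x[:-1].mean()))
        assert sd1**2 == pytest.approx(var - cov, rel=0.02)
        assert sd2**2 == pytest.approx(var + cov, rel=0.02)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_lowpass_signal_small_ratio(self, ehg_like_window):
        from scipy import signal as sps

        sos = sps.butter(4, 0.5, btype="lowpass", fs=FS, output="sos")
        x = sps.sosfilt(sos, ehg_like_window)
        _, _, ratio = ft.poincare(x)
        assert ratio < 0.5


# ---------------------------------------------------------------------------
# extract_all and invariance properties


class TestExtractAll:
    def test_vector_has_23_features(self, ehg_like_window):
        f = ft.extract_window(ehg_like_window, FS)
        assert len(f) == 23
        assert set(f) == set(ft.FEATURE_NAMES)

    def test_all_zero_window_no_exception(self):
        f = ft.extract_window(np.zeros(2400), FS)
        assert f["app"] == 0.0
        assert math.isnan(f["sampen"])
        assert f["lz_bin"] == pytest.approx(2 * math.log2(2400) / 2400)

    def test_window_count_bookkeeping(self, small_cohort):
        from ehgpred.ingest import condition, cut_windows

        _, cohort = small_cohort
        sig = condition(cohort[0].as_raw())
        ws = cut_windows(sig)
        df = ft.extract_all(ws)
        assert len(df) == len(ws.windows)
        assert list(df["start_s"]) == sorted(df["start_s"])


AMPLITUDE_SCALING = {
    # feature name -> exponent of the scale factor c under x -> c x
    **{name: 1 for name in ("app", "sd1", "sd2")},
    "timerev": 3,
    **{
        name: 0
        for name in (
            "df1",
            "df2",
            "hl_ratio",
            "d1",
            "d2",
            "d3",
            "d4",
            "d5",
            "d6",
            "d7",
            "d8",
            "d9",
            "smr",
            "lz_bin",
            "lz_multi6",
            "sampen",
            "fuzzyen",
            "specen",
            "sd1_sd2",
        )
    },
}


class TestInvariances:
    @pytest.mark.parametrize("scale", [0.25, 3.0, 40.0])
    def test_amplitude_equivariance_partition(self, ehg_like_window, scale):
        base = ft.extract_window(ehg_like_window, FS)
        scaled = ft.extract_window(scale * ehg_like_window, FS)
        for name, power in AMPLITUDE_SCALING.items():
            assert scaled[name] == pytest.approx(
                base[name] * scale**power, rel=1e-6
            ), name

    def test_deciles_monotone(self, rng, short_windows):
        for w in short_windows[:20]:
            x = np.tile(w, 8)  # long enough for the PSD precondition
            f = ft.extract_window(x, FS)
            deciles = [f[f"d{k}"] for k in range(1, 10)]
            assert all(a <= b for a, b in zip(deciles, deciles[1:]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 20.0))
    def test_scale_invariant_entropies_property(self, seed, scale):
        x = np.random.default_rng(seed).standard_normal(300)
        assert ft.sample_entropy(scale * x) == pytest.approx(
            ft.sample_entropy(x), rel=1e-9, nan_ok=True
        )
        assert ft.fuzzy_entropy(scale * x) == pytest.approx(
            ft.fuzzy_entropy(x), rel=1e-9, nan_ok=True
        )
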