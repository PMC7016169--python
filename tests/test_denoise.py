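"""Filter design/application, robust LOESS and NLM contracts, each checked
against an independent oracle where one exists."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgkit import synth
from ecgkit.denoise import (
    FilterDesignError,
    LoessSpec,
    LowpassSpec,
    NLMConfig,
    apply_zero_phase,
    denoise_record,
    denoise_signal,
    design_lowpass,
    estimate_noise_sd,
    loess_baseline,
    nlm_denoise,
    remove_baseline,
)
from .conftest import nlm_oracle

FS = 500.0


def _sinusoid(freq, fs=FS, n=5000, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestButterworthDesign:
    def test_minimum_order_matches_analytic_formula(self):
        spec = LowpassSpec()
        n_exact = math.log10((10 ** 0.25 - 1) / (10 ** 0.1 - 1)) / (2 * math.log10(60 / 50))
        assert design_lowpass(spec).order == math.ceil(n_exact) == 4

    def test_edge_constraints_met(self):
        filt = design_lowpass(LowpassSpec())
        assert filt.magnitude_db(50.0)[0] >= -1.0 - 1e-9
        assert filt.magnitude_db(60.0)[0] <= -2.5

    def test_dc_gain_is_unity(self):
        filt = design_lowpass(LowpassSpec())
        assert filt.magnitude_db(0.0)[0] == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(FilterDesignError):
            LowpassSpec(passband_hz=60.0, stopband_hz=50.0)


class TestZeroPhase:
    def test_passband_sinusoid_has_zero_lag(self):
        filt = design_lowpass(LowpassSpec())
        x = _sinusoid(10.0)
        y = apply_zero_phase(filt, x)
        period = int(FS / 10.0)
        lags = np.arange(-(period // 2 - 1), period // 2)  # within one period
        xc = [np.dot(x, np.roll(y, k)) for k in lags]
        assert lags[np.argmax(xc)] == 0

    def test_constant_signal_unchanged(self):
        filt = design_lowpass(LowpassSpec())
        x = np.full(3000, 123.4)
        np.testing.assert_allclose(apply_zero_phase(filt, x), x, rtol=1e-9)

    def test_stopband_attenuation_is_doubled_in_db(self):
        filt = design_lowpass(LowpassSpec())
        x = _sinusoid(60.0, n=20000)
        y = apply_zero_phase(filt, x)
        mid = slice(5000, 15000)  # avoid edge transients
        gain_db = 20 * np.log10(np.std(y[mid]) / np.std(x[mid]))
        single_db = filt.magnitude_db(60.0)[0]
        assert gain_db == pytest.approx(2 * single_db, abs=0.1)

    def test_signal_length_preserved(self):
        filt = design_lowpass(LowpassSpec())
        x = _sinusoid(5.0, n=777)
        assert apply_zero_phase(filt, x).shape == x.shape

    def test_too_short_signal_rejected(self):
        filt = design_lowpass(LowpassSpec())
        with pytest.raises(ValueError, match="too short"):
            apply_zero_phase(filt, np.zeros(12))


class TestLoess:
    def test_straight_line_reproduced_exactly(self):
        x = 2.0 + 3.0 * np.arange(1000)
        for degree in (1, 2):
            bl = loess_baseline(x, LoessSpec(span=0.2, degree=degree, robust_iterations=2))
            np.testing.assert_allclose(bl, x, rtol=1e-9)

    def test_quadratic_reproduced_by_degree_two(self):
        t = np.linspace(-1, 1, 800)
        x = 5.0 - 2.0 * t + 4.0 * t * t
        bl = loess_baseline(x, LoessSpec(span=0.25, degree=2))
        np.testing.assert_allclose(bl, x, rtol=1e-8, atol=1e-8)

    def test_constant_input_gives_constant_output(self):
        x = np.full(600, -42.0)
        np.testing.assert_allclose(loess_baseline(x, LoessSpec()), x, atol=1e-9)

    def test_isolated_spike_barely_moves_the_trend(self):
        t = np.arange(5000) / FS
        slow = 200.0 * np.sin(2 * np.pi * 0.2 * t)
        spec = LoessSpec()
        base = loess_baseline(slow, spec)
        spiked = slow.copy()
        spiked[2500] += 2000.0  # 10x the signal amplitude
        base2 = loess_baseline(spiked, spec)
        rms = np.sqrt(np.mean((base2 - base) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(slow ** 2))

    def test_wander_removal_halves_rms_error(self, clean_record):
        rec, _ = clean_record
        clean = rec.lead("II")
        t = np.arange(clean.size) / FS
        wander = 400.0 * np.sin(2 * np.pi * 0.3 * t + 0.7)
        noisy = clean + wander
        detrended = remove_baseline(noisy, LoessSpec())
        err_in = np.sqrt(np.mean((noisy - clean) ** 2))
        err_out = np.sqrt(np.mean((detrended - clean) ** 2))
        assert err_out < 0.5 * err_in

    def test_detrending_is_idempotent(self, clean_record):
        rec, _ = clean_record
        x = rec.lead("II") + 300.0 * np.sin(2 * np.pi * 0.25 * np.arange(5000) / FS)
        once = remove_baseline(x, LoessSpec())
        twice = remove_baseline(once, LoessSpec())
        scale = np.sqrt(np.mean(once ** 2))
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.02 * scale

    def test_tiny_span_rejected(self):
        with pytest.raises(ValueError):
            loess_baseline(np.zeros(100), LoessSpec(span=0.01, degree=2))

    def test_degree_one_no_robustness_matches_statsmodels_lowess(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=400))
        spec = LoessSpec(span=0.3, degree=1, robust_iterations=0)
        mine = loess_baseline(x, spec)
        theirs = statsmodels.nonparametric.lowess(
            x, np.arange(400.0), frac=0.3, it=0, return_sorted=False)
        np.testing.assert_allclose(mine, theirs, rtol=1e-6, atol=1e-6)


class TestNLM:
    def test_constant_input_returned_exactly(self):
        x = np.full(50, 7.5)
        cfg = NLMConfig(lambda_uv=None, patch_half_width=2, search_half_width=5)
        np.testing.assert_allclose(nlm_denoise(x, cfg), x, rtol=1e-12)

    def test_huge_lambda_tends_to_window_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 10, 60)
        cfg = NLMConfig(lambda_uv=1e9, patch_half_width=2, search_half_width=4,
                        kernel="uniform")
        out = nlm_denoise(x, cfg)
        n = x.size
        expect = np.array([x[max(0, i - 4):min(n, i + 5)].mean() for i in range(n)])
        np.testing.assert_allclose(out, expect, rtol=1e-6)

    def test_twenty_sample_case_equals_literal_oracle(self, rng):
        x = rng.normal(0, 25, 20)
        cfg = NLMConfig(lambda_uv=10.0, patch_half_width=1, search_half_width=3,
                        kernel="uniform")
        np.testing.assert_allclose(nlm_denoise(x, cfg), nlm_oracle(x, cfg),
                                   rtol=1e-12, atol=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.sampled_from(["uniform", "gaussian"]))
    def test_equals_oracle_on_random_instances(self, seed, kernel):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(1, 4))
        search = int(rng.integers(h, h + 5))
        n = int(rng.integers(2 * (h + search) + 1, 64))
        x = rng.normal(0, 30, n)
        cfg = NLMConfig(lambda_uv=float(rng.uniform(1, 50)),
                        patch_half_width=h,
                        search_half_width=search,
                        kernel=kernel)
        np.testing.assert_allclose(nlm_denoise(x, cfg), nlm_oracle(x, cfg),
                                   rtol=1e-11, atol=1e-11)

    def test_output_is_convex_combination_within_search_window(self, rng):
        x = rng.normal(0, 40, 120)
        cfg = NLMConfig(lambda_uv=15.0, patch_half_width=3, search_half_width=10)
        out = nlm_denoise(x, cfg)
        n = x.size
        for i in range(n):
            window = x[max(0, i - 10):min(n, i + 11)]
            assert window.min() - 1e-9 <= out[i] <= window.max() + 1e-9

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            NLMConfig(lambda_uv=0.0)

    def test_noise_sd_estimate_tracks_white_noise(self, rng):
        x = rng.normal(0, 12.0, 20000)
        assert estimate_noise_sd(x) == pytest.approx(12.0, rel=0.05)


class TestFullPipeline:
    def test_clean_input_nearly_unchanged(self, clean_record):
        rec, _ = clean_record
        x = rec.lead("II")
        y = denoise_signal(x, fs=FS)
        rms = np.sqrt(np.mean(x ** 2))
        assert np.sqrt(np.mean((y - x) ** 2)) < 0.05 * rms

    def test_full_noise_preset_rms_error_reduced(self):
        rec, _ = synth.generate_clean_record(seed=100)
        clean = rec.lead("II").copy()
        noisy = synth.add_noise(rec, synth.noise_preset("full", seed=101))
        y = denoise_signal(noisy.lead("II"), fs=FS)
        err_in = np.sqrt(np.mean((noisy.lead("II") - clean) ** 2))
        err_out = np.sqrt(np.mean((y - clean) ** 2))
        assert err_out < 0.4 * err_in

    def test_record_shape_and_lead_order_preserved(self, clean_record):
        rec, _ = clean_record
        small = NLMConfig(patch_half_width=5, search_half_width=40)
        loess = LoessSpec(robust_iterations=1)
        out = denoise_record(rec, loess=loess, nlm=small)
        assert out.samples.shape == rec.samples.shape
        assert out.leads == rec.leads
        assert out.n_samples == 5000

    def test_stage_error_names_the_lead(self, clean_record):
        rec, _ = clean_record
        short = rec.with_samples(rec.samples[:10, :])
        with pytest.raises(RuntimeError, match="lead I"):
            denoise_record(short)
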