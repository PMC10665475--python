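import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import respfusion as rf
from respfusion.preprocess import (
    axis_norm_combine,
    bandpass,
    denoise_accelerometer,
    median_filter,
    normalize_amplitude,
    pca_axis_combine,
    piezo_passthrough,
    resample_to,
    spectral_suppress,
    spectral_suppress_windowed,
    suppression_factor,
)
from respfusion.types import ChannelTrace, PipelineConfig


def dft_suppress_oracle(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Independent O(N^2) reference: explicit DFT sums -> per-bin exponential
    suppression -> explicit inverse-DFT sums."""
    n = len(x1)
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    X1 = W @ x1
    X2 = W @ x2
    mu = np.abs(X1).mean()
    sf = np.exp(-np.abs(X2) / mu)
    Xs = sf * X1
    return (np.conj(W) @ Xs).real / n


def trace(x, fs=100.0, name="t"):
    return ChannelTrace(name, np.asarray(x, dtype=float), fs)


class TestPassthroughAndBandpass:
    def test_piezo_identity(self, rng):
        t = trace(rng.normal(size=50))
        out = piezo_passthrough(t)
        assert out is t

    def test_band_preserves_in_band_tone(self):
        t = np.arange(20000) / 100.0
        tone = trace(np.sin(2 * np.pi * 0.25 * t))
        out = bandpass(tone, 0.1, 0.7)
        mid = slice(5000, 15000)  # avoid filter edges
        ratio = out.samples[mid].std() / tone.samples[mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_band_rejects_out_of_band_tone(self):
        t = np.arange(20000) / 100.0
        tone = trace(np.sin(2 * np.pi * 5.0 * t))
        out = bandpass(tone, 0.1, 0.7)
        assert out.samples.std() < 0.1 * tone.samples.std()

    def test_zero_in_zero_out(self):
        out = bandpass(trace(np.zeros(500)), 0.1, 0.7)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_invalid_band(self):
        with pytest.raises(rf.RespFusionError):
            bandpass(trace(np.zeros(100)), 0.7, 0.1)


class TestPCACombine:
    def test_collinear_axes_recover_generator(self, rng):
        x = rng.normal(size=400)
        tx, ty, tz = trace(x), trace(2 * x), trace(-x)
        out = pca_axis_combine(tx, ty, tz)
        # rank-1 cloud: output must be exactly proportional to x (centered)
        c = np.corrcoef(out.samples, x)[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)
        # unit-norm loading: output variance equals total cloud variance
        total = sum(np.var(a) for a in (x, 2 * x, -x))
        assert np.var(out.samples) == pytest.approx(total, rel=1e-9)

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(size=300)
        out1 = pca_axis_combine(trace(2 * x), trace(x), trace(x))
        # largest-variance axis is the first; loading on it must be positive
        assert np.corrcoef(out1.samples, x)[0, 1] > 0

    def test_isotropic_noise_pc1_share(self, rng):
        data = rng.normal(size=(30000, 3))
        out = pca_axis_combine(*(trace(data[:, i]) for i in range(3)))
        share = np.var(out.samples) / data.var(axis=0).sum()
        assert share == pytest.approx(1 / 3, abs=0.02)

    def test_constant_axes_zero_output(self):
        c = trace(np.full(100, 3.0))
        out = pca_axis_combine(c, c, c)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_length_mismatch(self):
        with pytest.raises(rf.RespFusionError):
            pca_axis_combine(trace(np.zeros(10)), trace(np.zeros(11)), trace(np.zeros(10)))

    def test_norm_combine_matches_euclidean(self, rng):
        a = rng.normal(size=(3, 50))
        out = axis_norm_combine(*(trace(a[i]) for i in range(3)))
        mag = np.sqrt((a**2).sum(axis=0))
        np.testing.assert_allclose(out.samples, mag - mag.mean())


class TestSuppressionFactor:
    def test_zero_noise_gives_unity(self):
        sf = suppression_factor(np.ones(8), np.zeros(8))
        np.testing.assert_allclose(sf, 1.0)

    def test_noise_at_mean_gives_inverse_e(self, rng):
        a1 = rng.uniform(0.5, 2.0, size=16)
        a2 = np.full(16, a1.mean())
        np.testing.assert_allclose(
            suppression_factor(a1, a2), np.exp(-1.0), rtol=1e-12
        )

    def test_matches_elementwise_formula(self, rng):
        a1 = rng.uniform(0, 3, size=16)
        a2 = rng.uniform(0, 3, size=16)
        expected = np.exp(-a2 / a1.mean())
        np.testing.assert_allclose(suppression_factor(a1, a2), expected, rtol=1e-12)

    def test_degenerate_signal(self):
        with pytest.raises(rf.RespFusionError, match="degenerate"):
            suppression_factor(np.zeros(4), np.ones(4))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotonicity_in_noise_magnitude(self, seed):
        r = np.random.default_rng(seed)
        a1 = r.uniform(0.1, 2.0, size=12)
        a2 = r.uniform(0.0, 2.0, size=12)
        bumped = a2.copy()
        i = int(r.integers(12))
        bumped[i] += r.uniform(0.1, 1.0)
        sf, sfb = suppression_factor(a1, a2), suppression_factor(a1, bumped)
        assert sfb[i] < sf[i]
        np.testing.assert_allclose(np.delete(sfb, i), np.delete(sf, i))


class TestSpectralSuppress:
    def test_zero_reference_is_identity(self, rng):
        x1 = trace(rng.normal(size=64))
        x2 = trace(np.zeros(64))
        out = spectral_suppress(x1, x2)
        np.testing.assert_allclose(out.denoised.samples, x1.samples, atol=1e-9)
        np.testing.assert_allclose(out.sf, 1.0)

    @pytest.mark.parametrize("n", [8, 17, 32, 64])
    def test_matches_brute_force_dft_oracle(self, rng, n):
        for _ in range(25):
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            out = spectral_suppress(trace(x1), trace(x2))
            np.testing.assert_allclose(
                out.denoised.samples, dft_suppress_oracle(x1, x2), atol=1e-9
            )

    def test_invariants_bounds_energy_realness(self, rng):
        for _ in range(20):
            x1 = rng.normal(size=48) * rng.uniform(0.1, 10)
            x2 = rng.normal(size=48) * rng.uniform(0.1, 10)
            out = spectral_suppress(trace(x1), trace(x2))
            assert np.all(out.sf > 0) and np.all(out.sf <= 1)
            assert np.all(
                np.abs(out.suppressed_spectrum) <= np.abs(out.x1_spectrum) + 1e-12
            )
            assert np.sum(out.denoised.samples**2) <= np.sum(x1**2) + 1e-9

    def test_length_mismatch(self):
        with pytest.raises(rf.RespFusionError):
            spectral_suppress(trace(np.ones(8)), trace(np.ones(9)))

    def test_windowed_variant_identity_with_silent_reference(self):
        t = np.arange(12000) / 100.0
        x1 = trace(np.sin(2 * np.pi * 0.25 * t))
        x2 = trace(np.full(12000, 1e-9))
        out = spectral_suppress_windowed(x1, x2, 3000)
        assert np.corrcoef(out.samples, x1.samples)[0, 1] > 0.999


class TestDenoiseAccelerometer:
    def test_silent_reference_reduces_to_bandpassed_pc1(self, rng):
        cfg = PipelineConfig(suppress_window_s=None)
        axes1 = tuple(trace(rng.normal(size=2000)) for _ in range(3))
        axes2 = tuple(trace(np.full(2000, 0.0) + 1e-12) for _ in range(3))
        out = denoise_accelerometer(axes1, axes2, cfg)
        bp = [bandpass(a, cfg.bandpass_low_hz, cfg.bandpass_high_hz) for a in axes1]
        expected = pca_axis_combine(*bp)
        np.testing.assert_allclose(out.samples, expected.samples, atol=1e-9)

    def test_mismatched_fs_rejected(self, rng):
        a1 = tuple(trace(rng.normal(size=100), fs=100.0) for _ in range(3))
        a2 = tuple(trace(rng.normal(size=100), fs=50.0) for _ in range(3))
        with pytest.raises(rf.RespFusionError, match="mismatch"):
            denoise_accelerometer(a1, a2)

    def test_recovers_respiration_from_shared_noise(self, small_sim):
        rec = small_sim.recording
        clean = small_sim.clean_respiration.samples[::2]
        a1 = tuple(rec[f"acc1_{a}"] for a in "xyz")
        a2 = tuple(rec[f"acc2_{a}"] for a in "xyz")
        raw = pca_axis_combine(*a1)
        den = denoise_accelerometer(a1, a2)
        c_raw = abs(np.corrcoef(raw.samples, clean)[0, 1])
        c_den = abs(np.corrcoef(den.samples, clean)[0, 1])
        assert c_den > c_raw


class TestResample:
    def test_length_contract(self, rng):
        out = resample_to(trace(rng.normal(size=1000), fs=100.0), 200.0)
        assert len(out) == 2000 and out.fs == 200.0

    def test_identity_when_rates_match(self, rng):
        t = trace(rng.normal(size=100))
        assert resample_to(t, t.fs) is t

    def test_upsampling_preserves_peak_location(self):
        t = np.arange(600) / 10.0
        tone = trace(np.sin(2 * np.pi * 0.3 * t), fs=10.0)
        out = resample_to(tone, 200.0)
        spec = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(len(out), 1 / 200.0)
        peak = freqs[np.argmax(spec[1:]) + 1]
        assert abs(peak - 0.3) <= freqs[1] + 1e-12

    def test_invalid_target(self):
        with pytest.raises(rf.RespFusionError):
            resample_to(trace(np.zeros(10)), -1.0)


class TestMedianFilter:
    def test_kernel_one_identity(self, rng):
        t = trace(rng.normal(size=50))
        assert median_filter(t, 1) is t

    def test_impulse_removed(self):
        out = median_filter(trace([0, 0, 9, 0, 0]), 3)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_matches_naive_sliding_median(self, rng):
        x = rng.normal(size=101)
        k = 5
        out = median_filter(trace(x), k)
        padded = np.pad(x, k // 2, mode="symmetric")  # edge sample included
        naive = np.array([np.median(padded[i : i + k]) for i in range(len(x))])
        np.testing.assert_allclose(out.samples, naive)

    def test_even_kernel_rejected(self):
        with pytest.raises(rf.RespFusionError):
            median_filter(trace(np.zeros(10)), 4)


class TestNormalize:
    @pytest.mark.parametrize(
        "data,expected",
        [([-2, 0, 2], [-1, 0, 1]), ([0, 5], [-1, 1]), ([3, 3, 3], [0, 0, 0])],
    )
    def test_examples(self, data, expected):
        out = normalize_amplitude(trace(data))
        np.testing.assert_allclose(out.samples, expected)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_range_and_endpoints(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=int(r.integers(2, 200))) * r.uniform(0.01, 100)
        out = normalize_amplitude(trace(x)).samples
        assert out.min() >= -1 - 1e-12 and out.max() <= 1 + 1e-12
        if x.max() > x.min():
            assert out.min() == pytest.approx(-1) and out.max() == pytest.approx(1)
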