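"""Metrics, rate-matched JPEG baseline, and spectral peak retention."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from tcsem.coding import VideoBlock, encode, generate_masks, normalize_measurement
from tcsem.errors import DimensionError, ParameterError
from tcsem.evaluation import (PSNR_CAP, evaluate_reconstruction,
                              fft_peak_contrast, jpeg_rate_matched,
                              naive_baseline, psnr, ssim)
from tcsem.synthetic import SceneConfig, lattice_video


def _textured(n=64, seed=0, peak=255.0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.uniform(0, 1, (n, n)), 2.0)
    img = (img - img.min()) / np.ptp(img)
    return img * peak


class TestPsnr:
    def test_identical_frames_hit_sentinel_cap(self):
        a = _textured()
        assert psnr(a, a, 255.0) == PSNR_CAP

    def test_constant_offset_closed_form(self):
        # MSE of a flat offset of 16 on peak 255: 10 log10(255^2/256) = 24.05 dB
        a = _textured()
        b = a + 16.0
        assert psnr(a, b, 255.0) == pytest.approx(24.0483, abs=1e-3)

    def test_monotone_decrease_with_noise_amplitude(self):
        a = _textured()
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1, a.shape)
        values = [psnr(a, a + amp * noise, 255.0) for amp in (2.0, 8.0, 32.0)]
        assert values[0] > values[1] > values[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)), 255.0)


class TestSsim:
    def test_identical_frames_give_one(self):
        a = _textured()
        assert ssim(a, a, 255.0) == pytest.approx(1.0)

    def test_inverted_image_below_one(self):
        a = _textured()
        assert ssim(a, 255.0 - a, 255.0) < 0.5

    def test_agrees_with_independent_windowed_implementation(self):
        """Direct Gaussian-window SSIM agrees with the package to 1e-6."""
        a = _textured(n=48, seed=2)
        b = np.clip(a + np.random.default_rng(3).normal(0, 12, a.shape), 0, 255)
        peak = 255.0

        # independently coded reference: 11-tap Gaussian window, sigma 1.5
        t = np.arange(11) - 5
        g = np.exp(-t ** 2 / (2 * 1.5 ** 2))
        kern = np.outer(g, g)
        kern /= kern.sum()

        def filt(x):
            from scipy.signal import convolve2d
            return convolve2d(x, kern, mode="valid")

        c1, c2 = (0.01 * peak) ** 2, (0.03 * peak) ** 2
        mu_a, mu_b = filt(a), filt(b)
        var_a = filt(a * a) - mu_a ** 2
        var_b = filt(b * b) - mu_b ** 2
        cov = filt(a * b) - mu_a * mu_b
        smap = ((2 * mu_a * mu_b + c1) * (2 * cov + c2) /
                ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))
        assert ssim(a, b, peak) == pytest.approx(float(smap.mean()), abs=1e-6)

    def test_frame_smaller_than_window_rejected(self):
        with pytest.raises(ParameterError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)), 255.0)


@pytest.fixture(scope="module")
def video96():
    cfg = SceneConfig(kind="lattice", b=4, nx=96, ny=96, seed=20, dose=200.0)
    _, noisy = lattice_video(cfg)
    return noisy


class TestJpegRateMatched:
    def test_bytes_monotone_in_quality(self, video96):
        from tcsem.evaluation import _jpeg_bytes
        u8 = video96.frames[0].astype(np.uint8)
        sizes = [len(_jpeg_bytes(u8, q)) for q in (5, 20, 40, 60, 80, 95)]
        assert sizes == sorted(sizes)

    def test_bisection_contract(self, video96):
        from tcsem.evaluation import _jpeg_bytes
        result = jpeg_rate_matched(video96, 4)
        budget = 96 * 96 // 4
        assert result.budget == budget
        for frame, q, used, flag in zip(video96.frames, result.qualities,
                                        result.bytes_used, result.infeasible):
            assert not flag
            assert used <= budget
            if q < 95:
                u8 = frame.astype(np.uint8)
                assert len(_jpeg_bytes(u8, q + 1)) > budget

    def test_low_compression_near_lossless_vs_high(self, video96):
        one = jpeg_rate_matched(video96, 1)
        twelve = jpeg_rate_matched(video96, 12)
        p1 = np.mean([psnr(t, d, 255.0) for t, d in
                      zip(video96.frames, one.video.frames)])
        p12 = np.mean([psnr(t, d, 255.0) for t, d in
                       zip(video96.frames, twelve.video.frames)])
        assert p1 > p12

    def test_tiny_frame_infeasible_flagged(self):
        video = VideoBlock(frames=np.full((2, 16, 16), 128.0))
        result = jpeg_rate_matched(video, 2)  # budget 128 bytes < any JPEG
        assert all(result.infeasible)
        assert all(q == 1 for q in result.qualities)


class TestNaiveBaseline:
    def test_constant_scene_hits_cap_and_frame_count(self):
        video = VideoBlock(frames=np.full((3, 16, 16), 55.0))
        masks = generate_masks(3, 16, 16, seed=2, guarantee_coverage=True)
        nm = normalize_measurement(encode(video, masks), masks)
        base = naive_baseline(nm, 3)
        assert base.b == 3
        assert psnr(video.frames[0], base.frames[0], 255.0) == PSNR_CAP

    def test_psnr_decreases_with_drift_speed(self):
        values = []
        for speed in (0.0, 0.8, 1.6):
            cfg = SceneConfig(kind="lattice", b=4, nx=32, ny=32, seed=3,
                              drift=(speed, 0.0), spacings=(6.0,),
                              orientations=(0.0,), amplitudes=(0.2,),
                              dose=np.inf, gaussian_sigma=0.0)
            clean, _ = lattice_video(cfg)
            masks = generate_masks(4, 32, 32, seed=4, guarantee_coverage=True)
            nm = normalize_measurement(encode(clean, masks), masks)
            base = naive_baseline(nm, 4)
            values.append(np.mean([psnr(t, f, 255.0) for t, f in
                                   zip(clean.frames, base.frames)]))
        assert values[0] > values[1] > values[2]


class TestFftPeakContrast:
    def test_pure_cosine_far_above_noise_floor(self):
        n = 64
        gx, gy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        img = 100 + 40 * np.cos(2 * np.pi * 8 / n * gx)
        assert fft_peak_contrast(img, (8, 0), window=2) > 10

    def test_white_noise_matches_noise_floor_oracle(self):
        """Mean ratio over draws matches an independent order-statistic
        simulation of the same max-of-window / median-of-annulus statistic
        on a flat complex-Gaussian spectrum."""
        rng = np.random.default_rng(7)
        measured = np.mean([
            fft_peak_contrast(rng.normal(0, 1, (64, 64)), (10, 6), window=2)
            for _ in range(20)])
        # oracle: Rayleigh magnitudes, same window (25 bins) and annulus
        orng = np.random.default_rng(8)
        n_annulus = 96  # bins between radius 2 and 6 (approximate count)
        oracle = np.mean([
            np.max(orng.rayleigh(1.0, 25)) / np.median(orng.rayleigh(1.0, n_annulus))
            for _ in range(4000)])
        assert measured == pytest.approx(oracle, rel=0.2)

    def test_invariant_to_constant_offset(self):
        img = _textured(n=64, seed=9)
        r1 = fft_peak_contrast(img, (8, 4), window=2)
        r2 = fft_peak_contrast(img + 57.0, (8, 4), window=2)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ParameterError):
            fft_peak_contrast(np.zeros((32, 32)), (40, 0))
        with pytest.raises(ParameterError):
            fft_peak_contrast(np.zeros((32, 32)), (8, 0), window=10)


class TestMetricsReport:
    def test_averages_equal_mean_of_per_frame_values(self):
        rng = np.random.default_rng(11)
        truth = VideoBlock(frames=rng.uniform(0, 255, (4, 32, 32)))
        cand = VideoBlock(frames=np.clip(
            truth.frames + rng.normal(0, 10, truth.frames.shape), 0, 255))
        rep = evaluate_reconstruction(truth, cand, method="x", b=4)
        assert rep.mean_psnr == pytest.approx(np.mean(rep.per_frame_psnr),
                                              abs=1e-9)
        assert rep.mean_ssim == pytest.approx(np.mean(rep.per_frame_ssim),
                                              abs=1e-9)
        assert all(-1 <= s <= 1 for s in rep.per_frame_ssim)
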