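"""Reference evaluation protocols for the encode-train-decode loop.

These helpers standardize how a trained decoder is scored so that tests,
scripts and examples measure the same quantities the same way:

* held-out scoring against the naive Ybar-replication baseline,
* a fixed noisy-lattice evaluation suite with a known fringe frequency,
  scored against the rate-matched JPEG baseline including the Fourier
  peak-contrast (Bragg-spot retention) statistic.

The decoder is fully convolutional, so a model trained on small patches
evaluates on larger frames; the coding masks are extended to the larger
canvas by periodic tiling, which preserves the local mask statistics the
model saw in training.
"""

from __future__ import annotations

import math

import numpy as np

from .coding import MaskSet, encode, normalize_measurement
from .evaluation import (fft_peak_contrast, jpeg_rate_matched, naive_baseline,
                         psnr, ssim)
from .synthetic import SceneConfig, lattice_video
from .training import ClipPair

__all__ = ["tile_masks", "score_on_pairs", "lattice_eval_scenes",
           "compare_with_jpeg"]


def tile_masks(masks: MaskSet, nx: int, ny: int) -> MaskSet:
    """Periodically tile mask planes to cover an (nx, ny) canvas."""
    mx, my = masks.frame_shape
    reps = (1, -(-nx // mx), -(-ny // my))
    tiled = np.tile(masks.masks, reps)[:, :nx, :ny]
    return MaskSet(masks=tiled, seed=masks.seed, density=masks.density)


def score_on_pairs(net, masks: MaskSet, pairs: list[ClipPair]) -> dict:
    """Mean PSNR/SSIM of the decoder and the naive baseline on clip pairs.

    Each pair's ``video`` is encoded with the masks and decoded; metrics
    are computed per frame against the pair's ``target`` and averaged over
    all frames of all clips.
    """
    acc = {"psnr_decoder": [], "psnr_naive": [],
           "ssim_decoder": [], "ssim_naive": []}
    for pair in pairs:
        m = encode(pair.video, masks)
        recon, _ = net.reconstruct(m, masks)
        naive = naive_baseline(normalize_measurement(m, masks), masks.b)
        peak = pair.target.pixel_peak
        for t, r, n in zip(pair.target.frames, recon.frames, naive.frames):
            acc["psnr_decoder"].append(psnr(t, r, peak))
            acc["psnr_naive"].append(psnr(t, n, peak))
            acc["ssim_decoder"].append(ssim(t, r, peak))
            acc["ssim_naive"].append(ssim(t, n, peak))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def lattice_eval_scenes(b: int, *, n_scenes: int = 3, nx: int = 96,
                        ny: int = 96, spacing: float = 6.0,
                        orientation: float = 30.0, amplitude: float = 0.18,
                        dose: float = 200.0, gaussian_sigma: float = 0.01,
                        seed: int = 100) -> tuple[list[ClipPair],
                                                  tuple[float, float]]:
    """Fixed noisy drifting-lattice fixtures with a known fringe frequency.

    Returns (pairs, freq) where freq is the fringe's position in FFT bin
    units for :func:`tcsem.evaluation.fft_peak_contrast`.
    """
    th = math.radians(orientation)
    freq = (nx / spacing * math.cos(th), ny / spacing * math.sin(th))
    pairs = []
    for i in range(n_scenes):
        ang = math.radians(25.0 + 40.0 * i / max(1, n_scenes - 1))
        drift = (0.4 * math.cos(ang), 0.4 * math.sin(ang))
        cfg = SceneConfig(kind="lattice", b=b, nx=nx, ny=ny, seed=seed + i,
                          drift=drift, spacings=(spacing,),
                          orientations=(orientation,),
                          amplitudes=(amplitude,), background=0.5,
                          dose=dose, gaussian_sigma=gaussian_sigma)
        clean, noisy = lattice_video(cfg)
        pairs.append(ClipPair(video=noisy, target=clean))
    return pairs, freq


def compare_with_jpeg(net, masks: MaskSet, pairs: list[ClipPair],
                      freq: tuple[float, float], *, window: int = 2) -> dict:
    """Decoder vs rate-matched JPEG on fixed scenes, plus peak retention.

    JPEG compresses each raw (noisy) frame to 1/B of its 8-bit size — the
    storage parity point with the snapshot measurement; both are scored
    against the clean ground truth.  ``fft_*`` values are the mean Fourier
    peak contrasts at the lattice frequency.
    """
    b = masks.b
    out = {"psnr_decoder": [], "psnr_jpeg": [], "ssim_decoder": [],
           "ssim_jpeg": [], "fft_decoder": [], "fft_jpeg": [],
           "fft_truth": [], "jpeg_infeasible": 0}
    for pair in pairs:
        m = encode(pair.video, masks)
        recon, _ = net.reconstruct(m, masks)
        jr = jpeg_rate_matched(pair.video, b)
        out["jpeg_infeasible"] += sum(jr.infeasible)
        peak = pair.target.pixel_peak
        for t, r, j in zip(pair.target.frames, recon.frames, jr.video.frames):
            out["psnr_decoder"].append(psnr(t, r, peak))
            out["psnr_jpeg"].append(psnr(t, j, peak))
            out["ssim_decoder"].append(ssim(t, r, peak))
            out["ssim_jpeg"].append(ssim(t, j, peak))
            out["fft_decoder"].append(fft_peak_contrast(r, freq, window))
            out["fft_jpeg"].append(fft_peak_contrast(j, freq, window))
            out["fft_truth"].append(fft_peak_contrast(t, freq, window))
    return {k: (float(np.mean(v)) if isinstance(v, list) else v)
            for k, v in out.items()}
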