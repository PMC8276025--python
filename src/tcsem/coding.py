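"""Temporal compressive-sensing encoder: coded masks, measurement, normalization.

A block of B video frames X_1..X_B is modulated element-wise by B binary
masks C_1..C_B and summed into a single snapshot measurement

    Y = sum_b X_b * C_b,

which is the whole encoder: storage shrinks by a factor of B once the masks
are pre-shared.  The normalized measurement

    Ybar = Y / sum_k C_k      (element-wise, where the coverage is nonzero)

is a crude scene estimate used as the decoder's anchor channel; Ybar * C_k
approximates the k-th coded frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError, ProvenanceError

__all__ = [
    "MaskSet", "VideoBlock", "Measurement", "NormalizedMeasurement",
    "generate_masks", "all_ones_masks", "encode", "normalize_measurement",
    "approx_coded_frames",
]


@dataclass
class MaskSet:
    """B binary coding masks of shape (B, Nx, Ny), values exactly 0 or 1."""

    masks: np.ndarray
    seed: int
    density: float = 0.5

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise DimensionError("masks must be a (B, Nx, Ny) stack")
        vals = np.unique(self.masks)
        if not np.isin(vals, (0, 1)).all():
            raise ParameterError("mask elements must be exactly 0 or 1")

    @property
    def b(self) -> int:
        return self.masks.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]

    def coverage(self) -> np.ndarray:
        """Per-pixel number of masks that are open: sum_k C_k."""
        return self.masks.sum(axis=0)


@dataclass
class VideoBlock:
    """B non-negative grayscale frames plus the peak representable intensity."""

    frames: np.ndarray
    pixel_peak: float = 255.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise DimensionError("frames must be a (B>=1, Nx, Ny) stack")
        if not np.isfinite(self.frames).all():
            raise ParameterError("frame intensities must be finite")
        if self.frames.min() < 0:
            raise ParameterError("frame intensities must be non-negative")

    @property
    def b(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Measurement:
    """One coded snapshot Y; dynamic range up to B * pixel_peak, never clipped."""

    y: np.ndarray
    b_used: int
    mask_seed: int
    pixel_peak: float = 255.0

    def __post_init__(self):
        # a 32-bit accumulator holds B * pixel_peak for any realistic B
        if np.issubdtype(np.asarray(self.y).dtype, np.integer):
            self.y = np.asarray(self.y, dtype=np.int32)
        else:
            self.y = np.asarray(self.y, dtype=np.float32)


@dataclass
class NormalizedMeasurement:
    """Ybar = Y / coverage with zero-coverage pixels set to 0 and flagged."""

    ybar: np.ndarray
    zero_coverage_mask: np.ndarray
    b_used: int = 0
    mask_seed: int = 0
    pixel_peak: float = 255.0

    def __post_init__(self):
        self.ybar = np.asarray(self.ybar, dtype=np.float32)
        self.zero_coverage_mask = np.asarray(self.zero_coverage_mask, dtype=bool)


def _frame_rng(seed: int, index: int) -> np.random.Generator:
    """Generator keyed by (seed, frame index): draw-order independent."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def generate_masks(b: int, nx: int, ny: int, seed: int,
                   density: float = 0.5, *,
                   guarantee_coverage: bool = False) -> MaskSet:
    """Draw B i.i.d. Bernoulli(density) binary masks, reproducible under seed.

    With ``guarantee_coverage`` pixels left closed by every mask are re-opened
    in one mask chosen uniformly, so the coverage sum_k C_k is >= 1 everywhere
    (a deviation from pure i.i.d. draws; off by default).
    """
    if b < 1 or nx < 1 or ny < 1:
        raise DimensionError(f"dimensions must be positive, got B={b}, {nx}x{ny}")
    if not 0.0 < density < 1.0:
        raise ParameterError(f"density must lie in (0, 1), got {density}")
    masks = np.empty((b, nx, ny), dtype=np.uint8)
    for k in range(b):
        masks[k] = (_frame_rng(seed, k).random((nx, ny)) < density)
    if guarantee_coverage:
        hole = masks.sum(axis=0) == 0
        if hole.any():
            pick = _frame_rng(seed, b).integers(0, b, size=int(hole.sum()))
            xs, ys = np.nonzero(hole)
            masks[pick, xs, ys] = 1
    return MaskSet(masks=masks, seed=seed, density=density)


def all_ones_masks(b: int, nx: int, ny: int) -> MaskSet:
    """Degenerate fully-open masks (identity code for B=1)."""
    return MaskSet(masks=np.ones((b, nx, ny), dtype=np.uint8), seed=-1, density=1.0)


def _check_shapes(video: VideoBlock, masks: MaskSet) -> None:
    if video.frames.shape != masks.masks.shape:
        raise DimensionError(
            f"video shape {video.frames.shape} != mask shape {masks.masks.shape}")


def encode(video: VideoBlock, masks: MaskSet) -> Measurement:
    """Forward model: Y = sum_b X_b * C_b, accumulated without clipping."""
    _check_shapes(video, masks)
    y = np.einsum("bij,bij->ij", video.frames.astype(np.float32),
                  masks.masks.astype(np.float32))
    return Measurement(y=y, b_used=video.b, mask_seed=masks.seed,
                       pixel_peak=video.pixel_peak)


def normalize_measurement(m: Measurement, masks: MaskSet) -> NormalizedMeasurement:
    """Ybar = Y / (sum_k C_k); zero-coverage pixels become 0 and are flagged."""
    if m.b_used != masks.b or m.mask_seed != masks.seed:
        raise ProvenanceError(
            f"measurement (B={m.b_used}, mask_seed={m.mask_seed}) was not "
            f"produced with these masks (B={masks.b}, seed={masks.seed})")
    cov = masks.coverage().astype(np.float32)
    zero = cov == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} pixel(s) have zero mask coverage; "
                      "Ybar set to 0 there", stacklevel=2)
    ybar = np.divide(np.asarray(m.y, dtype=np.float32), cov,
                     out=np.zeros_like(cov), where=~zero)
    return NormalizedMeasurement(ybar=ybar, zero_coverage_mask=zero,
                                 b_used=m.b_used, mask_seed=m.mask_seed,
                                 pixel_peak=m.pixel_peak)


def approx_coded_frames(nm: NormalizedMeasurement, masks: MaskSet) -> np.ndarray:
    """The B approximate coded frames Ybar * C_k used as decoder input channels."""
    if nm.ybar.shape != masks.frame_shape:
        raise DimensionError(
            f"ybar shape {nm.ybar.shape} != mask frame shape {masks.frame_shape}")
    return nm.ybar[None] * masks.masks.astype(np.float32)
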