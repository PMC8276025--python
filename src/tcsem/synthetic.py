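"""Synthetic in-situ EM video: drifting lattice fringes and moving fibers.

Two scene families cover the regimes snapshot compression is aimed at:

* ``lattice`` — atomic-resolution fringes: a sum of drifting 2-D cosines,
  optionally windowed by a shrinking particle envelope to mimic sintering.
* ``fibers`` — low-magnification morphology: dark smooth-profile ribbons
  moving over a bright background, as in in-situ deformation series.

Detector noise is Poisson-Gaussian: intensities are expressed as a fraction
of ``pixel_peak``, scaled by an electron ``dose`` (expected counts per pixel
at full scale), Poisson-sampled, rescaled, and perturbed with additive
Gaussian read noise.  ``dose=inf`` switches noise off.

Both generators return (clean, noisy) ``VideoBlock`` pairs and are fully
deterministic under ``seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .coding import VideoBlock
from .errors import ParameterError

__all__ = ["SceneConfig", "lattice_video", "fiber_video", "simulate_scene",
           "random_scene_config"]

#: default drift keeps successive frames coherent (|v| <= 2 px/frame)
_DEFAULT_DRIFT = (0.25, 0.1)


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Intensities (``background``, ``amplitudes``, fiber ``depths``) are
    fractions of ``pixel_peak``; lengths are in pixels, angles in degrees,
    velocities in pixels/frame.
    """

    kind: str = "lattice"
    b: int = 4
    nx: int = 32
    ny: int = 32
    seed: int = 0
    pixel_peak: float = 255.0
    drift: tuple[float, float] = _DEFAULT_DRIFT
    # lattice scene
    spacings: tuple[float, ...] = (6.0, 4.0)
    orientations: tuple[float, ...] = (0.0, 60.0)
    amplitudes: tuple[float, ...] = (0.16, 0.12)
    phases: tuple[float, ...] | None = None
    background: float = 0.55
    envelope: dict | None = None  # {"center": (x, y), "radius": r, "shrink": px/frame}
    # fiber scene
    fiber_positions: tuple[float, ...] = (10.0, 22.0)
    fiber_widths: tuple[float, ...] = (2.5, 4.0)
    fiber_depths: tuple[float, ...] = (0.45, 0.35)
    fiber_velocities: tuple[float, ...] = (0.4, -0.3)
    fiber_angles: tuple[float, ...] = (4.0, -6.0)
    fiber_background: float = 0.8
    # detector noise
    dose: float = 200.0
    gaussian_sigma: float = 0.01
    boundary: str = "periodic"  # or "clamped"

    def __post_init__(self):
        if self.kind not in ("lattice", "fibers"):
            raise ParameterError(f"unknown scene kind {self.kind!r}")
        if self.b < 1 or self.nx < 1 or self.ny < 1:
            raise ParameterError("b, nx, ny must be positive")
        if not (self.dose > 0):
            raise ParameterError("dose must be positive (inf disables noise)")
        if math.hypot(*self.drift) > 2.0 + 1e-9:
            warnings.warn("drift exceeds 2 px/frame; successive frames may be "
                          "too incoherent for recurrent reconstruction",
                          stacklevel=2)


def _apply_noise(clean_rel: np.ndarray, cfg: SceneConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if math.isinf(cfg.dose):
        noisy = clean_rel.copy()
    else:
        noisy = rng.poisson(clean_rel * cfg.dose).astype(np.float64) / cfg.dose
    if cfg.gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, cfg.gaussian_sigma, size=noisy.shape)
    return noisy


def _finish(clean_rel: np.ndarray, cfg: SceneConfig,
            rng: np.random.Generator) -> tuple[VideoBlock, VideoBlock]:
    if clean_rel.min() < 0:
        warnings.warn("negative intensities after scene composition; "
                      "clipping at 0", stacklevel=3)
        clean_rel = np.clip(clean_rel, 0.0, None)
    clean_rel = np.clip(clean_rel, 0.0, 1.0)
    noisy_rel = np.clip(_apply_noise(clean_rel, cfg, rng), 0.0, 1.0)
    peak = cfg.pixel_peak
    return (VideoBlock(frames=(clean_rel * peak).astype(np.float32), pixel_peak=peak),
            VideoBlock(frames=(noisy_rel * peak).astype(np.float32), pixel_peak=peak))


def _grids(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(cfg.nx, dtype=np.float64),
                       np.arange(cfg.ny, dtype=np.float64), indexing="ij")


def lattice_video(config: SceneConfig) -> tuple[VideoBlock, VideoBlock]:
    """Drifting cosine fringes, optionally inside a shrinking particle.

    Frame t is ``background + sum_i A_i cos(k_i . (r - v t) + phi_i)``; the
    cosine composition makes periodic-boundary drift exact by construction.
    """
    if config.kind != "lattice":
        raise ParameterError("lattice_video requires kind='lattice'")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gx, gy = _grids(cfg)
    n_freq = len(cfg.spacings)
    phases = cfg.phases if cfg.phases is not None else tuple(
        rng.uniform(0.0, 2 * math.pi, size=n_freq))
    frames = np.empty((cfg.b, cfg.nx, cfg.ny))
    vx, vy = cfg.drift
    for t in range(cfg.b):
        acc = np.full((cfg.nx, cfg.ny), cfg.background)
        fringe = np.zeros_like(acc)
        for d, theta, a, phi in zip(cfg.spacings, cfg.orientations,
                                    cfg.amplitudes, phases):
            th = math.radians(theta)
            kx = 2 * math.pi / d * math.cos(th)
            ky = 2 * math.pi / d * math.sin(th)
            fringe += a * np.cos(kx * (gx - vx * t) + ky * (gy - vy * t) + phi)
        if cfg.envelope is not None:
            cx, cy = cfg.envelope.get("center", (cfg.nx / 2, cfg.ny / 2))
            r0 = cfg.envelope.get("radius", min(cfg.nx, cfg.ny) / 3)
            r = max(r0 - cfg.envelope.get("shrink", 0.0) * t, 1.0)
            env = np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * r * r))
            fringe *= env
        frames[t] = acc + fringe
    return _finish(frames, cfg, rng)


def fiber_video(config: SceneConfig) -> tuple[VideoBlock, VideoBlock]:
    """Dark Gaussian-profile ribbons moving across a bright background."""
    if config.kind != "fibers":
        raise ParameterError("fiber_video requires kind='fibers'")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gx, gy = _grids(cfg)  # gx: row index, gy: column index
    frames = np.empty((cfg.b, cfg.nx, cfg.ny))
    for t in range(cfg.b):
        acc = np.full((cfg.nx, cfg.ny), cfg.fiber_background)
        for c0, w, depth, v, ang in zip(cfg.fiber_positions, cfg.fiber_widths,
                                        cfg.fiber_depths, cfg.fiber_velocities,
                                        cfg.fiber_angles):
            c = c0 + v * t
            if cfg.boundary == "periodic":
                c = c % cfg.ny
            elif not -w <= c <= cfg.ny + w:
                warnings.warn(f"fiber at column {c:.1f} is entirely outside "
                              "the frame", stacklevel=2)
            # signed distance of each pixel to the (slightly tilted) fiber axis
            dist = gy - (c + math.tan(math.radians(ang)) * (gx - cfg.nx / 2))
            if cfg.boundary == "periodic":
                dist = (dist + cfg.ny / 2) % cfg.ny - cfg.ny / 2
            acc -= depth * np.exp(-dist ** 2 / (2 * w * w))
        frames[t] = acc
    return _finish(frames, cfg, rng)


def simulate_scene(config: SceneConfig) -> tuple[VideoBlock, VideoBlock]:
    """Dispatch on ``config.kind``; returns (clean, noisy)."""
    if config.kind == "lattice":
        return lattice_video(config)
    return fiber_video(config)


def random_scene_config(kind: str, b: int, nx: int, ny: int,
                        rng: np.random.Generator, *,
                        dose: float = 200.0,
                        gaussian_sigma: float = 0.01) -> SceneConfig:
    """Draw a randomized scene of the given family, for training diversity.

    Lattice spacings span 4-8 px with arbitrary orientation; drift magnitude
    spans 0.1-0.8 px/frame, inside the coherence regime the recurrent
    decoder presumes.
    """
    seed = int(rng.integers(0, 2 ** 31 - 1))
    speed = rng.uniform(0.1, 0.8)
    ang = rng.uniform(0.0, 2 * math.pi)
    drift = (speed * math.cos(ang), speed * math.sin(ang))
    if kind == "lattice":
        n_freq = int(rng.integers(1, 3))
        return SceneConfig(
            kind="lattice", b=b, nx=nx, ny=ny, seed=seed, drift=drift,
            spacings=tuple(rng.uniform(4.0, 8.0, size=n_freq)),
            orientations=tuple(rng.uniform(0.0, 180.0, size=n_freq)),
            amplitudes=tuple(rng.uniform(0.08, 0.22, size=n_freq)),
            background=float(rng.uniform(0.4, 0.6)),
            dose=dose, gaussian_sigma=gaussian_sigma)
    n_fib = int(rng.integers(1, 4))
    return SceneConfig(
        kind="fibers", b=b, nx=nx, ny=ny, seed=seed, drift=drift,
        fiber_positions=tuple(rng.uniform(0.0, ny, size=n_fib)),
        fiber_widths=tuple(rng.uniform(1.5, 5.0, size=n_fib)),
        fiber_depths=tuple(rng.uniform(0.2, 0.5, size=n_fib)),
        fiber_velocities=tuple(rng.uniform(-0.8, 0.8, size=n_fib)),
        fiber_angles=tuple(rng.uniform(-10.0, 10.0, size=n_fib)),
        fiber_background=float(rng.uniform(0.7, 0.9)),
        dose=dose, gaussian_sigma=gaussian_sigma)
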