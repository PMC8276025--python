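"""Supervised training of the decoder on coded measurements of video clips.

Each training example pairs the coded measurement of a clip with the clip
itself; the masks are drawn once and shared by the whole dataset, matching
deployment where the coding patterns are pre-determined.  The loss
supervises both recurrent branches:

    L = w_f * MSE(forward frames, target) + w_b * MSE(backward frames, target)

computed in normalized intensity units (frames divided by ``pixel_peak``),
which keeps gradient magnitudes O(1) regardless of bit depth.  The same
formula applied to the trivial predictor that outputs the normalized
measurement Ybar for every frame gives the naive reference loss a trained
decoder must undercut.

Training is plain Adam with mini-batches, per-epoch validation on clips
drawn from a disjoint seed stream, optional early stopping on a validation
plateau, and full seed determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coding import (MaskSet, Measurement, VideoBlock, encode,
                     generate_masks, normalize_measurement)
from .errors import DimensionError, TrainingError
from .network import NetConfig, ReconstructionNet, ReconstructionState
from .nn import Adam
from .synthetic import random_scene_config, simulate_scene

__all__ = ["TrainConfig", "LossHistory", "ClipPair", "ClipDataSource",
           "make_training_pair", "loss", "naive_predictor_loss",
           "synthetic_clip_source", "train"]


@dataclass
class TrainConfig:
    """Desk-scale training conditions (sizes, budgets, seeds)."""

    b: int = 4
    clip_size: tuple[int, int] = (32, 32)
    n_train_clips: int = 200
    n_val_clips: int = 32
    batch_size: int = 2
    steps: int = 2000
    learning_rate: float = 1e-3
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)
    base_channels: int = 8
    attention_window: int | None = 16
    mask_density: float = 0.5
    patience: int = 10          # early-stop after this many flat epochs; 0 disables
    dose: float = 200.0
    gaussian_sigma: float = 0.01
    target: str = "clean"       # supervise with clean or noisy frames
    noise_augment: bool = True  # redraw detector noise per training batch

    def __post_init__(self):
        for name in ("b", "n_train_clips", "n_val_clips", "batch_size", "steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.target not in ("clean", "noisy"):
            raise ValueError("target must be 'clean' or 'noisy'")


@dataclass
class LossHistory:
    """Per-step training loss and per-epoch validation loss."""

    steps: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_epochs: list[int] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def rows(self):
        """(step, split, loss) rows for CSV export."""
        for s, l in zip(self.steps, self.train_loss):
            yield s, "train", l
        for s, l in zip(self.val_steps, self.val_loss):
            yield s, "val", l


@dataclass
class ClipPair:
    """A clip to encode (``video``) and the frames that supervise it."""

    video: VideoBlock
    target: VideoBlock


@dataclass
class ClipDataSource:
    train: list[ClipPair]
    val: list[ClipPair]


def make_training_pair(video: VideoBlock, masks: MaskSet
                       ) -> tuple[Measurement, VideoBlock]:
    """(coded measurement, target video); masks are fixed across a dataset."""
    if video.frames.shape != masks.masks.shape:
        raise DimensionError(
            f"video shape {video.frames.shape} != mask shape {masks.masks.shape}")
    return encode(video, masks), video


def loss(state: ReconstructionState, target: VideoBlock,
         weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Weighted forward + backward mean-squared error against the target."""
    tgt = target.frames
    if state.forward_frames.shape != tgt.shape:
        raise DimensionError(
            f"state frames {state.forward_frames.shape} != target {tgt.shape}")
    wf, wb = weights
    mse_f = float(np.mean((state.forward_frames - tgt) ** 2))
    mse_b = float(np.mean((state.backward_frames - tgt) ** 2))
    return wf * mse_f + wb * mse_b


def synthetic_clip_source(config: TrainConfig) -> ClipDataSource:
    """Lattice + fiber clips with Poisson-Gaussian noise.

    Training and validation clips come from child streams of disjoint
    spawn keys of the config seed, so the sets can never overlap.  The
    encoded input is the noisy clip; the supervision target is the clean
    clip unless ``config.target == 'noisy'``.
    """
    nx, ny = config.clip_size

    def make(n_clips: int, stream: int) -> list[ClipPair]:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(config.seed, spawn_key=(stream,))))
        pairs = []
        for i in range(n_clips):
            kind = "lattice" if i % 2 == 0 else "fibers"
            scene = random_scene_config(kind, config.b, nx, ny, rng,
                                        dose=config.dose,
                                        gaussian_sigma=config.gaussian_sigma)
            clean, noisy = simulate_scene(scene)
            pairs.append(ClipPair(video=noisy,
                                  target=clean if config.target == "clean" else noisy))
        return pairs

    return ClipDataSource(train=make(config.n_train_clips, 1),
                          val=make(config.n_val_clips, 2))


def _normalized_inputs(pairs: list[ClipPair], masks: MaskSet):
    """Precompute (yb, ym, tgt) stacks in normalized units for a clip list."""
    ybs, yms, tgts = [], [], []
    for p in pairs:
        m = encode(p.video, masks)
        nm = normalize_measurement(m, masks)
        peak = p.video.pixel_peak
        ybs.append(nm.ybar / peak)
        yms.append(np.asarray(m.y, dtype=np.float32) / peak)
        tgts.append(p.target.frames / peak)
    return (np.stack(ybs).astype(np.float32), np.stack(yms).astype(np.float32),
            np.stack(tgts).astype(np.float32))


def _batched_loss(net: ReconstructionNet, yb, ym, tgt, cmask, weights,
                  batch: int = 8) -> float:
    wf, wb = weights
    total, n = 0.0, yb.shape[0]
    for i in range(0, n, batch):
        out = net._forward_batch(yb[i:i + batch], ym[i:i + batch], cmask,
                                 keep_cache=False)
        t = tgt[i:i + batch]
        total += float(wf * np.sum((out["xf"] - t) ** 2) +
                       wb * np.sum((out["xb"] - t) ** 2)) / t[0].size
    return float(total / n)


def naive_predictor_loss(pairs: list[ClipPair], masks: MaskSet,
                         weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Loss of the predictor that outputs Ybar for every frame (both branches)."""
    yb, _, tgt = _normalized_inputs(pairs, masks)
    wf, wb = weights
    err = (yb[:, None] - tgt) ** 2
    return float((wf + wb) * err.mean())


def train(config: TrainConfig, data_source: ClipDataSource | None = None, *,
          masks: MaskSet | None = None, net_config: NetConfig | None = None,
          init_state: dict | None = None,
          callback=None) -> tuple[ReconstructionNet, MaskSet, LossHistory]:
    """Optimize the decoder; returns (trained net, masks, loss history).

    Fully deterministic under ``config.seed``.  Pass ``init_state`` (a
    weights dict from ``net.state_dict()``) to resume.  ``callback(step,
    loss)`` is invoked every step when given.
    """
    nx, ny = config.clip_size
    if data_source is None:
        data_source = synthetic_clip_source(config)
    if masks is None:
        masks = generate_masks(config.b, nx, ny, seed=config.seed,
                               density=config.mask_density)
    if net_config is None:
        net_config = NetConfig(b=config.b, base_channels=config.base_channels,
                               seed=config.seed + 1,
                               attention_window=config.attention_window)
    net = ReconstructionNet(net_config)
    if init_state is not None:
        net.load_state_dict(init_state)

    yb_tr, ym_tr, tgt_tr = _normalized_inputs(data_source.train, masks)
    yb_va, ym_va, tgt_va = _normalized_inputs(data_source.val, masks)
    cmask = masks.masks.astype(np.float32)
    wf, wb = config.loss_weights

    # per-batch noise augmentation: redraw the detector noise on the clean
    # frames each time a clip is used, so the denoiser generalizes over
    # noise realizations instead of memorizing the fixed draws.  Only
    # meaningful with clean supervision targets; validation clips keep
    # their fixed noise.
    augment = config.noise_augment and config.target == "clean"
    if augment:
        clean_tr = np.stack([p.target.frames / p.target.pixel_peak
                             for p in data_source.train]).astype(np.float32)
        cov = masks.coverage().astype(np.float32)
        inv_cov = np.divide(1.0, cov, out=np.zeros_like(cov), where=cov > 0)

    def _augmented_batch(idx, rng):
        clean = clean_tr[idx]
        if math.isinf(config.dose):
            noisy = clean.copy()
        else:
            noisy = rng.poisson(clean * config.dose).astype(np.float32) / config.dose
        if config.gaussian_sigma > 0:
            noisy += rng.normal(0.0, config.gaussian_sigma,
                                size=noisy.shape).astype(np.float32)
        noisy = np.clip(noisy, 0.0, 1.0)
        ym = np.einsum("bhw,nbhw->nhw", cmask, noisy)
        return ym * inv_cov, ym, tgt_tr[idx]

    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed, spawn_key=(3,))))
    history = LossHistory()
    n_train = yb_tr.shape[0]
    steps_per_epoch = max(1, math.ceil(n_train / config.batch_size))
    order = rng.permutation(n_train)
    pos = 0
    epoch = 0
    best_val = math.inf
    flat_epochs = 0
    for step in range(1, config.steps + 1):
        if pos + config.batch_size > n_train:
            order = rng.permutation(n_train)
            pos = 0
        idx = order[pos:pos + config.batch_size]
        pos += config.batch_size
        if augment:
            yb, ym, tgt = _augmented_batch(idx, rng)
        else:
            yb, ym, tgt = yb_tr[idx], ym_tr[idx], tgt_tr[idx]
        out = net._forward_batch(yb, ym, cmask, keep_cache=True)
        df = out["xf"] - tgt
        db = out["xb"] - tgt
        numel = tgt[0].size * tgt.shape[0]
        batch_loss = float(wf * np.sum(df ** 2) + wb * np.sum(db ** 2)) / numel
        if not math.isfinite(batch_loss):
            raise TrainingError(
                f"non-finite loss at step {step}",
                diagnostics={"step": step, "history": history,
                             "weights": net.state_dict()})
        net.zero_grad()
        net._backward_batch(out, (2.0 * wf / numel) * df, (2.0 * wb / numel) * db)
        opt.step()
        history.steps.append(step)
        history.train_loss.append(batch_loss)
        if callback is not None:
            callback(step, batch_loss)
        if step % steps_per_epoch == 0 or step == config.steps:
            epoch += 1
            val = _batched_loss(net, yb_va, ym_va, tgt_va, cmask,
                                config.loss_weights)
            history.val_epochs.append(epoch)
            history.val_steps.append(step)
            history.val_loss.append(val)
            if val < best_val - 1e-7:
                best_val = val
                flat_epochs = 0
            else:
                flat_epochs += 1
            if config.patience and flat_epochs >= config.patience:
                break
    return net, masks, history
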