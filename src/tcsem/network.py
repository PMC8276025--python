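"""Recurrent decoder for snapshot-compressed video.

The decoder estimates the B frames hidden in one coded measurement Y given
the masks C_1..C_B.  Its three stages mirror the encoding physics:

1. A 12-unit CNN maps the stack (Ybar, Ybar*C_1, ..., Ybar*C_B) to the
   first frame estimate.  The census is two four-layer convolutional
   stages, one three-layer residual block, and one self-attention block.
2. A forward RNN produces frames 2..B in time order.  The cell for frame k
   sees the previous estimate, a two-channel residual input
   (Ybar, Y - sum_{t<k} C_t*Xhat_t^f - sum_{t>k} C_t*Ybar), and the
   previous hidden state (zero before the first cell).
3. A backward RNN of identical structure but independent parameters
   refines frames in reverse order, with residual
   (Ybar, Y - sum_{t!=k} C_t*Xhat_t^f) and hidden chain initialized from
   the forward chain's last hidden state.  Its outputs are the final
   reconstruction.

When every estimate entering a residual is exact, the residual collapses
to the true coded frame C_k*X_k — the telescoping identity that makes the
two-channel input informative.

The forward pass keeps per-layer caches so training can run
backpropagation through time with the hand-written gradients in
:mod:`tcsem.nn`; inference simply discards them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .coding import (MaskSet, Measurement, NormalizedMeasurement, VideoBlock,
                     approx_coded_frames, normalize_measurement)
from .errors import ConfigurationError, DimensionError, StateError

__all__ = [
    "NetConfig", "ResidualInput", "ReconstructionState", "ReconstructionNet",
    "build_cnn_input", "forward_residual_input", "backward_residual_input",
]


@dataclass
class NetConfig:
    """Architecture hyper-parameters; B must match the masks in use."""

    b: int
    base_channels: int = 64
    kernel_size: int = 3
    attention_heads: int = 1
    nonlinearity: str = "relu"
    seed: int = 0
    attention_window: int | None = None

    def __post_init__(self):
        if self.b < 1:
            raise ConfigurationError("B must be >= 1")
        if self.base_channels < 8:
            raise ConfigurationError("base_channels must be >= 8")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd")
        if self.attention_heads != 1:
            raise ConfigurationError("only single-head attention is implemented")
        if self.nonlinearity.lower() != "relu":
            raise ConfigurationError("only ReLU nonlinearity is implemented")

    def to_dict(self) -> dict:
        return {"b": self.b, "base_channels": self.base_channels,
                "kernel_size": self.kernel_size,
                "attention_heads": self.attention_heads,
                "nonlinearity": self.nonlinearity, "seed": self.seed,
                "attention_window": self.attention_window}

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        return cls(**d)


@dataclass
class ResidualInput:
    """Two channels: Ybar and a measurement residual, stacked depth-wise."""

    xbb: np.ndarray  # (2, Nx, Ny); channel 0 is Ybar exactly

    @property
    def ybar(self) -> np.ndarray:
        return self.xbb[0]

    @property
    def residual(self) -> np.ndarray:
        return self.xbb[1]


@dataclass
class ReconstructionState:
    """Per-frame estimates and hidden units from both recurrent passes.

    ``forward_hidden[k]`` is the hidden state after the cell that produced
    frame k (index 0 holds the zero initial state, since frame 0 comes from
    the CNN); ``backward_hidden[k]`` likewise for the backward chain.
    """

    forward_frames: np.ndarray   # (B, Nx, Ny)
    backward_frames: np.ndarray  # (B, Nx, Ny)
    forward_hidden: np.ndarray   # (B, C, Nx, Ny)
    backward_hidden: np.ndarray  # (B, C, Nx, Ny)


def build_cnn_input(nm: NormalizedMeasurement, masks: MaskSet) -> np.ndarray:
    """Stack (Ybar, Ybar*C_1, ..., Ybar*C_B): the first-frame CNN's input."""
    if nm.ybar.shape != masks.frame_shape:
        raise DimensionError(
            f"ybar shape {nm.ybar.shape} != mask frame shape {masks.frame_shape}")
    return np.concatenate([nm.ybar[None], approx_coded_frames(nm, masks)], axis=0)


def forward_residual_input(k: int, m: Measurement, nm: NormalizedMeasurement,
                           masks: MaskSet,
                           prior_frames: np.ndarray) -> ResidualInput:
    """Residual input of forward cell k (1-based).

    residual = Y - sum_{t<k} C_t*Xhat_t^f - sum_{t>k} C_t*Ybar.  Frames not
    yet estimated are stood in for by Ybar, so with perfect priors on a
    constant scene the residual equals the true coded frame C_k*X_k.
    """
    b = masks.b
    if not 1 <= k <= b:
        raise StateError(f"frame index k={k} outside 1..{b}")
    prior_frames = np.asarray(prior_frames, dtype=np.float32)
    if len(prior_frames) != k - 1:
        raise StateError(f"expected {k - 1} prior frames, got {len(prior_frames)}")
    c = masks.masks.astype(np.float32)
    res = np.asarray(m.y, dtype=np.float32).copy()
    for t in range(k - 1):
        res -= c[t] * prior_frames[t]
    for t in range(k, b):
        res -= c[t] * nm.ybar
    return ResidualInput(xbb=np.stack([nm.ybar, res]))


def backward_residual_input(k: int, m: Measurement, nm: NormalizedMeasurement,
                            masks: MaskSet,
                            forward_frames: np.ndarray) -> ResidualInput:
    """Residual input of backward cell k (1-based).

    residual = Y - sum_{t!=k} C_t*Xhat_t^f, using the full forward pass.
    """
    b = masks.b
    if not 1 <= k <= b:
        raise StateError(f"frame index k={k} outside 1..{b}")
    forward_frames = np.asarray(forward_frames, dtype=np.float32)
    if len(forward_frames) != b:
        raise StateError(f"backward residual needs all {b} forward frames, "
                         f"got {len(forward_frames)}")
    c = masks.masks.astype(np.float32)
    coded = c * forward_frames
    res = np.asarray(m.y, dtype=np.float32) - coded.sum(axis=0) + coded[k - 1]
    return ResidualInput(xbb=np.stack([nm.ybar, res]))


class _FirstFrameCNN(nn.Module):
    """Two four-layer conv stages, a residual block and an attention block."""

    def __init__(self, b: int, c: int, k: int, *, rng, window, dtype):
        def conv(ci, co, name, kk=k):
            return nn.Conv2d(ci, co, kk, rng=rng, name=name, dtype=dtype)
        self.stage1 = nn.Sequential(
            conv(b + 1, c, "cnn.s1.0"), nn.ReLU(),
            conv(c, c, "cnn.s1.1"), nn.ReLU(),
            conv(c, c, "cnn.s1.2"), nn.ReLU(),
            conv(c, c, "cnn.s1.3"), nn.ReLU())
        self.res = nn.ResidualBlock(c, k, rng=rng, name="cnn.res", dtype=dtype)
        self.attn = nn.SelfAttention2d(c, rng=rng, window=window,
                                       name="cnn.attn", dtype=dtype)
        self.stage2 = nn.Sequential(
            conv(c, c, "cnn.s2.0"), nn.ReLU(),
            conv(c, c, "cnn.s2.1"), nn.ReLU(),
            conv(c, c, "cnn.s2.2"), nn.ReLU(),
            nn.Conv2d(c, 1, k, rng=rng, name="cnn.s2.3", dtype=dtype,
                      zero_init=True))

    def layer_census(self) -> list[tuple[str, int]]:
        """(unit kind, layer count) in execution order; counts sum to 12."""
        return [("four_layer_cnn", 4), ("residual_block", 3),
                ("self_attention", 1), ("four_layer_cnn", 4)]

    def forward(self, x):
        # the head predicts a correction to the Ybar anchor (channel 0)
        h, c1 = self.stage1.forward(x)
        h, c2 = self.res.forward(h)
        h, c3 = self.attn.forward(h)
        h, c4 = self.stage2.forward(h)
        return x[:, :1] + h, (c1, c2, c3, c4)

    def backward(self, cache, dy):
        c1, c2, c3, c4 = cache
        d = self.stage2.backward(c4, dy)
        d = self.attn.backward(c3, d)
        d = self.res.backward(c2, d)
        dx = self.stage1.backward(c1, d)
        dx[:, :1] += dy
        return dx


class _RNNCell(nn.Module):
    """One recurrent cell: three input sub-CNNs, fusion, two residual
    blocks producing the new hidden unit, and an output sub-CNN.

    The fusion convolution brings the concatenated 3C feature stack back to
    C channels so the hidden state width stays ``base_channels``.
    """

    def __init__(self, c: int, k: int, *, rng, name: str, dtype):
        def conv(ci, co, tag, kk=k):
            return nn.Conv2d(ci, co, kk, rng=rng, name=f"{name}.{tag}", dtype=dtype)
        self.sub_first = nn.Sequential(conv(1, c, "first.0"), nn.ReLU(),
                                       conv(c, c, "first.1"), nn.ReLU())
        self.sub_res = nn.Sequential(conv(2, c, "res.0"), nn.ReLU(),
                                     conv(c, c, "res.1"), nn.ReLU())
        self.sub_hidden = nn.Sequential(conv(c, c, "hid.0"), nn.ReLU(),
                                        conv(c, c, "hid.1"), nn.ReLU())
        self.fuse = nn.Sequential(conv(3 * c, c, "fuse"), nn.ReLU())
        self.block1 = nn.ResidualBlock(c, k, rng=rng, name=f"{name}.block1", dtype=dtype)
        self.block2 = nn.ResidualBlock(c, k, rng=rng, name=f"{name}.block2", dtype=dtype)
        self.out = nn.Sequential(conv(c, c, "out.0"), nn.ReLU(),
                                 nn.Conv2d(c, 1, k, rng=rng,
                                           name=f"{name}.out.1", dtype=dtype,
                                           zero_init=True))
        self._c = c

    def forward(self, first, resin, hidden):
        # the output head predicts a correction to the first-part estimate
        a, ca = self.sub_first.forward(first)
        b, cb = self.sub_res.forward(resin)
        h, ch = self.sub_hidden.forward(hidden)
        z = np.concatenate([a, b, h], axis=1)
        f, cf = self.fuse.forward(z)
        r1, cr1 = self.block1.forward(f)
        new_hidden, cr2 = self.block2.forward(r1)
        delta, co = self.out.forward(new_hidden)
        return first + delta, new_hidden, (ca, cb, ch, cf, cr1, cr2, co)

    def backward(self, cache, dframe, dhidden):
        ca, cb, ch, cf, cr1, cr2, co = cache
        dnh = self.out.backward(co, dframe)
        if dhidden is not None:
            dnh = dnh + dhidden
        dr1 = self.block2.backward(cr2, dnh)
        df = self.block1.backward(cr1, dr1)
        dz = self.fuse.backward(cf, df)
        c = self._c
        dfirst = self.sub_first.backward(ca, dz[:, :c]) + dframe
        dresin = self.sub_res.backward(cb, dz[:, c:2 * c])
        dhid = self.sub_hidden.backward(ch, dz[:, 2 * c:])
        return dfirst, dresin, dhid


class ReconstructionNet(nn.Module):
    """The full decoder: a pure function of (measurement, masks, weights)."""

    def __init__(self, config: NetConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        c, k = config.base_channels, config.kernel_size
        self.cnn = _FirstFrameCNN(config.b, c, k, rng=rng,
                                  window=config.attention_window, dtype=dtype)
        self.fcell = _RNNCell(c, k, rng=rng, name="fwd", dtype=dtype)
        self.bcell = _RNNCell(c, k, rng=rng, name="bwd", dtype=dtype)

    # -- spec-level operations -------------------------------------------

    def cnn_first_frame(self, stack: np.ndarray) -> np.ndarray:
        """First frame estimate from the (B+1)-channel input stack."""
        if stack.shape[0] != self.config.b + 1:
            raise ConfigurationError(
                f"expected {self.config.b + 1} channels, got {stack.shape[0]}")
        out, _ = self.cnn.forward(stack[None].astype(self.dtype))
        return out[0, 0]

    def rnn_cell(self, first: np.ndarray, residual: ResidualInput,
                 hidden: np.ndarray, direction: str = "forward"):
        """Apply one recurrent cell; returns (frame, new_hidden)."""
        cell = {"forward": self.fcell, "backward": self.bcell}[direction]
        c = self.config.base_channels
        if hidden.shape[0] != c or hidden.shape[-2:] != first.shape:
            raise ConfigurationError(
                f"hidden must be ({c}, Nx, Ny) matching the frame; got "
                f"{hidden.shape} vs frame {first.shape}")
        frame, new_hidden, _ = cell.forward(
            first[None, None].astype(self.dtype),
            residual.xbb[None].astype(self.dtype),
            hidden[None].astype(self.dtype))
        return frame[0, 0], new_hidden[0]

    def reconstruct(self, m: Measurement, masks: MaskSet
                    ) -> tuple[VideoBlock, ReconstructionState]:
        """Decode a measurement into B frames (backward-pass output)."""
        if masks.b != self.config.b:
            raise ConfigurationError(
                f"network was built for B={self.config.b}, masks have B={masks.b}")
        nm = normalize_measurement(m, masks)
        peak = float(m.pixel_peak)
        yb = (nm.ybar / peak)[None].astype(self.dtype)
        ym = (np.asarray(m.y, dtype=self.dtype) / peak)[None]
        cmask = masks.masks.astype(self.dtype)
        out = self._forward_batch(yb, ym, cmask, keep_cache=False)
        xb = np.clip(out["xb"][0] * peak, 0.0, None).astype(np.float32)
        state = ReconstructionState(
            forward_frames=(out["xf"][0] * peak).astype(np.float32),
            backward_frames=xb,
            forward_hidden=out["hf"][:, 0].astype(np.float32),
            backward_hidden=out["hb"][:, 0].astype(np.float32),
        )
        return VideoBlock(frames=xb, pixel_peak=peak), state

    # -- batched forward / backward for training -------------------------

    def _forward_batch(self, yb, ym, cmask, keep_cache):
        """Run the unrolled decoder on a batch.

        yb, ym: (N, H, W) in normalized units; cmask: (B, H, W) float.
        Returns frame stacks (N, B, H, W), hidden stacks (B, N, C, H, W)
        and, when ``keep_cache``, everything the BPTT pass needs.
        """
        n, h, w = yb.shape
        b = cmask.shape[0]
        cexp = cmask[None]                       # broadcast over batch
        stack = np.concatenate([yb[:, None], yb[:, None] * cexp], axis=1)
        x1, cache_cnn = self.cnn.forward(stack.astype(self.dtype))
        xf = [x1[:, 0]]
        cch = self.config.base_channels
        hidden = np.zeros((n, cch, h, w), dtype=self.dtype)
        hf_list, cache_f = [], []
        cov_yb = cmask.sum(axis=0)[None] * yb    # sum_t C_t * Ybar
        prefix = np.zeros_like(yb)               # sum_{t<k} C_t * xf_t
        cum_cyb = np.zeros_like(yb)              # sum_{t<=k} C_t * Ybar
        for k in range(1, b):
            prefix = prefix + cmask[k - 1] * xf[k - 1]
            cum_cyb = cum_cyb + cmask[k - 1] * yb
            suffix = cov_yb - cum_cyb - cmask[k] * yb
            res = ym - prefix - suffix
            resin = np.stack([yb, res], axis=1)
            frame, hidden, cache = self.fcell.forward(
                xf[k - 1][:, None], resin.astype(self.dtype), hidden)
            xf.append(frame[:, 0])
            hf_list.append(hidden)
            cache_f.append(cache if keep_cache else None)
        xf_arr = np.stack(xf, axis=1)            # (N, B, H, W)
        total = np.einsum("bhw,nbhw->nhw", cmask, xf_arr)
        xb = [None] * b
        hb_list = [None] * b
        cache_b = [None] * b
        for k in range(b - 1, -1, -1):
            res = ym - total + cmask[k] * xf_arr[:, k]
            resin = np.stack([yb, res], axis=1)
            first = xf_arr[:, b - 1] if k == b - 1 else xb[k + 1]
            frame, hidden, cache = self.bcell.forward(
                first[:, None], resin.astype(self.dtype), hidden)
            xb[k] = frame[:, 0]
            hb_list[k] = hidden
            cache_b[k] = cache if keep_cache else None
        hf_full = np.stack([np.zeros_like(hidden)] + hf_list, axis=0)
        out = {"xf": xf_arr, "xb": np.stack(xb, axis=1),
               "hf": hf_full, "hb": np.stack(hb_list, axis=0)}
        if keep_cache:
            out["caches"] = (cache_cnn, cache_f, cache_b, cmask)
        return out

    def _backward_batch(self, out, dxf_loss, dxb_loss):
        """Backpropagation through time; accumulates parameter gradients."""
        cache_cnn, cache_f, cache_b, cmask = out["caches"]
        b = cmask.shape[0]
        dxf = dxf_loss.copy()                    # (N, B, H, W)
        pending_first = None
        pending_hidden = None
        # backward cells were executed k = B-1 .. 0; reverse that order
        for k in range(b):
            dframe = dxb_loss[:, k]
            if pending_first is not None:
                dframe = dframe + pending_first
            dfirst, dresin, dhid = self.bcell.backward(
                cache_b[k], dframe[:, None], pending_hidden)
            dres = dresin[:, 1]
            # residual = ym - sum_{t != k} C_t * xf_t
            dxf -= cmask[None] * dres[:, None]
            dxf[:, k] += cmask[k] * dres
            pending_first, pending_hidden = dfirst[:, 0], dhid
        dxf[:, b - 1] += pending_first           # first input of cell k=B-1
        dh_next = pending_hidden                 # grad on h_B^f
        for k in range(b - 1, 0, -1):
            dfirst, dresin, dhid = self.fcell.backward(
                cache_f[k - 1], dxf[:, k][:, None], dh_next)
            dres = dresin[:, 1]
            # residual = ym - sum_{t<k} C_t*xf_t - sum_{t>k} C_t*yb
            dxf[:, :k] -= cmask[None, :k] * dres[:, None]
            dxf[:, k - 1] += dfirst[:, 0]
            dh_next = dhid
        # h_1^f is the zero constant; its gradient is dropped
        self.cnn.backward(cache_cnn, dxf[:, 0][:, None])

    # -- weight (de)serialization ----------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {p.name: p for p in self.params()}
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ConfigurationError(f"weight name mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ConfigurationError(
                    f"{name}: checkpoint shape {arr.shape} != {p.data.shape}")
            p.data[...] = arr
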