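"""Readers and writers for the pipeline's artifacts.

Grayscale multipage TIFF is the primary video format; a minimal MRC2014
stack reader covers the EM ecosystem (modes 0, 1, 2 and 6).  Every derived
artifact (mask archive, measurement, checkpoint) carries provenance — the
seeds and shapes needed to detect mask/measurement pairing mistakes, which
are the dominant failure mode of mask-coded compression.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import tifffile

from .coding import MaskSet, Measurement, VideoBlock
from .errors import FormatError, ProvenanceError
from .network import NetConfig, ReconstructionNet

__all__ = ["read_stack", "write_stack", "read_mrc", "write_mrc",
           "save_masks", "load_masks", "export_masks_tiff",
           "save_measurement", "load_measurement",
           "save_checkpoint", "load_checkpoint"]

_PEAK_BY_DTYPE = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0,
                  np.dtype(np.int8): 127.0, np.dtype(np.int16): 32767.0}


def _peak_for(arr: np.ndarray, default: float = 255.0) -> float:
    return _PEAK_BY_DTYPE.get(arr.dtype, default)


def read_stack(path: str | Path) -> VideoBlock:
    """Read a grayscale multipage TIFF (or .mrc) stack, pages in order.

    The bit depth sets ``pixel_peak`` (255 for 8-bit, 65535 for 16-bit);
    values are not rescaled.
    """
    path = Path(path)
    if path.suffix.lower() in (".mrc", ".mrcs", ".map"):
        return read_mrc(path)
    try:
        with tifffile.TiffFile(path) as tf:
            photometric = tf.pages[0].photometric
            if photometric not in (tifffile.PHOTOMETRIC.MINISBLACK,
                                   tifffile.PHOTOMETRIC.MINISWHITE):
                raise FormatError(
                    f"{path}: unsupported photometric dialect "
                    f"{photometric.name} (grayscale TIFF required)")
            arr = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - dialect-specific
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale stack, got shape {arr.shape} "
            "(color TIFF dialects are not supported)")
    peak = _peak_for(arr)
    return VideoBlock(frames=arr.astype(np.float32), pixel_peak=peak)


def write_stack(path: str | Path, video: VideoBlock,
                dtype: str = "uint16") -> None:
    """Write frames as a grayscale multipage TIFF in the requested dtype."""
    dt = np.dtype(dtype)
    if dt in _PEAK_BY_DTYPE:
        peak_out = _PEAK_BY_DTYPE[dt]
        arr = np.clip(np.round(video.frames / video.pixel_peak * peak_out),
                      0, peak_out).astype(dt)
    else:
        arr = video.frames.astype(dt)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


# -- minimal MRC2014 stack support --------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path: str | Path) -> VideoBlock:
    """Read an MRC2014 image stack (modes 0/1/2/6 only)."""
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: truncated MRC header")
    nx, ny, nz, mode = struct.unpack("<4i", raw[:16])
    (nsymbt,) = struct.unpack("<i", raw[92:96])
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")
    dt = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dt, count=count, offset=1024 + nsymbt)
    frames = data.reshape(nz, ny, nx).astype(np.float32)
    if frames.min() < 0:  # signed EM counts: shift into the non-negative range
        frames = frames - frames.min()
    return VideoBlock(frames=frames, pixel_peak=_peak_for(np.empty(0, dt)))


def write_mrc(path: str | Path, video: VideoBlock) -> None:
    """Write a float32 MRC2014 stack (mode 2)."""
    frames = video.frames.astype("<f4")
    nz, ny, nx = frames.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, float(nx), float(ny), float(nz))
    struct.pack_into("<3i", header, 64, 1, 2, 3)     # axis order
    struct.pack_into("<3f", header, 76, float(frames.min()),
                     float(frames.max()), float(frames.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"            # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(frames.tobytes())


# -- mask archive --------------------------------------------------------

def save_masks(path: str | Path, masks: MaskSet) -> None:
    """Archive: B bilevel planes plus a JSON header in one .npz file."""
    header = json.dumps({"b": masks.b, "nx": masks.frame_shape[0],
                         "ny": masks.frame_shape[1], "seed": masks.seed,
                         "density": masks.density})
    np.savez(Path(path), masks=np.packbits(masks.masks.astype(np.uint8), axis=-1),
             header=np.frombuffer(header.encode(), dtype=np.uint8))


def load_masks(path: str | Path) -> MaskSet:
    with np.load(Path(path)) as z:
        header = json.loads(bytes(z["header"]).decode())
        planes = np.unpackbits(z["masks"], axis=-1,
                               count=header["ny"])[:, :header["nx"], :]
    return MaskSet(masks=planes.astype(np.uint8), seed=header["seed"],
                   density=header["density"])


def export_masks_tiff(path: str | Path, masks: MaskSet) -> None:
    """Bilevel multipage TIFF view of the mask planes (0 / 255)."""
    tifffile.imwrite(Path(path), (masks.masks * 255).astype(np.uint8),
                     photometric="minisblack")


# -- measurement ---------------------------------------------------------

def save_measurement(path: str | Path, m: Measurement) -> None:
    """Single-page 32-bit TIFF plus a JSON provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(m.y, dtype=np.float32),
                     photometric="minisblack")
    sidecar = {"b": int(m.b_used), "mask_seed": int(m.mask_seed),
               "pixel_peak": float(m.pixel_peak)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_measurement(path: str | Path) -> Measurement:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ProvenanceError(f"measurement sidecar {sidecar_path} is missing")
    sidecar = json.loads(sidecar_path.read_text())
    y = tifffile.imread(path)
    return Measurement(y=np.asarray(y, dtype=np.float32), b_used=sidecar["b"],
                       mask_seed=sidecar["mask_seed"],
                       pixel_peak=sidecar["pixel_peak"])


# -- weights checkpoint --------------------------------------------------

_CHECKPOINT_SCHEMA = 1


def save_checkpoint(path: str | Path, net: ReconstructionNet,
                    extra: dict | None = None) -> None:
    """Config JSON + named weight tensors in one .npz archive."""
    meta = {"schema": _CHECKPOINT_SCHEMA, "config": net.config.to_dict(),
            "extra": extra or {}}
    meta_json = json.dumps(meta, default=float)
    arrays = {"weight/" + k: v for k, v in net.state_dict().items()}
    np.savez(Path(path), meta=np.frombuffer(meta_json.encode(),
                                            dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ReconstructionNet:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("schema") != _CHECKPOINT_SCHEMA:
            raise FormatError(f"unsupported checkpoint schema {meta.get('schema')}")
        state = {k[len("weight/"):]: z[k] for k in z.files
                 if k.startswith("weight/")}
    net = ReconstructionNet(NetConfig.from_dict(meta["config"]))
    net.load_state_dict(state)
    return net
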