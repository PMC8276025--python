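"""End-to-end orchestration: simulate -> genmasks -> encode -> train -> decode -> evaluate.

A run is described by one YAML mapping (see :func:`load_run_config`).  Every
artifact written gets a JSON provenance sidecar carrying the configuration
hash and the seeds that produced it; the decode stage refuses measurements
whose recorded mask seed does not match the mask archive.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tio
from .coding import encode, generate_masks, normalize_measurement
from .errors import ProvenanceError, TcsemError
from .evaluation import (evaluate_reconstruction, jpeg_rate_matched,
                         naive_baseline)
from .network import NetConfig
from .synthetic import SceneConfig, simulate_scene
from .training import TrainConfig, train

__all__ = ["RunConfig", "load_run_config", "run_pipeline"]

log = logging.getLogger("tcsem")


@dataclass
class RunConfig:
    """Validated pipeline configuration; B is consistent across sub-configs."""

    seed: int = 0
    b: int = 4
    workdir: Path = Path("tcsem_run")
    scene: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)
    net: dict = field(default_factory=dict)
    train: dict | None = None
    weights: str | None = None
    evaluate: dict = field(default_factory=lambda: {"jpeg": True})
    log_level: str = "INFO"

    def __post_init__(self):
        self.workdir = Path(self.workdir)
        for sub in (self.scene, self.net, self.train or {}):
            if "b" in sub and sub["b"] != self.b:
                raise TcsemError(
                    f"inconsistent B: top-level {self.b} vs sub-config {sub['b']}")

    def config_hash(self) -> str:
        blob = json.dumps({k: str(v) for k, v in self.__dict__.items()},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sidecar(path: Path, cfg: RunConfig, stage: str, **extra) -> None:
    from . import __version__
    payload = {"stage": stage, "config_hash": cfg.config_hash(),
               "seed": cfg.seed, "version": __version__, **extra}
    Path(str(path) + ".prov.json").write_text(json.dumps(payload, indent=1, default=float))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages; returns a dict of artifact paths.

    Raises on stage failure after logging the stage name; artifacts written
    so far are left in place for inspection.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    wd = cfg.workdir
    wd.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        scene = SceneConfig(b=cfg.b, seed=cfg.seed, **cfg.scene)
        clean, noisy = simulate_scene(scene)
        artifacts["clean"] = wd / "clean.tif"
        artifacts["noisy"] = wd / "noisy.tif"
        tio.write_stack(artifacts["clean"], clean, dtype="uint16")
        tio.write_stack(artifacts["noisy"], noisy, dtype="uint16")
        _sidecar(artifacts["noisy"], cfg, stage, kind=scene.kind)
        log.info("simulate: %d frames of %dx%d (%s)", cfg.b, scene.nx,
                 scene.ny, scene.kind)

        stage = "genmasks"
        masks = generate_masks(cfg.b, scene.nx, scene.ny, seed=cfg.seed,
                               **cfg.masks)
        artifacts["masks"] = wd / "masks.npz"
        tio.save_masks(artifacts["masks"], masks)
        _sidecar(artifacts["masks"], cfg, stage, mask_seed=masks.seed)

        stage = "encode"
        m = encode(noisy, masks)
        artifacts["measurement"] = wd / "measurement.tif"
        tio.save_measurement(artifacts["measurement"], m)
        _sidecar(artifacts["measurement"], cfg, stage, mask_seed=m.mask_seed)
        log.info("encode: B=%d frames -> one %s measurement", cfg.b,
                 m.y.shape)

        stage = "train"
        if cfg.train is not None:
            tcfg = TrainConfig(b=cfg.b, clip_size=(scene.nx, scene.ny),
                               seed=cfg.seed, **cfg.train)
            net_cfg = NetConfig(b=cfg.b, seed=cfg.seed + 1, **cfg.net) \
                if cfg.net else None
            net, _, history = train(tcfg, masks=masks, net_config=net_cfg)
            artifacts["weights"] = wd / "weights.npz"
            tio.save_checkpoint(artifacts["weights"], net,
                                extra={"final_val_loss": history.val_loss[-1]})
            artifacts["history"] = wd / "history.csv"
            with open(artifacts["history"], "w") as fh:
                fh.write("step,split,loss\n")
                for s, split, l in history.rows():
                    fh.write(f"{s},{split},{l}\n")
            _sidecar(artifacts["weights"], cfg, stage)
            log.info("train: %d steps, final val loss %.5f",
                     history.steps[-1], history.val_loss[-1])
        elif cfg.weights:
            net = tio.load_checkpoint(cfg.weights)
        else:
            log.info("no training requested and no weights given; stopping "
                     "after encode")
            return artifacts

        stage = "decode"
        m_loaded = tio.load_measurement(artifacts["measurement"])
        if m_loaded.mask_seed != masks.seed:
            raise ProvenanceError(
                f"measurement sidecar mask_seed {m_loaded.mask_seed} does not "
                f"match mask archive seed {masks.seed}")
        recon, _ = net.reconstruct(m_loaded, masks)
        artifacts["recon"] = wd / "recon.tif"
        tio.write_stack(artifacts["recon"], recon, dtype="uint16")
        _sidecar(artifacts["recon"], cfg, stage)

        stage = "evaluate"
        reports = [evaluate_reconstruction(clean, recon, method="tcs-dl",
                                           b=cfg.b)]
        nm = normalize_measurement(m_loaded, masks)
        reports.append(evaluate_reconstruction(
            clean, naive_baseline(nm, cfg.b), method="naive", b=cfg.b))
        if cfg.evaluate.get("jpeg", True):
            jr = jpeg_rate_matched(noisy, cfg.b)
            reports.append(evaluate_reconstruction(
                clean, jr.video, method="jpeg", b=cfg.b,
                bytes_compressed=jr.total_bytes))
        artifacts["report"] = wd / "report.json"
        artifacts["report"].write_text(json.dumps(
            {r.method: r.to_dict() for r in reports}, indent=1, default=float))
        for r in reports:
            log.info("evaluate[%s]: PSNR %.2f dB, SSIM %.4f", r.method,
                     r.mean_psnr, r.mean_ssim)
        return artifacts
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise
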