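"""Shared fixtures.

The two trained-decoder fixtures run real desk-scale optimizations (several
minutes each) and are session-scoped so every test that needs a trained
model shares one run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tcsem.coding import MaskSet, VideoBlock, encode, normalize_measurement
from tcsem.training import TrainConfig, train

# scene-composition and coverage warnings are expected at desk scale
warnings.filterwarnings("ignore", message=".*zero mask coverage.*")
warnings.filterwarnings("ignore", message=".*negative intensities.*")


@pytest.fixture
def worked_example():
    """The 2x2, B=2 block whose measurement can be checked by hand."""
    frames = np.array([[[1, 2], [3, 4]], [[5, 6], [7, 8]]], dtype=np.float32)
    planes = np.array([[[1, 0], [1, 1]], [[0, 1], [1, 0]]], dtype=np.uint8)
    video = VideoBlock(frames=frames, pixel_peak=255.0)
    masks = MaskSet(masks=planes, seed=7)
    m = encode(video, masks)
    nm = normalize_measurement(m, masks)
    return video, masks, m, nm


@pytest.fixture(scope="session")
def trained_b4():
    """Decoder trained at the B=4 desk-scale study conditions."""
    cfg = TrainConfig(b=4, clip_size=(32, 32), n_train_clips=200,
                      n_val_clips=32, batch_size=2, steps=2000, seed=0)
    net, masks, history = train(cfg)
    return cfg, net, masks, history


@pytest.fixture(scope="session")
def trained_b8():
    """Decoder trained at B=8 (same scenes, double compression)."""
    cfg = TrainConfig(b=8, clip_size=(32, 32), n_train_clips=200,
                      n_val_clips=32, batch_size=2, steps=1200, seed=0)
    net, masks, history = train(cfg)
    return cfg, net, masks, history
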