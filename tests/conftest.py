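"""Shared fixtures.

The desk-scale training runs are expensive (minutes each), so they are
session-scoped and shared between the training-behaviour tests and the
end-to-end recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from actin2nucleus.nn.model import ModelConfig
from actin2nucleus.nn.train import train
from actin2nucleus.synthetic import RenderConfig, generate_tiles

DESK_PX = 64
DESK_PIXEL_UM = 0.8203125          # 52.5 um tile at 64 px
DESK_CELLS = 3
TRAIN_TILES = 300
TEST_TILES = 40
TRAIN_ITERATIONS = 1200
ALPHA_CMP_ITERATIONS = 400


def desk_render(noise: str) -> RenderConfig:
    return RenderConfig(psf_sigma_px=0.8, noise_model=noise,
                        noise_sigma=0.01)


@pytest.fixture(scope="session")
def desk_train_tiles():
    return generate_tiles(TRAIN_TILES, n_cells=DESK_CELLS,
                          image_size_px=DESK_PX, pixel_size_um=DESK_PIXEL_UM,
                          render_cfg=desk_render("gaussian"), seed=11)


@pytest.fixture(scope="session")
def desk_test_tiles():
    """Noise-free held-out tiles for parameter-recovery evaluation."""
    return generate_tiles(TEST_TILES, n_cells=DESK_CELLS,
                          image_size_px=DESK_PX, pixel_size_um=DESK_PIXEL_UM,
                          render_cfg=desk_render("none"), seed=12)


def _stack(tiles):
    actin = np.stack([t.pair.actin for t in tiles])
    nucleus = np.stack([t.pair.nucleus for t in tiles])
    masks = np.stack([t.nucleus_mask for t in tiles]).astype(np.float32)
    return actin, nucleus, masks


@pytest.fixture(scope="session")
def desk_trained(desk_train_tiles):
    """The main desk-preset training run (alpha = 10)."""
    actin, nucleus, masks = _stack(desk_train_tiles)
    cfg = ModelConfig.from_preset("desk", seed=3,
                                  max_iterations=TRAIN_ITERATIONS)
    return train((actin, nucleus), masks, cfg)


@pytest.fixture(scope="session")
def alpha_comparison(desk_train_tiles):
    """Short equal-iteration runs with alpha=1 vs alpha=10."""
    actin, nucleus, masks = _stack(desk_train_tiles)
    states = {}
    for alpha in (1.0, 10.0):
        cfg = ModelConfig.from_preset(
            "desk", seed=3, alpha=alpha,
            max_iterations=ALPHA_CMP_ITERATIONS)
        states[alpha] = train((actin, nucleus), masks, cfg)
    return states
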