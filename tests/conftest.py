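"""Shared fixtures: synthetic scene sets and one session-scoped trained model.

The training fixture uses the package's desk-scale study conditions:
128x128 easy-preset scenes (8-18 well-separated, high-contrast panicles at
the same pixel scale as the 2.5 mm/px target), a stride-4 feature map and
a 6000-iteration schedule with OHEM K=64 — small enough that the whole
suite runs on one CPU, large enough that the detector reaches its
operating regime.
"""

from __future__ import annotations

import numpy as np
import pytest

from paniclecount import HyperParams, train
from paniclecount.synthetic_field import preset, render_scenes

EASY_SCENE = preset("easy").with_(
    image_size=(128, 128), panicle_count_range=(8, 18), rng_seed=100
)

EASY_HP = HyperParams(
    seed=1,
    iteration_budget=6000,
    verification_period=1000,
    ohem_k=64,
    region_ignore_band=(0.35, 0.5),
    backbone_strides=(2, 2, 1),
    anchor_scales=(10.0, 18.0),
)


@pytest.fixture(scope="session")
def easy_scenes():
    """200 easy scenes; the first 160 train, the last 40 are held out."""
    return render_scenes(EASY_SCENE, 200)


@pytest.fixture(scope="session")
def easy_trained(easy_scenes):
    train_imgs = [s.image for s in easy_scenes[:160]]
    return train(train_imgs, EASY_HP)


@pytest.fixture(scope="session")
def easy_heldout(easy_scenes):
    return easy_scenes[160:]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
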