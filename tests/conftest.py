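"""Shared fixtures: a small imaging geometry and pre-generated movies.

Tests run on 64-px frames (pixel pitch scales with the field of view, so
nothing downstream depends on the full 256-px sensor size); movies are
generated once per session and treated as read-only.
"""

import numpy as np
import pytest

from mesocage import synthetic as syn


@pytest.fixture(scope="session")
def geom64():
    return syn.RigGeometry(frame_px=64, bregma_px=(32, 32))


@pytest.fixture(scope="session")
def scene64(geom64):
    truth, masks = syn.default_scene(geom64)
    return truth, masks


@pytest.fixture(scope="session")
def movie900(geom64, scene64):
    """One 30 s trial (900 frames) with the default study conditions."""
    truth, masks = scene64
    return syn.generate_movie(truth, geom64, duration_s=30.0, seed=7,
                              masks=masks)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
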