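"""Shared fixtures: phantom rasterizations and reconstructions are expensive,
so they are produced once per session at a 0.1 mm raster (the acceptance
checks use the finer 0.05 mm production setting)."""

from __future__ import annotations

import numpy as np
import pytest

import calcisub as cs

RASTER_MM = 0.1
SEED = 20240912


@pytest.fixture(scope="session")
def default_spec() -> cs.PhantomSpec:
    return cs.default_phantom_spec()


@pytest.fixture(scope="session")
def phantom_pair(default_spec):
    """(pre, post, ground truth) high-resolution rasterizations."""
    pre, gt = cs.rasterize(default_spec, "pre", RASTER_MM)
    post, _ = cs.rasterize(default_spec, "post", RASTER_MM)
    return pre, post, gt


@pytest.fixture(scope="session")
def recon_pair(phantom_pair):
    """Pre/post volumes after FOV 100 mm + bone kernel reconstruction emulation."""
    pre, post, gt = phantom_pair
    cond = cs.ReconstructionCondition(100.0, 512, "bone")
    pre_rc = cs.emulate_reconstruction(pre, cond, SEED)
    post_rc = cs.emulate_reconstruction(post, cond, SEED + 1)
    return pre_rc, post_rc, gt


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
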