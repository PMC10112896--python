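"""Shared fixtures: small, fast synthetic-stack specs.

All fixtures are deterministic; stacks are generated at test time (no file
fixtures)."""

import numpy as np
import pytest

from vncquant.synthvnc import NoiseSpec, ScaffoldSpec


def make_small_spec(seed: int = 0, **overrides) -> ScaffoldSpec:
    """Two-neuromere stack, 14 x 15 x 3 µm footprint: fast to render."""
    kwargs = dict(
        n_segments=2,
        segment_pitch=7.0,
        midline_x=7.0,
        civ_tract_offsets=(-3.0, 3.0),
        ciii_tract_offsets=(-5.0, 5.0),
        landmark_tract_offset=4.0,
        dendrite_field_extent=(5.5, 1.0),
        shape=(6, 150, 140),
        puncta_count_per_region={"medial": 0, "lateral": 12},
        seed=seed,
    )
    kwargs.update(overrides)
    return ScaffoldSpec(**kwargs)


NO_NOISE = NoiseSpec(background_level=0.0, background_gradient=0.0,
                     shot_noise=False, read_noise_sd=0.0)


@pytest.fixture
def small_spec() -> ScaffoldSpec:
    return make_small_spec(seed=7)


@pytest.fixture
def noiseless_spec() -> ScaffoldSpec:
    return make_small_spec(seed=7, noise=NO_NOISE)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
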