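"""Shared fixtures: full-size geometry built once per session, plus a
coarse, fast configuration for end-to-end tests."""

import numpy as np
import pytest

import spvsim


@pytest.fixture(scope="session")
def array10():
    """The reference 10×10, 400 µm pitch array centred on the fovea."""
    return spvsim.build_electrode_array(10, 10, 400.0)


@pytest.fixture(scope="session")
def spec_default():
    return spvsim.RetinaSpec()


@pytest.fixture(scope="session")
def axon_map_default(spec_default):
    """Default-resolution axon map (500 bundles, 50 µm step); ~0.2 s build."""
    return spvsim.build_axon_map(spec_default)


@pytest.fixture(scope="session")
def spatial_default(array10, axon_map_default):
    return spvsim.SpatialModel(array10, axon_map_default)


def fast_config(**overrides):
    """Coarse configuration for end-to-end runs: fewer bundles, 0.5° grid,
    short clips.  Science parameters (array, ρ/λ, clock) stay at defaults."""
    base = dict(
        n_axons=150,
        axon_step_um=100.0,
        percept_grid_step_deg=0.5,
        stimulus_duration_s=1.0,
    )
    base.update(overrides)
    return spvsim.SimConfig(**base)


@pytest.fixture()
def cfg_fast():
    return fast_config()
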