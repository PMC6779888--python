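import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen_cfg():
    """A scaled-down screen: 700 clones, 6e4 cells, 3e4 reads/gate, 1% spike.

    The library must be large enough that the spike's own Δ does not dominate
    the background σ (the z ceiling of an n-clone screen is ~sqrt(n))."""
    from fretscreen.config import ScreenConfig
    return ScreenConfig.model_validate({
        "library": {"n_clones": 700, "spikes": [{"fraction": 0.01, "mode": "cell"}]},
        "simulation": {"total_cells": 60_000, "reads_per_gate": 30_000},
        "seed": 11,
    })


@pytest.fixture(scope="session")
def small_outcome(small_screen_cfg):
    from fretscreen.screen import run_screen
    return run_screen(small_screen_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190912)
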