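"""Shared fixtures: small meshes and simulation runs reused across tests."""

import numpy as np
import pytest

from epiboly import synthetic as syn
from epiboly.params import SimParams

R = 592.0


@pytest.fixture(scope="session")
def small_mesh():
    return syn.make_evl_tessellation(20, R, 1.0, seed=5)


@pytest.fixture(scope="session")
def small_pop():
    rng = np.random.default_rng(17)
    pos = syn.place_dcl_uniform(40, R, 1.0, rng)
    from epiboly.simulate import DCLPopulation
    return DCLPopulation(np.arange(40), pos, np.full(40, 15.0),
                         np.zeros(40, bool), [])


@pytest.fixture(scope="session")
def optimal_run():
    """Full three-force run at the optimal parameters (100 frames).

    Shared by the coupled-spreading, border-preference and track-statistic
    tests; generating it once keeps the suite fast.
    """
    cfg = syn.SyntheticConfig(n_frames=100, seed=7)
    tracks, cells, truth = syn.make_reference_dataset(
        cfg, SimParams(n_frames=100))
    return tracks, cells, truth
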