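import numpy as np
import pytest

from repnet.engine import run_simulation
from repnet.model import validate_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_params(**overrides):
    """Quick-to-run parameter record for unit tests."""
    base = dict(N=30, m=2, T=20, p_A=0.1, p_D=0.1, seed=7)
    base.update(overrides)
    return validate_params(base)


@pytest.fixture(scope="session")
def mixed_population_runs():
    """200 replicate runs per (r, mode) condition at p_A = p_D = 0.1.

    Shared by the directional tests: reputation should raise cooperation
    in both regimes and raise payoff–behaviour correspondence under
    strategic updating.  Full-scale defaults (N=100, T=100).
    """
    conditions = {}
    for mode_idx, mode in enumerate(("random_rewiring", "strategic_updating")):
        for r in (0, 1):
            params = validate_params(
                dict(p_A=0.1, p_D=0.1, r=r, mode=mode, theta0=0.1)
            )
            seq = np.random.SeedSequence(2021, spawn_key=(mode_idx, r))
            runs = [
                run_simulation(params, rng=np.random.default_rng(child))
                for child in seq.spawn(200)
            ]
            conditions[(mode, r)] = runs
    return conditions
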