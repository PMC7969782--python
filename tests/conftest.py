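import numpy as np
import pytest

from vascgen import engine, fixtures, hemo


@pytest.fixture(scope="session")
def disc_tree_40():
    """A 40-terminal tree in the unit disc, converged (shared, read-only)."""
    fx = fixtures.build("disc_uniform", n_terminals=40)
    forest, per_stage = engine.run_stages(fx["stages"], seed=42)
    state = hemo.solve(forest)
    return forest, per_stage, state, fx["stages"][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_forest(rng, n_terminals=5):
    """Small random grown forest for oracle comparisons."""
    fx = fixtures.build("disc_uniform", n_terminals=n_terminals)
    forest, _ = engine.run_stages(fx["stages"], seed=int(rng.integers(2**31 - 1)))
    hemo.solve(forest)
    return forest, fx["stages"][0]
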