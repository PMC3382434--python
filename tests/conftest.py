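import numpy as np
import pytest

import evonet as ev


@pytest.fixture(scope="session")
def envs():
    return {k: ev.make_environment(k) for k in ("A", "B", "XOR")}


@pytest.fixture(scope="session")
def reference_cells():
    return {ph: ev.build_reference_cell(ph) for ph in ("A", "B", "XOR")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def warm_engine(envs):
    """Trigger the one-off numba compilation before timed assertions."""
    r = np.random.default_rng(0)
    cell = ev.build_reference_cell("A")
    ev.fitness(cell, envs["A"], r)
    return True
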