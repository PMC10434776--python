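import numpy as np
import pytest

from hudopt import datasets


@pytest.fixture(scope="session")
def table3():
    return datasets.load_table("table3")


@pytest.fixture(scope="session")
def table1():
    return datasets.load_table("table1")


@pytest.fixture(scope="session")
def table4():
    return datasets.load_table("table4")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenes():
    """Forty 64x64 synthetic hotspot scenes (fast IVPM training)."""
    return [datasets.make_synthetic_scene(64, 64, 2, seed=s) for s in range(40)]
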