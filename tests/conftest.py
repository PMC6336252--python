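import numpy as np
import pytest

import breedsim as bs


@pytest.fixture(scope="session")
def default_map():
    return bs.build_map()


@pytest.fixture(scope="session")
def two_marker_map():
    """One linkage group, two markers 1 cM apart."""
    return bs.build_map(1, 2, 1.0)


@pytest.fixture(scope="session")
def small_map():
    """3 groups x 11 markers at 10 cM: cheap stand-in for the full genome."""
    return bs.build_map(3, 11, 10.0)


@pytest.fixture(scope="session")
def f2_default(default_map):
    """An F2 of 500 on the full map (shared; treat as read-only)."""
    p1, p2 = bs.make_founders(default_map)
    return bs.make_f2(p1, p2, 500, default_map, np.random.default_rng(42))


def rng(seed=0):
    return np.random.default_rng(seed)
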