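import numpy as np
import pytest

from reflexio.reflection_model import ReflectionTable, UnitCell, get_group


@pytest.fixture
def cubic_cell():
    return UnitCell(10, 10, 10)


@pytest.fixture
def ortho_cell():
    return UnitCell(30, 40, 50)


@pytest.fixture
def triclinic_cell():
    return UnitCell(10, 12, 15, 85, 95, 100)


@pytest.fixture
def p1():
    return get_group("P1")


@pytest.fixture
def p222():
    return get_group("P222")


def random_table(rng, n=200, index_range=8, n_images=20):
    """Small random reflection table; duplicate indices are likely, which is
    what the merging statistics need."""
    hkl = rng.integers(-index_range, index_range + 1, size=(n, 3))
    hkl[(hkl == 0).all(axis=1)] = (1, 0, 0)
    return ReflectionTable.from_arrays(
        hkl[:, 0], hkl[:, 1], hkl[:, 2],
        intensity=rng.normal(100, 30, n),
        sigma=rng.uniform(1, 10, n),
        image=rng.integers(1, n_images + 1, n),
    )
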