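import numpy as np
import pytest

from mfdc import (
    ControlIncrement,
    GeneratorSpec,
    Grid,
    ScalarMap,
    gaussian_smooth,
    identity_field,
    random_smooth_field,
)


@pytest.fixture(scope="session")
def grid16():
    return Grid((16, 16, 16))


@pytest.fixture(scope="session")
def grid32():
    return Grid((32, 32, 32))


@pytest.fixture(scope="session")
def smooth_field32():
    """Moderate-amplitude smooth diffeomorphic field on a 32^3 grid."""
    return random_smooth_field(GeneratorSpec(shape=(32, 32, 32), amplitude=2.0, sigma_gen=4, seed=1))


@pytest.fixture(scope="session")
def textured_volume():
    """Smooth but non-constant test image on a 48^3 grid."""
    g = Grid((48, 48, 48))
    c = g.coords()
    vals = np.sin(c[0] / 3.0) + np.cos(c[1] / 4.0) + 0.5 * np.sin(c[2] / 5.0 + 1.0)
    rng = np.random.default_rng(11)
    vals = vals + 0.1 * gaussian_smooth(rng.standard_normal(g.shape), 2.0)
    return ScalarMap(g, vals)


@pytest.fixture()
def stationary_increment32(smooth_field32):
    """The smooth field reused as a stationary boundary-compliant control."""
    return ControlIncrement(smooth_field32.grid, smooth_field32.d)


def identity_solution(shape, L):
    """Multiscale identity solution whose scale chain doubles up to `shape`."""
    from mfdc.metrics import MultiscaleSolution

    chain = [tuple(shape)]
    for _ in range(L - 1):
        chain.append(tuple(s // 2 for s in chain[-1]))
    chain = list(reversed(chain))
    fwd = [identity_field(Grid(s)) for s in chain]
    bwd = [identity_field(Grid(s)) for s in chain]
    return MultiscaleSolution(fwd=fwd, bwd=bwd)
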