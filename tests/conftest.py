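import numpy as np
import pytest

from csmlab import CPMParams, LatticeState, build_neighbourhood


@pytest.fixture(scope="session")
def n1():
    return build_neighbourhood(level=1, dim=2)


@pytest.fixture(scope="session")
def n2():
    return build_neighbourhood(level=2, dim=2)


@pytest.fixture(scope="session")
def n6():
    return build_neighbourhood(level=6, dim=2)


def random_state_and_params(rng, size=16, n_cells=3, neigh=None,
                            boundary="fixed-medium"):
    """A random multi-cell lattice with consistent random CPM parameters."""
    labels = rng.integers(0, n_cells + 1, size=(size, size)).astype(np.int32)
    types = {cid: int(rng.integers(1, 3)) for cid in range(1, n_cells + 1)}
    state = LatticeState(labels, types, neigh, boundary=boundary)
    nt = 2
    J = rng.random((nt + 1, nt + 1)) * 20
    J = (J + J.T) / 2
    params = CPMParams(
        J=J,
        A_target=rng.random(nt + 1) * 100,
        P_target=rng.random(nt + 1) * 200,
        lambda_a=rng.random(nt + 1) * 2,
        lambda_p=rng.random(nt + 1),
        T=10.0,
        neighbourhood=neigh,
        boundary=boundary,
    )
    return state, params
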