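import numpy as np
import pytest

from stcsim.community import Community, StrainRegistry
from stcsim.params import ModelParams


def build_community(V, s, nu, params):
    """Assemble a Community directly from arrays (test helper)."""
    V = np.asarray(V, dtype=float)
    s = np.asarray(s, dtype=float)
    nu = np.asarray(nu, dtype=float)
    registry = StrainRegistry()
    ids = np.array([registry.new_strain(s=s[i]) for i in range(len(s))])
    return Community(params=params, V=V, s=s, nu=nu, ids=ids, registry=registry)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def antisym_pair():
    """Two strains with the zero-sum antisymmetric game V = [[0,1],[-1,0]]."""
    params = ModelParams(gamma=-1.0, m=0.0, I=1, N=1e12, K=2, dt=0.01, seed=0)
    V = [[0.0, 1.0], [-1.0, 0.0]]
    return build_community(V, [0.0, 0.0], [[0.2], [0.8]], params)


@pytest.fixture
def rps_triple():
    """Rock-paper-scissors antisymmetric game: conserved nu1*nu2*nu3 orbit."""
    params = ModelParams(gamma=-1.0, m=0.0, I=1, N=1e12, K=3, dt=0.01, seed=0)
    V = [[0.0, 1.0, -1.0], [-1.0, 0.0, 1.0], [1.0, -1.0, 0.0]]
    return build_community(V, [0.0] * 3, [[0.2], [0.3], [0.5]], params)


@pytest.fixture(scope="session")
def small_stc():
    """A relaxed 100-strain chaotic community, shared across tests.

    Session-scoped because relaxation is the expensive step; tests must
    not mutate it (take .copy() first).
    """
    from stcsim.evolution import run_assembly

    params = ModelParams(gamma=-0.8, m=1e-3, I=10, N=1e8, K=100, seed=42)
    community, L0, averages = run_assembly(params)
    assert L0 > 10
    return community, averages
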