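"""Small deterministic communities for tests and demonstrations."""

from __future__ import annotations

import numpy as np

from . import rng as rng_mod
from .community import Community, StrainRegistry
from .params import ModelParams
from .sampling import sample_interaction_matrix

__all__ = ["make_fixture", "FIXTURE_NAMES", "PLANTED_S"]

# Known negative general fitness of the planted strain in "planted_decay".
PLANTED_S = -0.2

FIXTURE_NAMES = ("pair_antisym", "stc_small", "planted_decay")


def _build(params: ModelParams, V: np.ndarray, s: np.ndarray, nu: np.ndarray) -> Community:
    registry = StrainRegistry()
    ids = np.array([registry.new_strain(s=s[i]) for i in range(len(s))])
    return Community(params=params, V=V, s=s, nu=nu, ids=ids, registry=registry)


def make_fixture(name: str) -> Community:
    """Return a registered deterministic community.

    - ``pair_antisym``: 2 strains with a perfectly antisymmetric off-diagonal
      pair (gamma = -1), 2 islands.
    - ``stc_small``: K=200, gamma=-0.8, m=1e-3, I=10 — a desk-scale
      community that relaxes into the spatiotemporally chaotic state.
    - ``planted_decay``: interaction-free background plus one strain with a
      known negative general fitness (``PLANTED_S``), for validating the
      decay-based bias estimator against a planted truth.
    """
    if name == "pair_antisym":
        params = ModelParams(gamma=-1.0, m=1e-3, I=2, N=1e8, K=2, seed=11)
        gen = rng_mod.stream(params.seed, "assembly")
        V = sample_interaction_matrix(2, -1.0, gen)
        s = np.zeros(2)
        nu = np.array([[0.3, 0.6], [0.7, 0.4]])
        return _build(params, V, s, nu)

    if name == "stc_small":
        params = ModelParams(gamma=-0.8, m=1e-3, I=10, N=1e8, K=200, seed=7)
        gen = rng_mod.stream(params.seed, "assembly")
        V = sample_interaction_matrix(params.K, params.gamma, gen)
        s = np.zeros(params.K)
        init = rng_mod.stream(params.seed, "init")
        nu = init.exponential(size=(params.K, params.I))
        nu /= nu.sum(axis=0)[None, :]
        return _build(params, V, s, nu)

    if name == "planted_decay":
        # 20 interaction-free neutral strains plus a planted strain whose
        # only distinguishing property is its negative general fitness: its
        # decay rate with migration off is the planted value itself.
        K_bg = 20
        params = ModelParams(gamma=0.0, m=1e-3, I=5, N=1e8, K=K_bg + 1, seed=3)
        K = K_bg + 1
        V = np.zeros((K, K))
        s = np.zeros(K)
        s[-1] = PLANTED_S
        nu = np.full((K, params.I), (1.0 - 1e-2) / K_bg)
        nu[-1, :] = 1e-2
        return _build(params, V, s, nu)

    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
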