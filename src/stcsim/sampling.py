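"""Sampling of strains: interaction matrices, general fitnesses, invaders, mutants.

Interaction entries are Gaussian with ``E[V_ij] = 0`` and ``E[V_ij^2] = 1``
off the diagonal; the only nonzero covariance is the reciprocal correlation
``E[V_ij V_ji] = gamma``, which tunes the ecology from competition-like
(gamma > 0) to host-pathogen-like (gamma < 0).  Diagonal entries have
variance ``1 + gamma`` (their effect is negligible in diverse communities).

General fitnesses are i.i.d. draws from the stretched/compressed exponential
family

    P(s) ∝ exp[-(s/Sigma)^psi / psi] * Theta(s),

whose tail exponent ``psi`` controls whether serial evolution keeps
diversifying (psi > 1), saturates (psi = 1) or crashes (psi < 1).
Substituting ``y = (s/Sigma)^psi / psi`` shows that ``y`` is Gamma(1/psi)
distributed, which gives exact sampling, CDF and quantile functions.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from scipy import special

from .params import ParameterError

__all__ = [
    "sample_correlated_pairs",
    "sample_interaction_matrix",
    "sample_general_fitnesses",
    "fitness_cdf",
    "fitness_ppf",
    "sample_unrelated_invader",
    "choose_parent",
    "sample_mutant",
    "InvaderDraw",
]


class InvaderDraw(NamedTuple):
    """Interactions and fitness of a newly drawn strain A.

    ``row[j] = V_Aj`` (effect of extant strain j on A), ``col[j] = V_jA``
    (effect of A on j), ``self_interaction = V_AA``.
    """

    row: np.ndarray
    col: np.ndarray
    self_interaction: float
    s: float


def _check_gamma(gamma: float) -> None:
    if not -1.0 <= gamma <= 1.0:
        raise ParameterError(f"|gamma| must be <= 1, got {gamma}")


def sample_correlated_pairs(
    n: int, gamma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` bivariate standard-normal pairs with correlation gamma.

    At ``gamma = -1`` the second member is exactly the negative of the first.
    """
    _check_gamma(gamma)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, gamma * z1 + math.sqrt(1.0 - gamma * gamma) * z2


def sample_interaction_matrix(
    K: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Random K x K interaction matrix with reciprocal correlation gamma.

    Off-diagonal unordered pairs are bivariate normal (unit variances,
    correlation gamma); the diagonal is independent with variance
    ``1 + gamma``.
    """
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    _check_gamma(gamma)
    V = np.zeros((K, K))
    iu, ju = np.triu_indices(K, k=1)
    a, b = sample_correlated_pairs(iu.size, gamma, rng)
    V[iu, ju] = a
    V[ju, iu] = b
    V[np.diag_indices(K)] = math.sqrt(1.0 + gamma) * rng.standard_normal(K)
    return V


def sample_general_fitnesses(
    K: int, Sigma: float, psi: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. general fitnesses from P(s) ∝ exp[-(s/Sigma)^psi / psi] on s >= 0."""
    if Sigma < 0:
        raise ParameterError(f"Sigma must be >= 0, got {Sigma}")
    if psi <= 0:
        raise ParameterError(f"psi must be > 0, got {psi}")
    if Sigma == 0:
        return np.zeros(K)
    y = rng.gamma(shape=1.0 / psi, scale=1.0, size=K)
    return Sigma * (psi * y) ** (1.0 / psi)


def fitness_cdf(s, Sigma: float, psi: float):
    """CDF of the general-fitness distribution."""
    s = np.asarray(s, dtype=float)
    y = (np.clip(s, 0.0, None) / Sigma) ** psi / psi
    return special.gammainc(1.0 / psi, y)


def fitness_ppf(u, Sigma: float, psi: float):
    """Quantile function of the general-fitness distribution."""
    y = special.gammaincinv(1.0 / psi, np.asarray(u, dtype=float))
    return Sigma * (psi * y) ** (1.0 / psi)


def sample_unrelated_invader(
    L: int,
    gamma: float,
    Sigma: float,
    psi: float,
    rng: np.random.Generator,
) -> InvaderDraw:
    """Draw a strain unrelated to all extant strains.

    The (V_Aj, V_jA) pairs carry the same marginals and gamma-correlation
    as the original matrix; V_AA has variance ``1 + gamma``; s_A ~ P(s).
    """
    if L < 1:
        raise ParameterError("community must contain at least one extant strain")
    _check_gamma(gamma)
    row, col = sample_correlated_pairs(L, gamma, rng)
    self_int = math.sqrt(1.0 + gamma) * float(rng.standard_normal())
    s_A = float(sample_general_fitnesses(1, Sigma, psi, rng)[0])
    return InvaderDraw(row=row, col=col, self_interaction=self_int, s=s_A)


def choose_parent(nu_bar: np.ndarray, rng: np.random.Generator) -> int:
    """Choose a parent index with probability proportional to mean abundance."""
    nu_bar = np.asarray(nu_bar, dtype=float)
    if np.any(nu_bar < 0):
        raise ParameterError("mean abundances must be nonnegative")
    total = nu_bar.sum()
    if total <= 0:
        raise ParameterError("cannot choose a parent from an empty community")
    return int(rng.choice(nu_bar.size, p=nu_bar / total))


def _correlated_fitness(
    s_parent: float,
    rho_s: float,
    Sigma: float,
    psi: float,
    rng: np.random.Generator,
) -> float:
    """Mutant fitness with Gaussian-copula correlation rho_s to the parent.

    The copula leaves the mutant's marginal exactly P(s); rho_s = 0 is a
    fresh draw, rho_s = 1 copies the parent.
    """
    if Sigma == 0:
        return 0.0
    if rho_s == 0.0:
        return float(sample_general_fitnesses(1, Sigma, psi, rng)[0])
    if rho_s == 1.0:
        return float(s_parent)
    u_p = float(fitness_cdf(s_parent, Sigma, psi))
    # Clip away from {0, 1} so ndtri stays finite.
    u_p = min(max(u_p, 1e-15), 1.0 - 1e-15)
    z_p = special.ndtri(u_p)
    z_m = rho_s * z_p + math.sqrt(1.0 - rho_s**2) * float(rng.standard_normal())
    return float(fitness_ppf(special.ndtr(z_m), Sigma, psi))


def sample_mutant(
    V: np.ndarray,
    parent: int,
    gamma: float,
    rho: float,
    s_parent: float = 0.0,
    rho_s: float = 0.0,
    Sigma: float = 0.0,
    psi: float = 1.0,
    rng: np.random.Generator | None = None,
) -> InvaderDraw:
    """Draw a mutant M of extant strain P (index ``parent`` in ``V``).

    For every other strain j the mutant's interactions mix the parent's with
    fresh gamma-correlated noise,

        V_Mj = rho * V_Pj + sqrt(1 - rho^2) * eps_Mj,
        V_jM = rho * V_jP + sqrt(1 - rho^2) * eps_jM,

    with Corr(eps_Mj, eps_jM) = gamma, so that marginals, the reciprocal
    correlation Corr(V_Mj, V_jM) = gamma, and the parent correlations
    Corr(V_Mj, V_Pj) = Corr(V_jM, V_jP) = rho are all preserved.  The
    direct pair (V_MP, V_PM) mixes the parent's self-interaction with a
    fresh gamma-correlated pair in the same way, and V_MM is a fresh
    diagonal draw; in diverse communities these few entries carry a small
    fraction of the total abundance and the specific choice matters little.
    Returned ``row``/``col`` are indexed like the rows of ``V``.
    """
    if rng is None:
        raise ParameterError("an explicit rng is required")
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"rho must lie in [0, 1), got {rho}")
    _check_gamma(gamma)
    V = np.asarray(V, dtype=float)
    L = V.shape[0]
    if not 0 <= parent < L:
        raise ParameterError(f"parent index {parent} outside community of size {L}")

    mix = math.sqrt(1.0 - rho * rho)
    eps_row, eps_col = sample_correlated_pairs(L, gamma, rng)
    row = rho * V[parent, :] + mix * eps_row
    col = rho * V[:, parent] + mix * eps_col
    # Direct parent-mutant pair: mix parent's diagonal with a fresh pair.
    a, b = sample_correlated_pairs(1, gamma, rng)
    row[parent] = rho * V[parent, parent] + mix * float(a[0])
    col[parent] = rho * V[parent, parent] + mix * float(b[0])
    self_int = math.sqrt(1.0 + gamma) * float(rng.standard_normal())
    s_M = _correlated_fitness(s_parent, rho_s, Sigma, psi, rng)
    return InvaderDraw(row=row, col=col, self_interaction=self_int, s=s_M)
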