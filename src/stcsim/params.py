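"""Model parameters for the island metacommunity model.

All rates are in units of the ecological interaction timescale, which is
fixed by normalising the off-diagonal interaction variance to one.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a model parameter is outside its admissible range."""


@dataclass
class ModelParams:
    """Scalar parameters of the ecology, the evolution and the numerics.

    Parameters
    ----------
    gamma : float
        Symmetry of the interaction matrix, ``E[V_ij V_ji] = gamma`` for
        ``i != j``.  Host-pathogen-like (anticorrelated) interactions have
        ``gamma < 0``; the spatiotemporally chaotic phase requires
        substantially negative values.
    m : float
        Migration rate between islands (mean-field: ``m/I`` per ordered
        island pair, so the net flux on strain i is ``m (nu_bar_i - nu_i)``).
    I : int
        Number of islands.
    N : float
        Local population size per island.  Sets the extinction threshold at
        fractional abundance ``1/N``; dynamics are otherwise deterministic.
    K : int
        Number of unrelated strains in the initially assembled community.
    rho : float
        Correlation between a mutant's interaction rows/columns and its
        parent's; ``rho = 0`` reproduces unrelated invaders.
    rho_s : float
        Correlation between mutant and parent general fitness.
    Sigma : float
        Scale of the general-fitness distribution ``P(s)``; ``Sigma = 0``
        switches general fitnesses off.
    psi : float
        Tail exponent of ``P(s) ~ exp[-(s/Sigma)^psi / psi]``.
    epoch_multiplier : float
        Epoch length in units of ``M * L`` with ``M = ln(1/m)``.
    dt : float
        Integrator step.
    seed : int
        Root RNG seed; all named streams derive from it.
    """

    gamma: float = -0.8
    m: float = 1e-5
    I: int = 40
    N: float = 1e9
    K: int = 50
    rho: float = 0.0
    rho_s: float = 0.0
    Sigma: float = 0.0
    psi: float = 1.0
    epoch_multiplier: float = 3.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.gamma <= 1.0:
            raise ParameterError(f"gamma must lie in [-1, 1], got {self.gamma}")
        if self.m < 0:
            raise ParameterError(f"migration rate m must be >= 0, got {self.m}")
        if self.I < 1:
            raise ParameterError(f"island count I must be >= 1, got {self.I}")
        if self.N <= 1:
            raise ParameterError(f"population size N must exceed 1, got {self.N}")
        if self.K < 1:
            raise ParameterError(f"initial strain count K must be >= 1, got {self.K}")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 <= self.rho_s <= 1.0:
            raise ParameterError(f"rho_s must lie in [0, 1], got {self.rho_s}")
        if self.Sigma < 0:
            raise ParameterError(f"Sigma must be >= 0, got {self.Sigma}")
        if self.psi <= 0:
            raise ParameterError(f"psi must be > 0, got {self.psi}")
        if self.epoch_multiplier <= 0:
            raise ParameterError("epoch_multiplier must be > 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.m > 0 and self.m * self.N < 10:
            warnings.warn(
                f"m*N = {self.m * self.N:.3g} < 10: migration does not dominate "
                "demographic scales; the deterministic treatment assumes m*N >> 1.",
                stacklevel=2,
            )

    @property
    def extinction_threshold(self) -> float:
        """Fractional abundance below which a local population is zeroed."""
        return 1.0 / self.N

    @property
    def M(self) -> float:
        """Logarithmic fluctuation range ``M = ln(1/m)``."""
        if self.m <= 0:
            return math.inf
        return math.log(1.0 / self.m)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)
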