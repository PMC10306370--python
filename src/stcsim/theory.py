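"""Effective evolutionary theory of the chaotic phase.

On evolutionary timescales (one unit = one attempted invasion, T) the mean
drive ``zeta_i`` of each extant strain performs a biased random walk

    d zeta_i / dT = -B * zeta_i / L(T) + sqrt(2 D) / L(T) * eta_i(T),

with ``eta`` unit white noise and B, D order-unity coefficients set by the
fragility of the community; a strain is absorbed (goes globally extinct)
when its bias ``xi = zeta - Upsilon_bar`` falls below the critical bias
``xi_c``.  The matching Fokker-Planck problem with an absorbing boundary
and a source of successful invaders yields the quasi-stationary drive
distribution — vanishing linearly at the boundary — and an eigenvalue-like
net rate whose sign decides between diversification and decline.

The bias of a fresh unrelated invader is exactly Gaussian with mean
``-Upsilon_bar`` and standard deviation ``1/sqrt(L_eff)`` (``L_eff = 1/sum
nu_bar^2``), so the invasion probability is ``Phi[(xi_c + Upsilon_bar) *
sqrt(L_eff)]``.

General-fitness scaling laws: once evolution pushes the extant fitnesses
into the tail of ``P(s) ~ exp[-(s/Sigma)^psi/psi]``, the local tail scale
``Sigma_hat = -1/(d log P/ds)|_{s_hat} = Sigma (Sigma/s_hat)^(psi-1)``
controls the community size via ``L ~ Sigma_hat^-2``, giving

    s_hat/Sigma ~ [psi log((T+K) Sigma^2)]^(1/psi),
    L ~ Sigma^-2 [log((T+K) Sigma^2)]^(2-2/psi),
    Z ~ Sigma^-2 [log(T+K)]^(3-2/psi),

each up to an undetermined order-unity prefactor (the ``+K`` crudely
absorbs the assembly transient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "TheoryModel",
    "FokkerPlanckResult",
    "invasion_probability",
    "simulate_drive_walk",
    "solve_fokker_planck",
    "fit_drive_coefficients",
    "sigma_hat",
    "shat_over_sigma",
    "scaling_predictions",
]


class RegimeError(ValueError):
    """Raised when a scaling law is evaluated outside its asymptotic regime."""


@dataclass
class TheoryModel:
    """Coefficients of the effective drive-walk description.

    ``L`` is the community size appearing in the walk's denominators (the
    effective size ``L_eff`` by default; pass the extant count to compare
    conventions).
    """

    B: float
    D: float
    xi_c: float
    upsilon_bar: float
    L: float

    def __post_init__(self) -> None:
        if self.B <= 0 or self.D <= 0:
            raise ValueError("B and D must be positive for a well-posed problem")
        if self.L <= 0:
            raise ValueError("community size L must be positive")

    @property
    def boundary(self) -> float:
        """Absorbing drive value ``zeta = xi_c + Upsilon_bar``."""
        return self.xi_c + self.upsilon_bar


def invasion_probability(xi_c: float, upsilon_bar: float, L_eff: float) -> float:
    """Probability that a fresh unrelated invader has bias above xi_c.

    From the exact Gaussian invader-bias law (mean ``-Upsilon_bar``, sd
    ``1/sqrt(L_eff)``): ``P(xi_A > xi_c) = Phi[-(xi_c + Upsilon_bar) *
    sqrt(L_eff)]``.  The probability decreases as the critical bias rises
    toward the mean invader bias and is 1/2 when ``xi_c = -Upsilon_bar``.
    """
    if L_eff <= 0:
        raise ValueError("L_eff must be positive")
    return float(stats.norm.cdf(-(xi_c + upsilon_bar) * math.sqrt(L_eff)))


def simulate_drive_walk(
    model: TheoryModel,
    zeta0: np.ndarray,
    T: int,
    rng: np.random.Generator,
    L_schedule: np.ndarray | None = None,
    absorbing: bool = True,
) -> dict:
    """Euler-Maruyama simulation of the per-invasion drive walk.

    One step per attempted invasion.  Returns the trajectory array
    (shape (T+1, n), NaN after absorption), the absorption step of each
    walker (-1 if it survived) and the surviving walkers' final drives.
    """
    zeta = np.array(zeta0, dtype=float)
    n = zeta.size
    if L_schedule is None:
        L_schedule = np.full(T, float(model.L))
    if len(L_schedule) != T:
        raise ValueError("L_schedule must have length T")
    traj = np.full((T + 1, n), np.nan)
    traj[0] = zeta
    alive = np.ones(n, dtype=bool)
    if absorbing:
        alive &= zeta >= model.boundary
    absorbed_at = np.full(n, -1, dtype=int)
    absorbed_at[~alive] = 0
    noise_amp = math.sqrt(2.0 * model.D)
    for step in range(1, T + 1):
        Lt = float(L_schedule[step - 1])
        eta = rng.standard_normal(n)
        zeta[alive] += (
            -model.B * zeta[alive] / Lt + noise_amp * eta[alive] / Lt
        )
        if absorbing:
            newly = alive & (zeta < model.boundary)
            absorbed_at[newly] = step
            alive &= ~newly
        traj[step, alive] = zeta[alive]
    return {
        "trajectories": traj,
        "absorbed_at": absorbed_at,
        "survivors": zeta[alive],
        "alive": alive,
    }


@dataclass
class FokkerPlanckResult:
    grid: np.ndarray  # cell centres in zeta
    quasi_stationary: np.ndarray  # leading absorbing mode, integrates to 1
    decay_rate: float  # decay rate of the leading mode (per attempt)
    steady_density: np.ndarray | None  # source-driven steady state (if source)
    source_density: np.ndarray | None
    invasion_prob: float | None
    extinction_flux: float | None  # mean extinctions per attempt, decay_rate * L
    net_rate: float | None  # dL/dT = invasion_prob - decay_rate * L
    residual: float


def _fp_operator(model: TheoryModel, grid: np.ndarray) -> np.ndarray:
    """Dense drift-diffusion operator with absorbing (Dirichlet) edges.

    ``A p = -d/dzeta[a(zeta) p] + Dc d^2 p/dzeta^2`` with drift
    ``a = -B zeta / L`` and diffusion ``Dc = D / L^2``, discretized with
    second-order central differences on the interior nodes.
    """
    n = grid.size
    h = grid[1] - grid[0]
    Dc = model.D / model.L**2
    a = -model.B * grid / model.L
    A = np.zeros((n, n))
    for k in range(n):
        km1, kp1 = k - 1, k + 1
        # diffusion
        A[k, k] += -2.0 * Dc / h**2
        if km1 >= 0:
            A[k, km1] += Dc / h**2
        if kp1 < n:
            A[k, kp1] += Dc / h**2
        # advection: -d/dzeta (a p), central
        if km1 >= 0:
            A[k, km1] += a[km1] / (2.0 * h)
        if kp1 < n:
            A[k, kp1] += -a[kp1] / (2.0 * h)
    return A


def solve_fokker_planck(
    model: TheoryModel,
    n_grid: int = 400,
    span_sd: float = 6.0,
    with_source: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FokkerPlanckResult:
    """Quasi-stationary drive density and net diversification rate.

    The grid spans from the absorbing boundary ``xi_c + Upsilon_bar`` up to
    ``span_sd`` stationary standard deviations (``sqrt(D/(B L))``) above
    zero.  The quasi-stationary density is the leading eigenmode of the
    discretized operator, found by inverse iteration to residual ``tol``;
    it vanishes linearly at the boundary.  With a source (successful
    invaders, whose drives follow the Gaussian invader law truncated at the
    boundary, normalised to the invasion probability), the source-driven
    steady-state density is computed as well.  The eigenvalue-like
    condition separating diversification from decline is the sign of
    ``net_rate = invasion_prob - decay_rate * L``: a community of L strains
    whose drive distribution has relaxed to the quasi-stationary mode loses
    ``decay_rate * L`` strains per attempted invasion and gains
    ``invasion_prob``.
    """
    sd_stat = math.sqrt(model.D / (model.B * model.L))
    lo = model.boundary
    hi = max(0.0, model.boundary) + span_sd * sd_stat
    if hi <= lo:
        raise ValueError("grid span is empty; check xi_c and Upsilon_bar")
    # Interior nodes; density is pinned to zero at lo and hi.
    edges = np.linspace(lo, hi, n_grid + 2)
    grid = edges[1:-1]
    h = edges[1] - edges[0]
    A = _fp_operator(model, grid)

    # Inverse iteration for the eigenvalue of smallest magnitude (all modes
    # decay, so this is the quasi-stationary one).
    lu, piv = linalg.lu_factor(A)
    p = np.exp(-((grid - max(0.0, model.boundary)) ** 2) / (2 * sd_stat**2))
    p /= np.linalg.norm(p)
    lam = 0.0
    residual = math.inf
    for _ in range(max_iter):
        q = linalg.lu_solve((lu, piv), p)
        q /= np.linalg.norm(q)
        lam = float(q @ A @ q)
        residual = float(np.linalg.norm(A @ q - lam * q))
        converged = residual < tol * max(1.0, abs(lam))
        p = q
        if converged:
            break
    else:
        raise RuntimeError(
            f"inverse iteration failed to converge (residual {residual:.3e})"
        )
    qs = np.abs(p)
    qs /= qs.sum() * h  # normalise to unit integral
    decay_rate = -lam

    steady = source = phi = flux = net = None
    if with_source:
        sd_inv = 1.0 / math.sqrt(model.L)
        phi = invasion_probability(model.xi_c, model.upsilon_bar, model.L)
        raw = stats.norm.pdf(grid, loc=0.0, scale=sd_inv)
        mass = raw.sum() * h
        if mass <= 0:
            raise RuntimeError("source density vanishes on the grid")
        source = raw / mass * phi  # influx normalised to invasion probability
        steady = linalg.lu_solve((lu, piv), -source)
        steady = np.clip(steady, 0.0, None)
        flux = decay_rate * model.L  # extinctions per attempt at quasi-stationarity
        net = phi - flux
    return FokkerPlanckResult(
        grid=grid,
        quasi_stationary=qs,
        decay_rate=decay_rate,
        steady_density=steady,
        source_density=source,
        invasion_prob=phi,
        extinction_flux=flux,
        net_rate=net,
        residual=residual,
    )


def fit_drive_coefficients(
    zeta_before: np.ndarray,
    zeta_after: np.ndarray,
    L: float,
) -> tuple[float, float]:
    """Fit B and D from per-invasion drive changes of surviving strains.

    Regresses ``delta_zeta`` on ``zeta``: the slope estimates ``-B/L`` and
    the residual variance estimates ``2D/L^2``.
    """
    zeta_before = np.asarray(zeta_before, dtype=float)
    delta = np.asarray(zeta_after, dtype=float) - zeta_before
    res = stats.linregress(zeta_before, delta)
    B = -float(res.slope) * L
    resid = delta - (res.intercept + res.slope * zeta_before)
    D = float(resid.var()) * L**2 / 2.0
    return B, D


def sigma_hat(s_hat: float, Sigma: float, psi: float) -> float:
    """Local tail scale ``Sigma_hat = -1/(d log P/ds)`` at ``s = s_hat``.

    For the stretched-exponential family this is ``Sigma *
    (Sigma/s_hat)^(psi-1)``; at psi = 1 it reduces to Sigma for any s_hat.
    """
    if Sigma <= 0 or psi <= 0:
        raise ValueError("Sigma and psi must be positive")
    if psi == 1.0:
        return Sigma
    if s_hat <= 0:
        raise RegimeError(
            "Sigma_hat diverges (psi < 1) or vanishes (psi > 1) as s_hat -> 0"
        )
    return Sigma * (Sigma / s_hat) ** (psi - 1.0)


def shat_over_sigma(psi: float, T: float, L: float) -> float:
    """Asymptotic mean-fitness ratio ``[psi log(T/L)]^(1/psi)``."""
    if T <= L:
        raise RegimeError("requires T > L (past the transient regime)")
    return (psi * math.log(T / L)) ** (1.0 / psi)


def scaling_predictions(
    Sigma: float,
    psi: float,
    K: int,
    T: np.ndarray,
) -> dict[str, np.ndarray]:
    """Scaling curves s_hat(T), L(T), Z(T) for the general-fitness model.

    Each curve carries an undetermined order-unity prefactor and is valid
    once ``(T+K) * Sigma^2 > 1``; the returned values are the bare scaling
    forms, to be rescaled when compared against simulation.
    """
    T = np.asarray(T, dtype=float)
    if Sigma <= 0 or psi <= 0:
        raise ValueError("Sigma and psi must be positive")
    arg = (T + K) * Sigma**2
    if np.any(arg <= 1.0):
        raise RegimeError(
            "scaling laws require (T+K)*Sigma^2 > 1 for all requested T"
        )
    log_arg = np.log(arg)
    s_hat = Sigma * (psi * log_arg) ** (1.0 / psi)
    L_curve = Sigma**-2 * log_arg ** (2.0 - 2.0 / psi)
    Z_curve = Sigma**-2 * np.log(T + K) ** (3.0 - 2.0 / psi)
    return {"T": T, "s_hat": s_hat, "L": L_curve, "Z": Z_curve}
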