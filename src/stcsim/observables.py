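"""Theory-facing statistics of evolved communities.

The central per-strain quantity is the *bias* ``xi_i = zeta_i + s_i -
Upsilon_bar``: the average growth rate of strain i at low abundance with
migration switched off, with the *mean drive* ``zeta_i`` the average
interaction force from the rest of the community.  Strains persist in the
chaotic phase iff their bias exceeds a (negative) critical value ``xi_c``.

Three bias estimators of increasing cost are provided: the leave-in
estimator (drives computed with the strain's own influence left in — a
cheap O(L) proxy), the leave-one-out estimator (re-integrates the
community without the strain, matching the defining construction), and the
decay-fit estimator (switches off the strain's migration and fits its
exponential decay, matching the operational definition of the bias).
Cross-validation between the three bounds the estimation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .community import Community
from .dynamics import EpochAverages, integrate
from .evolution import EpochSummary, epoch_length

__all__ = [
    "BiasTable",
    "ExtinctionStats",
    "DecayFit",
    "effective_size",
    "mean_fitness",
    "estimate_bias_leave_in",
    "estimate_bias_leave_one_out",
    "estimate_bias_by_decay",
    "extinction_statistics",
    "estimate_susceptibility",
    "community_fragility",
    "sample_invader_biases",
    "distribution_reports",
]


@dataclass
class BiasTable:
    """Per-strain bias/drive estimates from one estimator at one epoch."""

    ids: np.ndarray
    xi: np.ndarray
    zeta: np.ndarray
    estimator: str
    epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_id": self.ids,
                "xi": self.xi,
                "zeta": self.zeta,
                "estimator": self.estimator,
                "epoch": self.epoch,
            }
        )


@dataclass
class ExtinctionStats:
    """Distribution of the number of extinctions per successful invasion."""

    counts: np.ndarray  # histogram over ell = 0, 1, 2, ...
    n_successes: int
    beta: float | None  # fitted tail rate of P(ell) ~ exp(-beta*ell)/ell
    mean_ell: float
    status: str = "ok"


@dataclass
class DecayFit:
    xi: float
    stderr: float
    r_squared: float
    status: str  # "ok" | "non_decaying" | "poor_fit"


def effective_size(nu_bar: np.ndarray) -> float:
    """Effective community size ``1 / sum(nu_bar^2)`` (participation ratio)."""
    nu_bar = np.asarray(nu_bar, dtype=float)
    sq = float((nu_bar**2).sum())
    if sq <= 0:
        raise ValueError("effective size undefined for an all-zero abundance vector")
    return 1.0 / sq


def mean_fitness(nu_bar: np.ndarray, s: np.ndarray) -> float:
    """Population-weighted mean general fitness ``s_hat = sum_j nu_bar_j s_j``."""
    nu_bar = np.asarray(nu_bar, dtype=float)
    s = np.asarray(s, dtype=float)
    if nu_bar.shape != s.shape:
        raise ValueError("nu_bar and s must have matching shapes")
    return float(nu_bar @ s)


def estimate_bias_leave_in(
    community: Community, averages: EpochAverages, epoch: int = 0
) -> BiasTable:
    """Leave-in bias estimate from steady-state averages.

    ``zeta_i = sum_{j != i} V_ij nu_bar_j`` and ``xi_i = zeta_i + s_i -
    Upsilon_bar``.  The defining drive uses leave-one-out averages
    ``nu_bar_{j \\ i}``; keeping strain i in is the cheap O(L) proxy, and
    its error is bounded by cross-validation against the leave-one-out and
    decay estimators.
    """
    nu_bar = averages.nu_bar
    if nu_bar.size != community.L:
        raise ValueError("averages do not match the current community size")
    drive_full = community.V @ nu_bar
    zeta = drive_full - np.diag(community.V) * nu_bar  # exclude self term
    xi = zeta + community.s - averages.upsilon_bar
    return BiasTable(
        ids=community.ids.copy(), xi=xi, zeta=zeta, estimator="leave_in", epoch=epoch
    )


def estimate_bias_leave_one_out(
    community: Community,
    strain_id: int,
    relaxation_multiplier: float = 1.0,
) -> float:
    """Leave-one-out bias: re-integrate the community without strain i.

    Removes the strain, renormalises every island to the simplex,
    integrates one ecological relaxation time (``relaxation_multiplier *
    M * L``) and returns ``xi_i = sum_j V_ij nu_bar_{j\\i} + s_i -
    Upsilon_bar_{\\i}``.  Expensive; intended for validation on small
    communities.
    """
    row = community.index_of(strain_id)
    work = community.copy()
    v_row = community.V[row, :].copy()
    s_i = float(community.s[row])
    work.drop_rows(np.array([row]))
    colsum = work.nu.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("removal emptied an island; community too small")
    work.nu /= colsum[None, :]
    duration = epoch_length(
        work.params.m, work.L, multiplier=relaxation_multiplier
    )
    avg = integrate(work, duration)
    v_others = np.delete(v_row, row)
    zeta = float(v_others @ avg.nu_bar)
    return zeta + s_i - avg.upsilon_bar


def estimate_bias_by_decay(
    community: Community,
    strain_id: int,
    duration: float,
    record: float = 1.0,
) -> DecayFit:
    """Bias from the exponential decay after switching off migration.

    Zeroes the migration of strain i only, integrates, and fits the slope
    of its island-averaged log abundance against time — the operational
    definition of a negative bias as the strain's decay rate once rescue by
    migration stops.  Returns a ``non_decaying`` status if the strain
    blooms instead.
    """
    row = community.index_of(strain_id)
    work = community.copy()
    work.migration = np.full(work.L, work.params.m)
    work.migration[row] = 0.0
    _, times, traj = integrate(work, duration, record=record, return_trajectory=True)
    series = traj[:, row, :]  # (T, I)
    alive = series > 0
    any_alive = alive.any(axis=1)
    if not any_alive[0]:
        return DecayFit(math.nan, math.nan, math.nan, "non_decaying")
    last = int(np.max(np.flatnonzero(any_alive))) + 1
    mean_log = np.array(
        [np.log(series[k][alive[k]]).mean() for k in range(last)]
    )
    if mean_log.size < 10:
        return DecayFit(math.nan, math.nan, math.nan, "poor_fit")
    res = stats.linregress(times[:last], mean_log)
    r2 = float(res.rvalue**2)
    if res.slope >= 0:
        return DecayFit(float(res.slope), float(res.stderr), r2, "non_decaying")
    status = "ok" if r2 > 0.3 else "poor_fit"
    return DecayFit(float(res.slope), float(res.stderr), r2, status)


def _tail_mean(q: float) -> float:
    """Mean of ell >= 1 under P(ell) ∝ q^ell / ell with q = exp(-beta)."""
    return (q / (1.0 - q)) / (-math.log1p(-q))


def extinction_statistics(summaries: list[EpochSummary]) -> ExtinctionStats:
    """Histogram and tail fit of extinctions per successful invasion.

    Conditions on successful epochs; fits ``beta`` in ``P(ell) ∝
    exp(-beta*ell)/ell`` on ``ell >= 1`` by maximum likelihood (the
    sufficient statistic is the mean, solved by bracketing).  Requires at
    least 30 successful invasions.
    """
    ells = np.array([s.ell for s in summaries if s.invader_succeeded])
    if ells.size < 30:
        raise ValueError(
            f"need >= 30 successful invasions for extinction statistics, "
            f"got {ells.size}"
        )
    counts = np.bincount(ells)
    positive = ells[ells >= 1]
    mean_ell = float(ells.mean())
    if positive.size < 10:
        return ExtinctionStats(
            counts=counts,
            n_successes=int(ells.size),
            beta=None,
            mean_ell=mean_ell,
            status="too_few_positive_counts",
        )
    target = float(positive.mean())
    if target <= 1.0 + 1e-9:
        beta: float | None = math.inf
    else:
        q = optimize.brentq(
            lambda q: _tail_mean(q) - target, 1e-12, 1.0 - 1e-12
        )
        beta = -math.log(q)
    return ExtinctionStats(
        counts=counts,
        n_successes=int(ells.size),
        beta=beta,
        mean_ell=mean_ell,
        status="ok",
    )


def estimate_susceptibility(
    community: Community,
    strain_id: int,
    delta: float | None = None,
    relaxation_multiplier: float = 2.0,
) -> float:
    """Static response ``chi_i = d nu_bar_i / d xi_i`` by central differences.

    Perturbs ``s_i`` by ±delta (default ``0.1 / L_eff`` — large enough to
    dominate chaotic averaging noise, small enough for linear response),
    re-equilibrates with a doubled averaging window, and differences the
    steady-state mean abundance.
    """
    row = community.index_of(strain_id)
    if community.L == 1:
        return 0.0  # lone strain is pinned to nu_bar = 1
    if delta is None:
        base = integrate(
            community.copy(),
            epoch_length(community.params.m, community.L, multiplier=1.0),
        )
        delta = 0.1 / effective_size(base.nu_bar)
    results = []
    for sign in (+1.0, -1.0):
        work = community.copy()
        work.s = work.s.copy()
        work.s[row] += sign * delta
        duration = epoch_length(
            work.params.m, work.L, multiplier=relaxation_multiplier
        )
        avg = integrate(work, duration)
        results.append(float(avg.nu_bar[row]))
    return (results[0] - results[1]) / (2.0 * delta)


def community_fragility(chis: np.ndarray) -> tuple[float, float]:
    """Total response ``X = sum(chi_i)`` and fragility ``Xi = S/(1-S)``.

    ``S = sum(chi_i^2)``; the fragility measures the mean-square response
    of the community to a simultaneous random perturbation of all strains
    (the effect of a successful invasion).  Raises if ``S >= 1`` (divergent
    response).
    """
    chis = np.asarray(chis, dtype=float)
    S = float((chis**2).sum())
    if S >= 1.0:
        raise ValueError(f"sum of squared susceptibilities {S:.3f} >= 1: "
                         "fragility divergent")
    return float(chis.sum()), S / (1.0 - S)


def estimate_critical_bias(
    tables: list[BiasTable],
    registry,
    min_survival_epochs: int = 5,
) -> tuple[float, float]:
    """Empirical critical bias from per-epoch bias tables.

    For each epoch table, takes the minimum bias over strains that remain
    extant for at least ``min_survival_epochs`` further epochs (transient
    marginal strains are excluded); returns the mean and standard
    deviation of these per-epoch minima.  The critical bias is sharp only
    for large communities and many islands; the spread quantifies the
    finite-size rounding.
    """
    minima = []
    for table in tables:
        xs = []
        for sid, xi in zip(table.ids, table.xi):
            rec = registry.records[int(sid)]
            death = rec.death_epoch
            if death is None or death - table.epoch >= min_survival_epochs:
                xs.append(xi)
        if xs:
            minima.append(min(xs))
    if not minima:
        raise ValueError("no surviving strains in any table")
    return float(np.mean(minima)), float(np.std(minima))


def sample_invader_biases(
    community: Community,
    averages: EpochAverages,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Biases ``xi_A = sum_j V_Aj nu_bar_j - Upsilon_bar`` of n fresh invaders.

    Because the V_Aj are fresh unit normals, the result is exactly Gaussian
    with mean ``-Upsilon_bar`` and standard deviation ``sqrt(sum
    nu_bar_j^2) = 1/sqrt(L_eff)``, independent of correlations among the
    extant strains.  (Zero general fitnesses; add draws from P(s) for the
    general-fitness case.)
    """
    nu_bar = averages.nu_bar
    rows = rng.standard_normal((n, nu_bar.size))
    return rows @ nu_bar - averages.upsilon_bar


def distribution_reports(
    bias_table: BiasTable,
    nu_bar: np.ndarray,
    n_bins: int = 30,
) -> dict[str, pd.DataFrame]:
    """Binned abundance and scaled-bias distributions plus a bias rank curve.

    Biases are scaled by ``sqrt(L_eff)`` (the invader-bias standard
    deviation is ``1/sqrt(L_eff)``), the natural units in which evolved
    and assembled communities can be compared.  Binning is deterministic:
    identical inputs yield identical tables.
    """
    L_eff = effective_size(nu_bar)
    scaled = bias_table.xi * math.sqrt(L_eff)

    abund_edges = np.linspace(0.0, float(nu_bar.max()) * (1 + 1e-12), n_bins + 1)
    abund_hist, _ = np.histogram(nu_bar, bins=abund_edges)
    abund = pd.DataFrame(
        {
            "bin_left": abund_edges[:-1],
            "bin_right": abund_edges[1:],
            "count": abund_hist,
        }
    )

    lo, hi = float(scaled.min()), float(scaled.max())
    pad = 1e-12 * max(1.0, abs(hi))
    bias_edges = np.linspace(lo, hi + pad, n_bins + 1)
    bias_hist, _ = np.histogram(scaled, bins=bias_edges)
    bias = pd.DataFrame(
        {
            "bin_left": bias_edges[:-1],
            "bin_right": bias_edges[1:],
            "count": bias_hist,
        }
    )

    order = np.argsort(scaled)
    rank = pd.DataFrame(
        {
            "rank": np.arange(scaled.size),
            "strain_id": bias_table.ids[order],
            "xi_scaled": scaled[order],
        }
    )
    return {"abundance": abund, "bias": bias, "bias_rank": rank}
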