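"""Serial-invasion evolution protocol.

Evolution proceeds in the quasistatic limit: long ecological epochs
separated by the introduction of a single new strain (an unrelated invader
or a rho-correlated mutant of an abundance-weighted parent).  Each epoch
lasts ``epoch_multiplier * M * L`` with ``M = ln(1/m)`` — several ecological
relaxation times — after which global extinctions are flushed permanently
and the epoch summary recorded.  The new strain is introduced at abundance
``1/L`` on every island simultaneously (a "could it invade" assay that
bypasses the stochastic low-abundance establishment phase), with resident
abundances scaled down proportionately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import rng as rng_mod
from .community import Community, EmptyCommunityError, StrainRegistry
from .dynamics import EpochAverages, integrate
from .params import ModelParams
from .sampling import (
    InvaderDraw,
    choose_parent,
    sample_general_fitnesses,
    sample_interaction_matrix,
    sample_mutant,
    sample_unrelated_invader,
)

__all__ = [
    "EpochSummary",
    "run_assembly",
    "introduce_strain",
    "epoch_length",
    "run_evolution",
    "classify_outcome",
    "diversification_rate",
]


@dataclass
class EpochSummary:
    """Per-epoch bookkeeping of the serial-invasion process."""

    T: int  # attempted-invasion index
    L: int  # extant strain count at epoch end
    Z: int  # cumulative successful invasions
    invader_succeeded: bool
    ell: int  # extinctions of previously extant strains this epoch
    s_hat: float  # population-weighted mean general fitness
    L_eff: float  # effective community size 1 / sum(nu_bar^2)
    upsilon_bar: float
    epoch_duration: float
    invader_id: int = -1

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "L": self.L,
            "Z": self.Z,
            "invader_succeeded": int(self.invader_succeeded),
            "ell": self.ell,
            "s_hat": self.s_hat,
            "L_eff": self.L_eff,
            "upsilon_bar": self.upsilon_bar,
            "epoch_duration": self.epoch_duration,
            "invader_id": self.invader_id,
        }


def epoch_length(m: float, L: int, multiplier: float = 3.0) -> float:
    """Epoch duration ``multiplier * M * L`` with ``M = ln(1/m)``.

    ``M * L`` is the ecological relaxation time of the chaotic steady
    state; the default multiplier of 3 leaves ample margin (a tenfold
    longer epoch changes the diversification dynamics little).
    """
    if L < 1:
        raise ValueError("epoch length requires at least one extant strain")
    M = math.log(1.0 / m)
    return multiplier * M * L


def run_assembly(
    params: ModelParams,
) -> tuple[Community, int, EpochAverages]:
    """Assemble K unrelated strains and relax to the persistent community.

    Samples the interaction matrix and general fitnesses, starts every
    island from an independent uniform-on-the-simplex abundance draw
    (maximally desynchronized initial conditions), integrates one epoch and
    removes global extinctions permanently.  Returns the surviving
    community, its size ``L0`` and the steady-state epoch averages
    (restricted to survivors, renormalised).
    """
    rng_asm = rng_mod.stream(params.seed, "assembly")
    rng_fit = rng_mod.stream(params.seed, "fitness")
    rng_init = rng_mod.stream(params.seed, "init")

    V = sample_interaction_matrix(params.K, params.gamma, rng_asm)
    s = sample_general_fitnesses(params.K, params.Sigma, params.psi, rng_fit)
    # Independent uniform-on-simplex initial conditions per island.
    nu = rng_init.exponential(size=(params.K, params.I))
    nu /= nu.sum(axis=0)[None, :]

    registry = StrainRegistry()
    ids = np.array([registry.new_strain(s=s[i], birth_epoch=0) for i in range(params.K)])
    community = Community(params=params, V=V, s=s, nu=nu, ids=ids, registry=registry)

    duration = epoch_length(params.m, params.K, params.epoch_multiplier)
    averages = integrate(community, duration)
    survivors = (community.nu > 0).any(axis=1)
    nu_bar = averages.nu_bar[survivors]
    community.flush_global_extinctions(epoch=0)
    L0 = community.L
    if L0 == 0:
        warnings.warn("all strains went extinct during assembly (L0 = 0)", stacklevel=2)
        return community, 0, averages
    averages = EpochAverages(
        nu_bar=nu_bar / nu_bar.sum() if nu_bar.sum() > 0 else nu_bar,
        upsilon_bar=averages.upsilon_bar,
        C0=averages.C0,
        window=averages.window,
        n_samples=averages.n_samples,
    )
    return community, L0, averages


def introduce_strain(community: Community, draw: InvaderDraw, sid: int) -> None:
    """Add a new strain at abundance 1/L on every island simultaneously.

    ``L`` is the extant count immediately before introduction; resident
    abundances are scaled by ``1 - 1/L`` so each island stays exactly on
    the simplex.  Requires ``L >= 2``: with a lone resident the protocol
    would replace the community outright.
    """
    L = community.L
    if L < 2:
        raise EmptyCommunityError(
            f"introduction requires at least 2 extant strains, have {L}"
        )
    inv_abund = 1.0 / L
    community.nu *= 1.0 - inv_abund
    community.append_strain(draw, sid)
    community.nu[-1, :] = inv_abund


def run_evolution(
    community: Community,
    T_max: int,
    mode: str = "unrelated",
    averages: EpochAverages | None = None,
    rng_invaders: np.random.Generator | None = None,
    rng_mutants: np.random.Generator | None = None,
    checkpoint_every: int = 0,
    checkpoint_callback=None,
    T_start: int = 1,
    Z_start: int = 0,
) -> list[EpochSummary]:
    """Run ``T_max`` attempted invasions; returns one summary per epoch.

    ``mode`` selects unrelated invaders or rho-correlated mutants (parent
    chosen with probability proportional to its steady-state mean
    abundance from the previous epoch).  The invader counts as successful
    iff it is still extant at the end of its introduction epoch; the
    bookkeeping identity ``L(T) = L(T-1) + success - ell`` holds exactly.
    Terminates early if the community crashes below 2 strains.
    """
    if mode not in ("unrelated", "mutant"):
        raise ValueError(f"mode must be 'unrelated' or 'mutant', got {mode!r}")
    p = community.params
    if rng_invaders is None:
        rng_invaders = rng_mod.stream(p.seed, "invaders")
    if rng_mutants is None:
        rng_mutants = rng_mod.stream(p.seed, "mutants")

    summaries: list[EpochSummary] = []
    Z = Z_start
    prev_nu_bar = None if averages is None else averages.nu_bar

    for T in range(T_start, T_start + T_max):
        L_before = community.L
        if L_before < 2:
            break  # community crashed; nothing left to invade

        if mode == "unrelated":
            draw = sample_unrelated_invader(
                L_before, p.gamma, p.Sigma, p.psi, rng_invaders
            )
            parent_id = None
        else:
            weights = (
                prev_nu_bar
                if prev_nu_bar is not None and prev_nu_bar.size == L_before
                else community.nu_bar
            )
            parent_row = choose_parent(weights, rng_mutants)
            parent_id = int(community.ids[parent_row])
            draw = sample_mutant(
                community.V,
                parent_row,
                p.gamma,
                p.rho,
                s_parent=float(community.s[parent_row]),
                rho_s=p.rho_s,
                Sigma=p.Sigma,
                psi=p.psi,
                rng=rng_mutants,
            )

        sid = community.registry.new_strain(s=draw.s, parent_id=parent_id, birth_epoch=T)
        introduce_strain(community, draw, sid)

        duration = epoch_length(p.m, community.L, p.epoch_multiplier)
        epoch_avg = integrate(community, duration)

        # Epoch statistics are computed over the pre-flush strain set; the
        # soon-dead strains have near-zero steady-state weight anyway.
        nu_bar_full = epoch_avg.nu_bar
        s_hat = float(nu_bar_full @ community.s)
        sq = float((nu_bar_full**2).sum())
        L_eff = 1.0 / sq if sq > 0 else float("nan")

        survivors = (community.nu > 0).any(axis=1)
        surviving_nu_bar = nu_bar_full[survivors]
        dead_ids = community.flush_global_extinctions(epoch=T)
        succeeded = sid not in dead_ids
        ell = len(dead_ids) - (0 if succeeded else 1)
        Z += int(succeeded)

        tot = surviving_nu_bar.sum()
        prev_nu_bar = surviving_nu_bar / tot if tot > 0 else surviving_nu_bar

        summaries.append(
            EpochSummary(
                T=T,
                L=community.L,
                Z=Z,
                invader_succeeded=succeeded,
                ell=ell,
                s_hat=s_hat,
                L_eff=L_eff,
                upsilon_bar=epoch_avg.upsilon_bar,
                epoch_duration=duration,
                invader_id=sid,
            )
        )
        if (
            checkpoint_every
            and checkpoint_callback is not None
            and T % checkpoint_every == 0
        ):
            checkpoint_callback(community, T, summaries)

    return summaries


def classify_outcome(
    summaries: list[EpochSummary],
    L_crash: int = 5,
    slope_threshold: float = 0.05,
) -> str:
    """Classify a run as ``diversifying``, ``crashed`` or ``undetermined``.

    Crashed: final L at or below ``L_crash`` sustained over the last 20
    epochs.  Diversifying: least-squares slope of L(T) over the final half
    exceeds ``slope_threshold`` per attempt and L ended above its starting
    value.  Otherwise undetermined (e.g. a saturated plateau).
    """
    if len(summaries) < 50:
        raise ValueError("classification requires at least 50 recorded epochs")
    L_series = np.array([s.L for s in summaries])
    T_series = np.array([s.T for s in summaries])
    if np.all(L_series[-20:] <= L_crash):
        return "crashed"
    half = len(summaries) // 2
    slope = stats.linregress(T_series[half:], L_series[half:]).slope
    if slope > slope_threshold and L_series[-1] > L_series[0]:
        return "diversifying"
    return "undetermined"


def diversification_rate(
    summaries: list[EpochSummary],
    window: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Average diversification rate ``U = <dL/dT>`` with its standard error.

    Least-squares slope of L versus T over ``window`` (inclusive T-range;
    default: all recorded epochs).  Requires at least 10 epochs.
    """
    T_series = np.array([s.T for s in summaries])
    L_series = np.array([s.L for s in summaries], dtype=float)
    if window is not None:
        lo, hi = window
        mask = (T_series >= lo) & (T_series <= hi)
        T_series, L_series = T_series[mask], L_series[mask]
    if T_series.size < 10:
        raise ValueError("diversification rate requires a window of >= 10 epochs")
    if np.allclose(L_series, L_series[0]):
        return 0.0, 0.0
    res = stats.linregress(T_series, L_series)
    return float(res.slope), float(res.stderr)
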