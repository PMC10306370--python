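"""Bias estimators, effective size, extinction statistics, susceptibility."""

import math

import numpy as np
import pytest
from scipy import stats

from stcsim.dynamics import integrate
from stcsim.evolution import epoch_length
from stcsim.fixtures import PLANTED_S, make_fixture
from stcsim.observables import (
    BiasTable,
    community_fragility,
    distribution_reports,
    effective_size,
    estimate_bias_by_decay,
    estimate_bias_leave_in,
    estimate_bias_leave_one_out,
    estimate_susceptibility,
    extinction_statistics,
    mean_fitness,
    sample_invader_biases,
)
from stcsim.params import ModelParams
from tests_util_summaries import make_summaries_with_ells

from conftest import build_community


class TestEffectiveSize:
    def test_uniform(self):
        assert effective_size(np.full(25, 1 / 25)) == pytest.approx(25.0)

    def test_single(self):
        v = np.zeros(10)
        v[0] = 1.0
        assert effective_size(v) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert effective_size(np.array([0.5, 0.3, 0.2])) == pytest.approx(1 / 0.38)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            effective_size(np.zeros(4))


class TestMeanFitness:
    def test_constant_fitness(self):
        nu = np.array([0.2, 0.3, 0.5])
        assert mean_fitness(nu, np.full(3, 0.7)) == pytest.approx(0.7)

    def test_arithmetic(self):
        assert mean_fitness(np.array([0.5, 0.5]), np.array([0.0, 0.1])) == (
            pytest.approx(0.05)
        )

    def test_constant_shift_invariance(self, rng):
        nu = rng.dirichlet(np.ones(8))
        s = rng.normal(size=8)
        assert mean_fitness(nu, s + 3.0) == pytest.approx(mean_fitness(nu, s) + 3.0)


class TestLeaveInBias:
    def test_planted_three_strain_arithmetic(self):
        # hand-computed zeta and xi for fixed V, nu_bar, Upsilon
        from stcsim.dynamics import EpochAverages

        V = np.array([[0.1, 1.0, -2.0], [0.5, -0.3, 1.5], [-1.0, 2.0, 0.2]])
        nu_bar = np.array([0.5, 0.3, 0.2])
        s = np.array([0.0, 0.05, -0.05])
        params = ModelParams(gamma=0.0, m=1e-3, I=2, N=1e9, K=3)
        comm = build_community(V, s, np.tile(nu_bar[:, None], (1, 2)), params)
        avg = EpochAverages(
            nu_bar=nu_bar, upsilon_bar=0.4, C0=0.38, window=(0, 1), n_samples=1
        )
        table = estimate_bias_leave_in(comm, avg)
        # zeta_1 = V12*0.3 + V13*0.2 = 0.3 - 0.4 = -0.1
        assert table.zeta[0] == pytest.approx(1.0 * 0.3 + (-2.0) * 0.2)
        assert table.xi[0] == pytest.approx(-0.1 + 0.0 - 0.4)
        # zeta excludes the self-interaction term
        assert table.zeta[1] == pytest.approx(0.5 * 0.5 + 1.5 * 0.2)

    def test_noninteracting_strains_match_leave_one_out(self):
        # With zero off-diagonal interactions removing a strain changes
        # nothing, so the cheap and expensive estimators agree.
        K = 4
        params = ModelParams(gamma=0.0, m=1e-2, I=3, N=1e9, K=K, dt=0.02)
        nu = np.full((K, 3), 1.0 / K)
        comm = build_community(np.zeros((K, K)), np.zeros(K), nu, params)
        avg = integrate(comm.copy(), 200.0)
        table = estimate_bias_leave_in(comm, avg)
        loo = estimate_bias_leave_one_out(comm, int(comm.ids[0]))
        assert table.xi[0] == pytest.approx(loo, abs=1e-6)


class TestDecayEstimator:
    def test_planted_fitness_recovered(self):
        # Planted-decay oracle: a strain with known negative general fitness
        # in an interaction-free background decays at rate ~ s once its
        # migration is switched off.
        comm = make_fixture("planted_decay")
        sid = int(comm.ids[-1])
        fit = estimate_bias_by_decay(comm, sid, duration=40.0)
        assert fit.status == "ok"
        assert fit.xi == pytest.approx(PLANTED_S, rel=0.2)

    def test_positive_bias_reports_non_decaying(self):
        comm = make_fixture("planted_decay")
        # flip the planted strain's fitness: it should bloom, not decay
        comm.s = comm.s.copy()
        comm.s[-1] = +0.2
        fit = estimate_bias_by_decay(comm, int(comm.ids[-1]), duration=40.0)
        assert fit.status == "non_decaying"


class TestExtinctionStatistics:
    def test_beta_recovery_parametric(self, rng):
        # Parametric-bootstrap oracle: draw ell from P(ell) ∝ exp(-b*ell)/ell
        # on ell >= 1 with known b, mixed with ell=0 epochs, and recover b.
        beta_true = 1.0
        ells_support = np.arange(1, 60)
        p = np.exp(-beta_true * ells_support) / ells_support
        p /= p.sum()
        draws = rng.choice(ells_support, size=3000, p=p)
        zeros = np.zeros(1000, dtype=int)
        all_ells = np.concatenate([draws, zeros])
        rng.shuffle(all_ells)
        stats_out = extinction_statistics(make_summaries_with_ells(all_ells))
        assert stats_out.status == "ok"
        assert stats_out.beta == pytest.approx(beta_true, abs=0.1)

    def test_all_zero_ells(self):
        stats_out = extinction_statistics(make_summaries_with_ells([0] * 50))
        assert stats_out.beta is None
        assert stats_out.status == "too_few_positive_counts"
        assert stats_out.counts[0] == 50

    def test_mean_matches_histogram(self, rng):
        ells = rng.integers(0, 5, size=60)
        out = extinction_statistics(make_summaries_with_ells(ells))
        hist_mean = (np.arange(len(out.counts)) * out.counts).sum() / out.n_successes
        assert out.mean_ell == pytest.approx(hist_mean)
        assert out.counts.sum() == out.n_successes

    def test_too_few_successes_rejected(self):
        with pytest.raises(ValueError):
            extinction_statistics(make_summaries_with_ells([1] * 10))


class TestSusceptibility:
    def test_fragility_arithmetic(self):
        X, Xi = community_fragility(np.array([0.2, 0.4]))
        assert X == pytest.approx(0.6)
        assert Xi == pytest.approx(0.2 / 0.8)

    def test_fragility_divergence_flagged(self):
        with pytest.raises(ValueError):
            community_fragility(np.array([0.8, 0.8]))

    def test_single_strain_pinned(self):
        params = ModelParams(gamma=0.0, m=1e-3, I=2, N=1e9, K=1)
        comm = build_community([[0.0]], [0.0], np.ones((1, 2)), params)
        assert estimate_susceptibility(comm, int(comm.ids[0])) == 0.0

    def test_noninteracting_response_sign(self):
        # In an interaction-free community a fitness bump raises the
        # strain's steady abundance: chi > 0.
        K = 5
        params = ModelParams(gamma=0.0, m=1e-2, I=2, N=1e9, K=K, dt=0.02)
        nu = np.full((K, 2), 1.0 / K)
        comm = build_community(np.zeros((K, K)), np.zeros(K), nu, params)
        chi = estimate_susceptibility(comm, int(comm.ids[0]), delta=0.02)
        assert chi > 0


class TestInvaderBiasLaw:
    def test_exact_gaussian_construction(self, small_stc, rng):
        # For a frozen community the invader bias is a dot product of fresh
        # unit normals with nu_bar: exactly Gaussian, mean -Upsilon_bar,
        # sd 1/sqrt(L_eff).
        comm, avg = small_stc
        xi = sample_invader_biases(comm, avg, 10**4, rng)
        sd_expected = 1.0 / math.sqrt(effective_size(avg.nu_bar))
        assert xi.mean() == pytest.approx(-avg.upsilon_bar, abs=4 * sd_expected / 100)
        assert xi.std() == pytest.approx(sd_expected, rel=0.03)
        assert stats.normaltest(xi).pvalue > 1e-3


class TestDistributionReports:
    def test_deterministic_and_consistent(self, small_stc):
        comm, avg = small_stc
        table = estimate_bias_leave_in(comm, avg)
        r1 = distribution_reports(table, avg.nu_bar)
        r2 = distribution_reports(table, avg.nu_bar)
        for key in r1:
            assert r1[key].equals(r2[key])
        assert r1["abundance"]["count"].sum() == comm.L
        assert r1["bias"]["count"].sum() == comm.L
        # rank curve is sorted
        ranks = r1["bias_rank"]["xi_scaled"].to_numpy()
        assert np.all(np.diff(ranks) >= 0)


class TestCrossEstimatorValidation:
    def test_planted_strain_decay_in_chaotic_background(self, small_stc):
        # A zero-interaction strain with known negative fitness planted in
        # a relaxed chaotic community has exact bias s - Upsilon_bar; the
        # decay estimator must recover it within 30%.
        from stcsim.community import Community
        from stcsim.sampling import InvaderDraw
        import numpy as np

        comm, avg = small_stc
        work = comm.copy()
        s_plant = -0.25
        draw = InvaderDraw(
            row=np.zeros(work.L), col=np.zeros(work.L),
            self_interaction=0.0, s=s_plant,
        )
        sid = work.registry.new_strain(s=s_plant)
        work.append_strain(draw, sid)
        work.nu[-1, :] = 1e-3
        work.nu /= work.nu.sum(axis=0)[None, :]
        expected = s_plant - avg.upsilon_bar
        fit = estimate_bias_by_decay(work, sid, duration=60.0)
        assert fit.status == "ok"
        assert fit.xi == pytest.approx(expected, rel=0.3)

    def test_leave_one_out_bias_tracks_abundance(self):
        # Theory: steady-state mean abundance is an increasing function of
        # the (leave-one-out) bias, so across strains the two must rank
        # together.  Desk-scale check on a small chaotic community.
        from stcsim.evolution import run_assembly

        params = ModelParams(gamma=-0.8, m=1e-3, I=8, N=1e8, K=40, seed=21)
        comm, L0, avg = run_assembly(params)
        loos = [
            estimate_bias_leave_one_out(comm, int(sid)) for sid in comm.ids
        ]
        rho = stats.spearmanr(avg.nu_bar, loos).statistic
        assert rho > 0.5

    def test_typical_bias_shrinks_with_community_size(self, small_stc):
        # Across assembled communities of different size, typical bias
        # magnitudes decrease as the community grows.
        from stcsim.evolution import run_assembly

        params = ModelParams(gamma=-0.8, m=1e-3, I=5, N=1e8, K=15, seed=33)
        small_comm, _, small_avg = run_assembly(params)
        big_comm, big_avg = small_stc
        t_small = estimate_bias_leave_in(small_comm, small_avg)
        t_big = estimate_bias_leave_in(big_comm, big_avg)
        assert np.median(np.abs(t_big.xi)) < np.median(np.abs(t_small.xi))


class TestCriticalBias:
    def test_excludes_transient_strains(self):
        from stcsim.community import StrainRegistry
        from stcsim.observables import estimate_critical_bias

        reg = StrainRegistry()
        ids = [reg.new_strain(0.0) for _ in range(3)]
        reg.mark_dead(ids[0], epoch=2)  # dies right after epoch 0: excluded
        tables = [
            BiasTable(
                ids=np.array(ids),
                xi=np.array([-0.9, -0.3, 0.1]),
                zeta=np.zeros(3),
                estimator="leave_in",
                epoch=0,
            )
        ]
        mean_xc, spread = estimate_critical_bias(tables, reg, min_survival_epochs=5)
        assert mean_xc == pytest.approx(-0.3)
        assert spread == 0.0
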