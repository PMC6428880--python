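"""Exact simulation, histogram estimation and the finite-state CME oracle."""

import numpy as np
import pytest
from scipy import stats

from stochmet import (
    SystemState,
    Trajectory,
    EventBudgetExceeded,
    propensities,
    simulate,
    stationary_histogram,
    run_stationary_histogram,
    cme_stationary,
    cme_marginal,
    birth_death_reactions,
    three_stage_reactions,
    poisson_parameter,
    reduced_propensities,
    three_stage_params,
    three_stage_pmf,
    total_variation,
    pmm_distribution,
    pmm_moments,
)
from stochmet.ssa import STATE_CHANGES, ZERO_STATE, Reaction


class TestPropensities:
    def test_empty_state_only_promoter_activation(self, table1):
        rates = propensities(ZERO_STATE, table1)
        assert rates[6] == table1.k_on
        rates[6] = 0.0
        assert np.all(rates == 0.0)

    def test_binding_dominates_for_free_enzyme_pool(self, table1):
        state = SystemState(dna_on=1, n_m=1, n_e=100, n_c=0, n_p=0)
        rates = propensities(state, table1)
        assert rates[0] == pytest.approx(3.0e5)
        assert rates[0] == rates.max()

    def test_total_enzyme_changes_only_by_translation_and_dilution(self):
        # bookkeeping: net change of n_e + n_c per reaction channel
        net = STATE_CHANGES[:, 2] + STATE_CHANGES[:, 3]
        expected = np.zeros(12, dtype=int)
        expected[4] = +1   # translation
        expected[10] = -1  # enzyme dilution
        expected[11] = -1  # complex dilution
        assert np.array_equal(net, expected)


class TestSimulate:
    def test_absorbing_zero_state(self, table1):
        traj = simulate(table1.with_(k_on=0.0), 100.0, seed=1)
        assert traj.states.max() == 0
        assert traj.n_events == 0

    def test_seed_reproducibility(self, table1):
        rc = table1.scaled_binding(100.0)
        a = simulate(rc, 2000.0, seed=7)
        b = simulate(rc, 2000.0, seed=7)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        c = simulate(rc, 2000.0, seed=8)
        assert not np.array_equal(a.states, c.states)

    def test_event_budget_refusal(self, table1):
        with pytest.raises(EventBudgetExceeded, match="budget"):
            simulate(table1, 1e4, seed=1, max_events=10_000)

    def test_time_average_matches_mixture_mean(self, table1):
        # 50 cell cycles, burn-in 10; batch-means standard error
        rc = table1.scaled_binding(10.0)
        cyc = rc.doubling_time
        res = run_stationary_histogram(rc, 50 * cyc, seed=21, burn_in=10 * cyc)
        enz = three_stage_pmf(three_stage_params(rc))
        m_pred, _ = pmm_moments(enz, poisson_parameter(rc))
        batches = [
            run_stationary_histogram(rc, 20 * cyc, seed=s, burn_in=10 * cyc)["n_p"].mean()
            for s in (22, 23, 24, 25)
        ]
        se = np.std(batches, ddof=1) / np.sqrt(len(batches))
        assert abs(res["n_p"].mean() - m_pred) < 3 * max(se, 1.0)

    def test_trajectory_table_round_trip(self, table1, tmp_path):
        traj = simulate(table1.scaled_binding(100.0), 500.0, seed=3)
        path = tmp_path / "traj.tsv"
        traj.write(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# seed\t3")
        assert len(lines) == 5 + traj.times.size


class TestStationaryHistogram:
    def test_constant_trajectory_is_point_mass(self, table1):
        traj = Trajectory(
            times=np.array([0.0, 1.0, 2.0]),
            states=np.tile([1, 0, 0, 0, 4], (3, 1)),
            rc=table1, seed=0, t_end=3.0, thinned=False,
        )
        pmf = stationary_histogram(traj, burn_in=0.0, species="n_p")
        assert pmf.probs[4] == pytest.approx(1.0)

    def test_two_state_occupancy_fractions(self, table1):
        # 30% of the time at 0, 70% at 5
        traj = Trajectory(
            times=np.array([0.0, 3.0]),
            states=np.array([[1, 0, 0, 0, 0], [1, 0, 0, 0, 5]]),
            rc=table1, seed=0, t_end=10.0, thinned=False,
        )
        pmf = stationary_histogram(traj, burn_in=0.0, species="n_p")
        assert pmf.probs[0] == pytest.approx(0.3)
        assert pmf.probs[5] == pytest.approx(0.7)

    def test_stationary_law_independent_of_initial_state(self, downscaled_rc):
        from_zero = run_stationary_histogram(downscaled_rc, 2e6, seed=31,
                                             burn_in=5e4)
        loaded = SystemState(dna_on=1, n_m=2, n_e=10, n_c=5, n_p=15)
        from_loaded = run_stationary_histogram(downscaled_rc, 2e6, seed=32,
                                               burn_in=5e4,
                                               initial_state=loaded)
        assert total_variation(from_zero["n_p"], from_loaded["n_p"]) < 0.05
        assert total_variation(from_zero["n_etot"], from_loaded["n_etot"]) < 0.05

    def test_streaming_and_trajectory_histograms_agree(self, downscaled_rc):
        # independent realisations of a fast-mixing system: the streaming
        # expected-holding-time estimator and the exact-clock trajectory
        # histogram must converge to the same law
        res = run_stationary_histogram(downscaled_rc, 1e6, seed=9, burn_in=5e4)
        traj = simulate(downscaled_rc, 1e6, seed=10, burn_in=5e4)
        in_run = stationary_histogram(traj, burn_in=5e4, species="n_etot")
        assert total_variation(res["n_etot"], in_run) < 0.05


class TestCMEOracle:
    def test_birth_death_is_poisson(self):
        pi = cme_stationary(birth_death_reactions(5.0, 1.0), caps=[60])
        np.testing.assert_allclose(pi.reshape(-1),
                                   stats.poisson.pmf(np.arange(61), 5.0),
                                   atol=1e-8)

    def test_reduced_birth_death_matches_lambda_map(self, table1):
        # the reduced metabolite process at fixed n_etot is Poisson(lambda)
        for n_etot in (1, 8, 40):
            birth, death = reduced_propensities(table1, n_etot)
            lam = poisson_parameter(table1).lam(n_etot)
            cap = int(lam + 10 * np.sqrt(lam) + 20)
            pi = cme_stationary(birth_death_reactions(birth, death), caps=[cap])
            np.testing.assert_allclose(
                pi.reshape(-1), stats.poisson.pmf(np.arange(cap + 1), lam),
                atol=1e-8)

    def test_small_cap_signalled(self):
        with pytest.raises(ValueError, match="boundary mass"):
            cme_stationary(birth_death_reactions(50.0, 1.0), caps=[20])

    def test_state_space_cap_enforced(self):
        with pytest.raises(ValueError, match="exceeds cap"):
            cme_stationary(birth_death_reactions(5.0, 1.0), caps=[10**7])

    def test_three_stage_marginal_matches_closed_form(self, table1):
        rc = table1.with_(k_tx=table1.k_tx / 4.0)
        pi = cme_stationary(three_stage_reactions(rc), caps=[1, 12, 90])
        prot = cme_marginal(pi, 2)
        closed = three_stage_pmf(three_stage_params(rc))
        assert total_variation(closed, prot) < 1e-3
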