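"""Simulation engine: determinism, synchrony, record schema, exact oracle."""

import numpy as np
import pandas as pd
import pytest

from bmcoop import (
    HARD,
    LearnerParams,
    PayoffMatrix,
    PGGParams,
    PopulationSpec,
    RunConfig,
    complete_group,
    enumerate_small_pdg,
    realized_prob,
    run_ensemble,
    run_noisy_grim,
    run_pdg,
    run_pgg,
    square_lattice,
)


@pytest.fixture(scope="module")
def small_result():
    return run_pdg(
        square_lattice(3), LearnerParams(beta=0.2, A=0.5), t_max=5, n_runs=4, seed=99
    )


class TestPDGEngine:
    def test_reproducible_byte_identical(self, small_result):
        again = run_pdg(
            square_lattice(3), LearnerParams(beta=0.2, A=0.5), t_max=5, n_runs=4, seed=99
        )
        a, b = small_result.to_records(), again.to_records()
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_record_count_is_runs_by_players_by_rounds(self, small_result):
        df = small_result.to_records()
        assert len(df) == 4 * 9 * 5 == small_result.n_records

    def test_round_one_has_no_fc(self, small_result):
        df = small_result.to_records()
        assert df.loc[df["t"] == 1, "f_C_prev"].isna().all()
        assert df.loc[df["t"] > 1, "f_C_prev"].notna().all()

    def test_recorded_payoffs_consistent_with_actions(self, small_result):
        net = square_lattice(3)
        df = small_result.to_records()
        M = PayoffMatrix()
        for (run, t), grp in df.groupby(["run_id", "t"]):
            acts = grp.sort_values("player_id")["action"].to_numpy()
            for i in range(net.n):
                nbrs = acts[net.neighbors[i]]
                f = (nbrs == "C").mean()
                expect = M.R * f + M.S * (1 - f) if acts[i] == "C" else M.T * f + M.P * (1 - f)
                got = grp.loc[grp["player_id"] == i, "payoff"].iloc[0]
                assert got == pytest.approx(expect)

    def test_realized_ptilde_is_error_corrupted_intended_p(self, small_result):
        df = small_result.to_records()
        expect = realized_prob(df["intended_p"].to_numpy(), 0.2)
        assert np.allclose(df["realized_ptilde"].to_numpy(), expect)

    def test_mean_cooperation_within_epsilon_band(self, mcc_result):
        m = mcc_result.mean_cooperation_per_round()
        assert np.all(m >= 0.2 - 1e-12) and np.all(m <= 0.8 + 1e-12)

    def test_distinct_seeds_agree_within_sampling_error(self, lattice10):
        params = LearnerParams(beta=0.2, A=0.5)
        r1 = run_pdg(lattice10, params, t_max=25, n_runs=120, seed=1)
        r2 = run_pdg(lattice10, params, t_max=25, n_runs=120, seed=2)
        m1 = r1.ptilde.mean(axis=(1, 2))
        m2 = r2.ptilde.mean(axis=(1, 2))
        se = np.hypot(m1.std() / np.sqrt(m1.size), m2.std() / np.sqrt(m2.size))
        assert abs(m1.mean() - m2.mean()) < 3 * se

    def test_update_on_intended_changes_trajectories(self, lattice10):
        params = LearnerParams(beta=0.4, A=0.5)
        r_imp = run_pdg(lattice10, params, t_max=10, n_runs=5, seed=3)
        r_int = run_pdg(lattice10, params, t_max=10, n_runs=5, seed=3, update_on="intended")
        assert not np.allclose(r_imp.intended_p, r_int.intended_p)

    def test_invalid_configuration_rejected_before_running(self, lattice10):
        with pytest.raises(ValueError):
            run_pdg(lattice10, LearnerParams(), t_max=0)
        with pytest.raises(ValueError):
            run_pdg(lattice10, LearnerParams(), update_on="other")


class TestDefectors:
    def test_defector_count_and_behavior(self, lattice10):
        res = run_pdg(
            lattice10,
            LearnerParams(beta=0.4, A=0.5),
            pop=PopulationSpec(defector_fraction=0.3),
            t_max=10,
            n_runs=6,
            seed=5,
        )
        assert res.defectors.sum(axis=1).tolist() == [30] * 6
        # defectors never cooperate, with no implementation noise
        assert not res.action[np.broadcast_to(res.defectors[:, None, :], res.action.shape)].any()
        df = res.to_records()
        assert (df["role"] == "defector").sum() == 30 * 10 * 6

    def test_placement_varies_across_runs(self, lattice10):
        res = run_pdg(
            lattice10,
            LearnerParams(),
            pop=PopulationSpec(defector_fraction=0.2),
            t_max=2,
            n_runs=8,
            seed=6,
        )
        assert len({tuple(np.flatnonzero(row)) for row in res.defectors}) > 1

    def test_fraction_above_half_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(defector_fraction=0.6)


class TestStrategyLimitsInEngine:
    def test_pavlov_pair_sustains_mutual_cooperation(self):
        # hard stimulus, P < A < R, eps = 0, both start at p = 1
        res = run_pdg(
            complete_group(2),
            LearnerParams(beta=HARD, A=2.0, epsilon=0.0, p_init=1.0),
            t_max=10,
            n_runs=3,
            seed=7,
        )
        assert res.action.all()
        assert (res.payoff == 3.0).all()

    def test_grim_regime_defection_is_absorbing(self):
        # hard stimulus, S < A < P, eps = 0: after the first D, D forever
        res = run_pdg(
            complete_group(3),
            LearnerParams(beta=HARD, A=0.5, epsilon=0.0, p_init=0.5),
            t_max=8,
            n_runs=10,
            seed=8,
        )
        coop = res.action  # (runs, t, players)
        ever_defected = np.logical_or.accumulate(~coop, axis=1)
        # wherever a defection has happened at t, the action at t+1 is D
        assert not (ever_defected[:, :-1, :] & coop[:, 1:, :]).any()


class TestEnumerationOracle:
    def test_single_round_equals_realized_prob(self):
        params = LearnerParams(beta=0.3, A=1.0, epsilon=0.1, p_init=0.7)
        out = enumerate_small_pdg(params, n_players=2, t_max=1)
        assert out[0] == pytest.approx(realized_prob(0.7, 0.1))

    def test_pavlov_regime_stays_fully_cooperative(self):
        params = LearnerParams(beta=HARD, A=2.0, epsilon=0.0, p_init=1.0)
        out = enumerate_small_pdg(params, n_players=2, t_max=5)
        assert np.allclose(out, 1.0)

    def test_matches_monte_carlo_within_three_se(self):
        params = LearnerParams(beta=0.2, A=0.5, epsilon=0.2)
        exact = enumerate_small_pdg(params, n_players=2, t_max=4)
        res = run_pdg(complete_group(2), params, t_max=4, n_runs=30_000, seed=10)
        mc = res.ptilde.mean(axis=(0, 2))
        se = res.ptilde.mean(axis=2).std(axis=0) / np.sqrt(res.n_runs)
        # round 1 is exact by construction; later rounds within 3 SE
        assert mc[0] == exact[0] == 0.5
        assert np.all(np.abs(mc[1:] - exact[1:]) < 3 * se[1:])

    def test_three_player_system_supported(self):
        params = LearnerParams(beta=0.2, A=0.5, epsilon=0.1)
        out = enumerate_small_pdg(params, n_players=3, t_max=3)
        assert out.shape == (3,)
        assert np.all((out >= 0.1) & (out <= 0.9))

    def test_size_guard(self):
        with pytest.raises(ValueError):
            enumerate_small_pdg(LearnerParams(), n_players=4)
        with pytest.raises(ValueError):
            enumerate_small_pdg(LearnerParams(), t_max=7)


class TestPGGEngine:
    def test_contributions_in_unit_interval_and_shapes(self):
        res = run_pgg(PGGParams(beta=0.4, A=0.9, X=0.3), t_max=6, n_groups=5, n_runs=3, seed=11)
        assert res.action.shape == (3, 6, 20)
        assert res.action.min() >= 0 and res.action.max() <= 1
        assert res.n_records == 3 * 6 * 20

    def test_uniform_initial_expected_contributions(self):
        res = run_pgg(PGGParams(beta=0.1, A=0.9), t_max=1, n_groups=500, seed=12)
        p1 = res.intended_p[0, 0, :]
        assert 0.4 < p1.mean() < 0.6  # mean 0.5 +/- sampling noise
        assert p1.min() < 0.1 and p1.max() > 0.9

    def test_defectors_contribute_exactly_zero(self):
        res = run_pgg(
            PGGParams(beta=0.4, A=0.9),
            pop=PopulationSpec(defector_fraction=0.5),
            t_max=5,
            n_groups=10,
            seed=13,
        )
        mask = np.broadcast_to(res.defectors[:, None, :], res.action.shape)
        assert (res.action[mask] == 0.0).all()

    def test_group_payoff_conservation(self):
        params = PGGParams(beta=0.4, A=0.9)
        res = run_pgg(params, t_max=4, n_groups=6, seed=14)
        a = res.action.reshape(1, 4, 6, 4)
        pay = res.payoff.reshape(1, 4, 6, 4)
        expected = 4 * params.endowment + (params.multiplier - 1) * a.sum(axis=3)
        assert np.allclose(pay.sum(axis=3), expected)

    def test_nash_equilibrium_is_absorbing_under_satisfaction(self):
        # sigma -> 0+, p1 = 0, A below the all-zero payoff of 1
        res = run_pgg(
            PGGParams(beta=0.4, A=0.5, X=0.3, sigma=0.01),
            t_max=25,
            n_groups=50,
            seed=15,
            p_init=0.0,
        )
        assert res.grand_mean_cooperation() < 0.05

    def test_fc_prev_is_others_previous_mean(self):
        res = run_pgg(PGGParams(beta=0.4, A=0.9), t_max=3, n_groups=2, seed=16)
        a = res.action[0]
        fc = res.f_c_prev[0]
        grp = a.reshape(3, 2, 4)
        expect = (grp.sum(axis=2, keepdims=True) - grp) / 3
        assert np.allclose(fc[1:], expect.reshape(3, 8)[:-1])


class TestNoisyGrimComparator:
    def test_population_collapses_to_noise_floor(self, lattice10):
        res = run_noisy_grim(lattice10, epsilon=0.2, t_max=25, n_runs=50, seed=17)
        m = res.mean_cooperation_per_round()
        assert m[0] == pytest.approx(0.8)  # everyone starts cooperative
        assert np.allclose(m[5:], 0.2, atol=0.02)  # triggered -> noise floor

    def test_no_learning_propensities_are_binary(self, lattice10):
        res = run_noisy_grim(lattice10, epsilon=0.2, t_max=10, n_runs=5, seed=18)
        assert set(np.unique(res.intended_p)) <= {0.0, 1.0}


class TestRunEnsemble:
    def test_config_round_trip_determinism(self):
        cfg = RunConfig(game="pdg", network="lattice", L=3, t_max=4, n_runs=3, seed=77)
        a = run_ensemble(cfg).to_records()
        b = run_ensemble(cfg).to_records()
        pd.testing.assert_frame_equal(a, b)

    def test_master_seed_override(self):
        cfg = RunConfig(game="pdg", network="lattice", L=3, t_max=4, n_runs=3, seed=77)
        a = run_ensemble(cfg, master_seed=1).to_records()
        b = run_ensemble(cfg, master_seed=2).to_records()
        assert not a.equals(b)

    def test_pgg_dispatch(self):
        cfg = RunConfig(game="pgg", n_groups=3, t_max=4, n_runs=2, p_init=None, seed=5)
        res = run_ensemble(cfg)
        assert res.game == "pgg"
        assert res.n_records == 2 * 4 * 12

    def test_regular_random_network_dispatch(self):
        cfg = RunConfig(game="pdg", network="regular_random", n=20, k=4, t_max=3,
                        n_runs=2, seed=9)
        res = run_ensemble(cfg)
        assert res.network.n == 20
        assert set(res.network.degrees.tolist()) == {4}
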