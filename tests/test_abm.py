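"""Lattice ABM: update rules, conservation, boundedness, ensemble statistics."""

import numpy as np
import pytest
from scipy.linalg import expm

from smoreglos import ABMParams, run_ensemble, sample_parameter_space, simulate_abm
from smoreglos.abm import CapacityError, EnsembleTimeSeries, replicate_seeds
from smoreglos.gsa import ParameterSpace


def frozen(**kw):
    base = dict(K_A=300, rho_G1_S=0, rho_S_G2=0, rho_G2_M=0, rho_M_G1=0, s=0)
    base.update(kw)
    return ABMParams(**base)


class TestSimulate:
    def test_no_events_means_constant_counts(self):
        ens = simulate_abm(frozen(), lattice_size=20, n_initial=10, seed=4)
        totals = ens.total()[0]
        assert np.all(totals == 10)
        # individual phase counts are frozen too
        assert np.all(ens.counts[0] == ens.counts[0, 0])

    def test_division_of_single_m_cell_yields_two_g1_cells(self):
        # one cell, only the M->G1 transition possible and effectively
        # instantaneous; a cell seeded in M divides into two G1 cells,
        # any other seed phase stays put
        p = ABMParams(K_A=50, rho_G1_S=0, rho_S_G2=0, rho_G2_M=0, rho_M_G1=1000, s=0)
        outcomes = set()
        for seed in range(30):
            ens = simulate_abm(p, lattice_size=10, n_initial=1, t_end=0.1,
                               record_times=(0.0, 0.1), seed=seed)
            start = tuple(ens.counts[0, 0].astype(int))
            end = tuple(ens.counts[0, -1].astype(int))
            if start == (0, 1):  # seeded in G2 or M
                assert end in {(2, 0), (0, 1)}  # M divided, G2 frozen
            else:
                assert end == start
            outcomes.add(end)
        assert (2, 0) in outcomes  # at least one division observed

    def test_population_bounded_by_capacity_and_lattice(self):
        # exhaustive over many seeds on a small lattice
        p = ABMParams(K_A=60, T_con=7, s=20, rho_G1_S=8, rho_S_G2=8,
                      rho_G2_M=8, rho_M_G1=8)
        for seed in range(25):
            ens = simulate_abm(p, lattice_size=8, n_initial=30, seed=seed)
            assert ens.total().max() <= min(60, 64)

    def test_identical_seed_reproduces_trajectory(self):
        a = simulate_abm(ABMParams(), seed=11)
        b = simulate_abm(ABMParams(), seed=11)
        c = simulate_abm(ABMParams(), seed=12)
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_validation_errors(self):
        with pytest.raises(CapacityError):
            simulate_abm(ABMParams(), n_initial=500, lattice_size=10)
        with pytest.raises(CapacityError):  # K_A above the number of sites
            simulate_abm(ABMParams(K_A=30), n_initial=10, lattice_size=5)
        with pytest.raises(ValueError):  # recording beyond t_end
            simulate_abm(ABMParams(), record_times=(0.0, 5.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ABMParams(rho_G1_S=-1)
        with pytest.raises(ValueError):
            ABMParams(T_con=9)


class TestEnsemble:
    def test_single_replicate_matches_simulate(self):
        ens = run_ensemble(ABMParams(), n_replicates=1, base_seed=7)
        solo = simulate_abm(ABMParams(), seed=replicate_seeds(7, 1)[0])
        assert np.array_equal(ens.counts, solo.counts)

    def test_deterministic_limit_has_zero_total_sd(self):
        # with all rates zero nothing evolves: totals are deterministic and
        # each replicate's phase counts are frozen at their initial draw
        ens = run_ensemble(frozen(), n_replicates=4, base_seed=1,
                           lattice_size=20, n_initial=10)
        assert np.all(ens.total() == 10)
        assert np.all(ens.counts == ens.counts[:, :1, :])

    def test_pure_transition_mean_matches_markov_chain(self):
        # no divisions (rho_M_G1 = 0), no interactions: each cell is an
        # independent unidirectional 4-state chain; compare the ensemble
        # mean against the matrix-exponential expectation within 3 SE
        rates = np.array([2.0, 3.0, 4.0, 0.0])
        Q = np.zeros((4, 4))
        for i in range(3):
            Q[i, i] = -rates[i]
            Q[i, i + 1] = rates[i]
        n0, R = 200, 200
        p = ABMParams(K_A=900, T_con=8, s=0, rho_G1_S=2, rho_S_G2=3,
                      rho_G2_M=4, rho_M_G1=0)
        ens = run_ensemble(p, n_replicates=R, base_seed=5,
                           lattice_size=30, n_initial=n0)
        p0 = np.full(4, 0.25)
        for ti, t in enumerate(ens.times):
            pt = p0 @ expm(Q * t)
            pg = pt[0] + pt[1]
            se = np.sqrt(max(n0 * pg * (1 - pg) / R, 1e-12))
            assert abs(ens.mean()[ti, 0] - n0 * pg) <= 3 * se + 1e-9

    @pytest.mark.parametrize("K_A, T_con", [(900, 2), (950, 2), (1000, 2), (1050, 2)])
    def test_g1s_accumulates_when_culture_saturates(self, K_A, T_con):
        # crowded cultures that reach >= 0.9 K_A by day 3 shift toward G1/S
        p = ABMParams(K_A=K_A, T_con=T_con, s=10, rho_G1_S=5, rho_S_G2=5,
                      rho_G2_M=5, rho_M_G1=5)
        ens = run_ensemble(p, n_replicates=4, base_seed=9)
        tot = ens.total().mean(axis=0)
        assert tot[-1] >= 0.9 * K_A  # saturation precondition holds
        frac = ens.mean()[:, 0] / tot
        assert frac[-1] > frac[1]  # day 3 vs day 0.5

    def test_conservation_under_transitions_and_division(self):
        # totals never decrease (no death) and increase only via division
        p = ABMParams()
        ens = simulate_abm(p, seed=2)
        totals = ens.total()[0]
        assert np.all(np.diff(totals) >= 0)


class TestSampling:
    def space(self, bounds):
        return ParameterSpace([f"p{i}" for i in range(len(bounds))], bounds)

    def test_two_level_grid_is_exactly_the_corners(self):
        pts = sample_parameter_space(self.space([(0, 1), (2, 4)]), "grid", levels=2)
        assert sorted(map(tuple, pts)) == [(0, 2), (0, 4), (1, 2), (1, 4)]

    def test_three_level_grid_in_1d(self):
        pts = sample_parameter_space(self.space([(0, 1)]), "grid", levels=3)
        assert np.allclose(sorted(pts.ravel()), [0, 0.5, 1])

    def test_lhs_stratifies_each_marginal_and_appends_corners(self):
        sp = self.space([(0, 1)] * 3)
        pts = sample_parameter_space(sp, "lhs", n_points=10, seed=0)
        interior, corners = pts[:10], pts[10:]
        assert corners.shape == (8, 3)
        assert {tuple(c) for c in corners} == {
            tuple(c) for c in np.stack(np.meshgrid(*[[0, 1]] * 3), -1).reshape(-1, 3)
        }
        for j in range(3):
            deciles = np.floor(interior[:, j] * 10).astype(int)
            assert sorted(deciles) == list(range(10))

    def test_bad_bounds_rejected(self):
        class Box:
            bounds = [(1.0, 0.0)]

        with pytest.raises(ValueError):
            sample_parameter_space(Box(), "grid", levels=2)


class TestMockGrowth:
    def test_zero_noise_reproduces_ode_solution(self):
        from smoreglos import GrowthSMParams, mock_growth_ensemble, solve_growth

        times = np.linspace(0, 3, 7)
        ens = mock_growth_ensemble("logistic", {"r": 1.0, "K": 1000.0}, 0.0,
                                   times, 5, seed=1, N0=50.0)
        sol = solve_growth(GrowthSMParams("logistic", r=1.0, K=1000.0), 50.0, times)
        assert np.allclose(ens.counts[:, :, 0], sol.values[:, 0])
        assert ens.std().max() <= 1e-10

    def test_logistic_started_at_capacity_stays_there(self):
        from smoreglos import mock_growth_ensemble

        times = np.linspace(0, 3, 7)
        ens = mock_growth_ensemble("logistic", {"r": 1.0, "K": 500.0}, 0.05,
                                   times, 8, seed=2, N0=500.0)
        assert np.allclose(ens.mean()[:, 0], 500.0, rtol=0.1)

    def test_large_ensemble_mean_near_ode_solution(self):
        from smoreglos import GrowthSMParams, mock_growth_ensemble, solve_growth

        times = np.linspace(0, 3, 7)
        ens = mock_growth_ensemble("exponential", {"lambda_": 0.8}, 0.1,
                                   times, 500, seed=3, N0=100.0)
        sol = solve_growth(GrowthSMParams("exponential", lambda_=0.8), 100.0, times)
        # lognormal factors have mean exp(sigma^2/2) ~ 1.005
        assert np.allclose(ens.mean()[:, 0], sol.values[:, 0], rtol=0.02)

    def test_unknown_model_rejected(self):
        from smoreglos import mock_growth_ensemble

        with pytest.raises(ValueError):
            mock_growth_ensemble("gompertz", {}, 0.1, [0, 1], 3)


def test_container_validates_dimensions():
    with pytest.raises(ValueError):
        EnsembleTimeSeries(np.array([0.0, 1.0]), ("a",), np.zeros((2, 3, 1)))
    with pytest.raises(ValueError):
        EnsembleTimeSeries(np.array([1.0, 0.0]), ("a",), np.zeros((2, 2, 1)))
    with pytest.raises(ValueError):
        EnsembleTimeSeries(np.array([0.0, 1.0]), ("a",), -np.ones((2, 2, 1)))
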