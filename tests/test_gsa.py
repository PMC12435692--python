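"""Morris and eFAST engines, metric wrappers, surrogate transfer."""

import numpy as np
import pytest

from smoreglos import (
    ABMParams,
    CallableModel,
    Hyperrectangle,
    ParameterSpace,
    SampledBounds,
    abm_metric,
    build_field,
    efast_design,
    efast_indices,
    final_value,
    morris_design,
    morris_indices,
    run_gsa,
    surrogate_metric,
)
from smoreglos.gsa import MetricFunction

try:
    from hypothesis import given, strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def unit_space(m):
    return ParameterSpace([f"x{i}" for i in range(m)], [(0.0, 1.0)] * m)


class TestMorrisDesign:
    def test_one_parameter_trajectory_is_a_delta_step(self):
        d = morris_design(unit_space(1), r=1, levels=4, seed=0)
        assert d.X_unit.shape == (2, 1)
        assert abs(d.X_unit[1, 0] - d.X_unit[0, 0]) == pytest.approx(d.delta)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_consecutive_points_differ_in_exactly_one_coordinate(self, seed):
        m, r, p = 5, 6, 4
        d = morris_design(unit_space(m), r=r, levels=p, seed=seed)
        for t in range(r):
            seen = set()
            for j in range(m):
                a = d.X_unit[t * (m + 1) + j]
                b = d.X_unit[t * (m + 1) + j + 1]
                diff = np.flatnonzero(np.abs(b - a) > 1e-12)
                assert diff.size == 1
                assert abs(b[diff[0]] - a[diff[0]]) == pytest.approx(d.delta)
                seen.add(diff[0])
            assert seen == set(range(m))  # every parameter perturbed once

    def test_all_points_on_the_level_grid(self):
        p = 4
        d = morris_design(unit_space(3), r=5, levels=p, seed=3)
        grid = np.arange(p) / (p - 1)
        for x in d.X_unit.ravel():
            assert np.min(np.abs(grid - x)) < 1e-12

    def test_odd_levels_rejected(self):
        with pytest.raises(ValueError):
            morris_design(unit_space(2), r=2, levels=5)


class TestMorrisIndices:
    def test_linear_function_has_exact_degenerate_effects(self):
        space = unit_space(3)
        d = morris_design(space, r=10, levels=4, seed=1)
        f = np.array([3 * x[0] + x[1] - 2 * x[2] for x in d.X_unit])
        res = morris_indices(d, f)
        assert np.allclose(res.mu, [3, 1, -2], atol=1e-12)
        assert np.allclose(res.mu_star, [3, 1, 2], atol=1e-12)
        assert np.allclose(res.sigma, 0, atol=1e-10)

    def test_constant_function_is_inert(self):
        d = morris_design(unit_space(2), r=4, levels=4, seed=2)
        res = morris_indices(d, np.ones(len(d.X)))
        assert np.all(res.mu == 0) and np.all(res.mu_star == 0) and np.all(res.sigma == 0)

    def test_product_function_matches_naive_elementary_effects(self):
        # independent oracle: recompute effects by scanning for the single
        # changed coordinate between consecutive points, with no use of the
        # design's permutation/sign bookkeeping
        space = unit_space(2)
        d = morris_design(space, r=50, levels=4, seed=4)
        f = d.X_unit[:, 0] * d.X_unit[:, 1]
        res = morris_indices(d, f)
        ee = {0: [], 1: []}
        m = 2
        for t in range(d.r):
            for j in range(m):
                a = d.X_unit[t * (m + 1) + j]
                b = d.X_unit[t * (m + 1) + j + 1]
                i = int(np.flatnonzero(np.abs(b - a) > 1e-12)[0])
                step = b[i] - a[i]
                ee[i].append((f[t * (m + 1) + j + 1] - f[t * (m + 1) + j]) / step)
        for i in range(m):
            assert res.mu_star[i] == pytest.approx(np.mean(np.abs(ee[i])))
            assert res.mu[i] == pytest.approx(np.mean(ee[i]))

    def test_misaligned_values_rejected(self):
        d = morris_design(unit_space(2), r=3, levels=4, seed=0)
        with pytest.raises(ValueError):
            morris_indices(d, np.ones(5))


class TestEfast:
    def test_design_points_respect_bounds_and_cover_ranges(self):
        space = ParameterSpace(["a", "b"], [(2.0, 4.0), (-1.0, 1.0)])
        d = efast_design(space, Ns=65, M=4, Nr=2, seed=0)
        X = d.X.reshape(-1, 2)
        assert X[:, 0].min() >= 2 and X[:, 0].max() <= 4
        # the parameter of interest sweeps essentially its whole range
        poi = d.X[0, 0, :, 0]
        assert poi.min() < 2 + 0.02 * 2 and poi.max() > 4 - 0.02 * 2

    def test_distinct_parameters_of_interest_get_distinct_designs(self):
        d = efast_design(unit_space(3), Ns=65, M=4, Nr=1, seed=1)
        assert not np.allclose(d.X[0], d.X[1])
        assert d.omegas[0, 0] == d.omegas[1, 1] == d.omega_max

    def test_constant_output_gives_zero_indices_with_warning(self):
        d = efast_design(unit_space(2), Ns=65, M=4, Nr=1, seed=0)
        with pytest.warns(RuntimeWarning):
            res = efast_indices(d, np.ones((2, 1, 65)))
        assert np.all(res.S == 0) and np.all(res.ST == 0)

    def test_single_active_parameter_takes_all_variance(self):
        space = unit_space(3)
        res = run_gsa("efast", lambda p: p[0], space,
                      options={"Ns": 65, "M": 4, "Nr": 2}, seed=5)
        assert res.S[0] > 0.95
        assert res.ST[1] < 0.05 and res.ST[2] < 0.05

    def test_additive_main_effects_bounded_by_one(self):
        space = unit_space(3)
        res = run_gsa("efast", lambda p: p.sum(), space,
                      options={"Ns": 65, "M": 4, "Nr": 2}, seed=6)
        assert res.S.sum() <= 1.05
        assert np.all(res.S <= res.ST + 0.02)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            efast_design(unit_space(2), Ns=7, M=4)
        with pytest.raises(ValueError):
            efast_design(unit_space(1), Ns=65, M=4)


def linear_model():
    # surrogate whose final value is theta_0 + theta_1 (times irrelevant)
    return CallableModel(
        "toy", ["u", "v"], [(0.0, 10.0)] * 2,
        lambda th, t, init: np.full_like(np.asarray(t, float), th[0] + th[1]),
        log_scale=False,
    )


def degenerate_field(space, value_u=2.0, value_v=3.0):
    pts = np.array(np.meshgrid(*[[lo, hi] for lo, hi in space.bounds], indexing="ij"))
    pts = pts.reshape(space.m, -1).T
    lo = np.tile([value_u, value_v], (len(pts), 1))
    return build_field(SampledBounds(tuple(space.names), pts, ("u", "v"), lo, lo.copy()))


class TestSurrogateMetric:
    def test_degenerate_field_has_zero_monte_carlo_variance(self):
        space = unit_space(2)
        field = degenerate_field(space)
        f1 = surrogate_metric(field, linear_model(), final_value, [0.0, 1.0], [0.0], n_mc=10, seed=1)
        f2 = surrogate_metric(field, linear_model(), final_value, [0.0, 1.0], [0.0], n_mc=10, seed=99)
        p = np.array([0.4, 0.6])
        assert f1(p) == f2(p) == pytest.approx(5.0)

    def test_constant_metric_passes_through(self):
        space = unit_space(2)
        field = degenerate_field(space)
        f = surrogate_metric(field, linear_model(), lambda traj: 42.0, [0.0, 1.0], [0.0], n_mc=5, seed=0)
        assert f(np.array([0.2, 0.8])) == 42.0

    def test_box_mean_converges_to_quadrature_oracle(self):
        # nonuniform box: compare the Monte-Carlo box mean with a
        # deterministic tensor-grid quadrature of the same functional
        model = CallableModel(
            "quad", ["u", "v", "w"], [(0.0, 10.0)] * 3,
            lambda th, t, init: np.full_like(np.asarray(t, float), th[0] * th[1] + th[2] ** 2),
            log_scale=False,
        )
        rect_lo = np.array([1.0, 2.0, 0.0])
        rect_hi = np.array([3.0, 5.0, 2.0])
        space = ParameterSpace(["A"], [(0.0, 1.0)])
        pts = np.array([[0.0], [1.0]])
        field = build_field(SampledBounds(("A",), pts, ("u", "v", "w"),
                                          np.tile(rect_lo, (2, 1)), np.tile(rect_hi, (2, 1))))
        # Gauss-Legendre tensor quadrature oracle
        from numpy.polynomial.legendre import leggauss

        x, w = leggauss(8)
        nodes = [(0.5 * (hi - lo) * x + 0.5 * (hi + lo), w / 2)
                 for lo, hi in zip(rect_lo, rect_hi)]
        total = 0.0
        for u, wu in zip(*nodes[0]):
            for v, wv in zip(*nodes[1]):
                for z, wz in zip(*nodes[2]):
                    total += wu * wv * wz * (u * v + z**2)
        f = surrogate_metric(field, model, final_value, [0.0, 1.0], [0.0], n_mc=4000, seed=7)
        est = f(np.array([0.5]))
        # MC standard error of the box mean
        draws = []
        rng = np.random.default_rng(0)
        sample = rect_lo + rng.random((4000, 3)) * (rect_hi - rect_lo)
        draws = sample[:, 0] * sample[:, 1] + sample[:, 2] ** 2
        se = draws.std() / np.sqrt(4000)
        assert abs(est - total) < 3 * se

    def test_standard_error_halves_when_samples_quadruple(self):
        space = unit_space(2)
        model = linear_model()
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        lo = np.tile([0.0, 0.0], (4, 1))
        hi = np.tile([4.0, 6.0], (4, 1))
        field = build_field(SampledBounds(("x0", "x1"), pts, ("u", "v"), lo, hi))
        p = np.array([0.3, 0.7])
        sds = []
        for n_mc in (25, 100, 400):
            vals = [
                surrogate_metric(field, model, final_value, [0.0, 1.0], [0.0],
                                 n_mc=n_mc, seed=s)(p)
                for s in range(40)
            ]
            sds.append(np.std(vals, ddof=1))
        assert 1.6 < sds[0] / sds[1] < 2.4
        assert 1.6 < sds[1] / sds[2] < 2.4


class TestAbmMetric:
    def test_deterministic_limit_returns_n_initial(self):
        space = ParameterSpace(["K_A"], [(500.0, 900.0)])
        template = ABMParams(rho_G1_S=0, rho_S_G2=0, rho_G2_M=0, rho_M_G1=0, s=0)
        f = abm_metric(space, final_value, template=template, n_replicates=2,
                       seed=0, lattice_size=40, n_initial=30)
        assert f(np.array([600.0])) == 30.0

    def test_repeatable_and_counts_evaluations(self):
        space = ParameterSpace(["K_A"], [(500.0, 900.0)])
        f = abm_metric(space, final_value, n_replicates=2, seed=3,
                       lattice_size=40, n_initial=30)
        v1 = f(np.array([700.0]))
        v2 = f(np.array([700.0]))  # cache hit
        v3 = f(np.array([800.0]))
        assert v1 == v2
        assert f.n_calls == 3 and f.n_evaluations == 2
        g = abm_metric(space, final_value, n_replicates=2, seed=3,
                       lattice_size=40, n_initial=30)
        assert g(np.array([700.0])) == v1  # same seed policy, same value


class TestRunGsa:
    def test_moat_on_degenerate_field_is_exact_for_linear_metric(self):
        space = unit_space(2)
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        # box bounds depending linearly on the ABM point, zero width
        lo = np.column_stack([2 * pts[:, 0], 3 * pts[:, 1]])
        field = build_field(SampledBounds(("x0", "x1"), pts, ("u", "v"), lo, lo.copy()))
        f = surrogate_metric(field, linear_model(), final_value, [0.0, 1.0], [0.0], n_mc=1, seed=0)
        res = run_gsa("moat", f, space, options={"r": 6, "levels": 4}, seed=0)
        assert np.allclose(res.mu, [2.0, 3.0], atol=1e-9)
        assert np.allclose(res.sigma, 0.0, atol=1e-9)

    def test_same_seed_same_results(self):
        space = unit_space(3)
        fn = lambda p: p[0] ** 2 + np.sin(p[1])
        a = run_gsa("moat", fn, space, options={"r": 8}, seed=9)
        b = run_gsa("moat", fn, space, options={"r": 8}, seed=9)
        assert np.array_equal(a.mu_star, b.mu_star)
        c = run_gsa("efast", fn, space, options={"Ns": 65, "M": 4, "Nr": 2}, seed=9)
        d = run_gsa("efast", fn, space, options={"Ns": 65, "M": 4, "Nr": 2}, seed=9)
        assert np.array_equal(c.S, d.S)

    def test_metric_failure_names_the_point(self):
        space = unit_space(2)

        def bad(p):
            if p[0] > 0.5:
                raise FloatingPointError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="design point"):
            run_gsa("moat", bad, space, options={"r": 4}, seed=0)

    def test_evaluation_count_recorded(self):
        space = unit_space(2)
        res = run_gsa("moat", lambda p: p.sum(), space, options={"r": 5}, seed=1)
        assert res.n_evaluations <= 5 * 3  # caching may dedupe grid points


if HAVE_HYPOTHESIS:

    @given(st.integers(0, 1000), st.integers(1, 6), st.integers(2, 5))
    def test_morris_points_always_inside_unit_cube(seed, r, m):
        """Design points stay in [0,1]^m for any seed, r and dimension."""
        d = morris_design(unit_space(m), r=r, levels=4, seed=seed)
        assert d.X_unit.min() >= -1e-12 and d.X_unit.max() <= 1 + 1e-12
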