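import numpy as np
import pytest

from cmfseg.cmf import (
    CapacityField, build_capacities, solve_cmf_two_label, solve_cmf_potts,
    threshold_labels, discrete_mincut_energy, potts_bruteforce_energy,
    potts_energy,
)


def _random_two_label(seed, shape=(8, 8)):
    gen = np.random.default_rng(seed)
    return CapacityField(Cs=gen.uniform(0, 1, shape),
                         Ct=gen.uniform(0, 1, shape),
                         C=gen.uniform(0, 1, shape))


class TestCapacities:
    def test_zero_sink_cost_at_fg_mean(self):
        img = np.full((8, 8), 10.0)
        img[2, 2] = 100.0
        cap = build_capacities(img, fg_mean=100.0, bg_mean=10.0)
        assert cap.Ct[2, 2] == 0.0

    def test_two_valued_image_vanishing_costs(self):
        img = np.where(np.arange(64).reshape(8, 8) < 32, 5.0, 50.0)
        cap = build_capacities(img, fg_mean=50.0, bg_mean=5.0)
        assert np.all(cap.Cs[img == 5.0] == 0)
        assert np.all(cap.Ct[img == 50.0] == 0)

    def test_edge_adaptive_flat_image_constant(self):
        img = np.full((8, 8), 3.0)
        cap = build_capacities(img, fg_mean=10.0, bg_mean=0.0,
                               lambda_tv=2.5, edge_adaptive=True)
        np.testing.assert_allclose(cap.C, 2.5)

    def test_otsu_means_default(self, rng):
        img = np.concatenate([rng.normal(10, 1, 32), rng.normal(90, 1, 32)])
        cap = build_capacities(img.reshape(8, 8))
        # foreground cost low on bright pixels
        assert cap.Ct[img.reshape(8, 8) > 50].mean() < \
            cap.Ct[img.reshape(8, 8) < 50].mean()

    def test_degenerate_single_intensity(self):
        with pytest.raises(ValueError):
            build_capacities(np.full((8, 8), 1.0))

    def test_rejects_negative_capacity(self):
        with pytest.raises(ValueError):
            CapacityField(Cs=np.full((2, 2), -1.0), Ct=np.zeros((2, 2)), C=0.0)


class TestTwoLabelSolver:
    def test_single_pixel_cheapest_cut(self):
        cap = CapacityField(Cs=[[2.0]], Ct=[[1.0]], C=0.0)
        u, state, energy = solve_cmf_two_label(cap, tv="anisotropic",
                                               max_iter=2000)
        assert threshold_labels(u)[0, 0] == 1
        assert energy.total == pytest.approx(1.0, rel=1e-3)

    def test_two_pixels_brute_force(self):
        # oracle: enumerate the 4 labelings of E = sum data + C|u0-u1|
        cap = CapacityField(Cs=[[3.0, 0.0]], Ct=[[0.0, 3.0]], C=1.0)
        best = np.inf
        for u0 in (0, 1):
            for u1 in (0, 1):
                e = ((1 - u0) * 3.0 + u1 * 3.0 + 1.0 * abs(u0 - u1))
                best = min(best, e)
        assert best == 1.0
        u, state, energy = solve_cmf_two_label(cap, tv="anisotropic",
                                               max_iter=2000)
        np.testing.assert_array_equal(threshold_labels(u), [[1, 0]])
        assert energy.total == pytest.approx(best, rel=1e-2)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("shape", [(6, 6), (8, 8)])
    def test_matches_discrete_mincut(self, seed, shape):
        cap = _random_two_label(seed, shape)
        u, state, energy = solve_cmf_two_label(cap, tv="anisotropic",
                                               max_iter=3000, tol=1e-7)
        oracle = discrete_mincut_energy(cap)
        assert abs(energy.total - oracle) / oracle <= 0.01

    def test_energy_nonincreasing(self):
        cap = _random_two_label(42)
        trace = []
        solve_cmf_two_label(cap, tv="anisotropic", max_iter=600, tol=0.0,
                            energy_trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-9)

    def test_feasibility_at_convergence(self):
        cap = _random_two_label(7)
        u, state, _ = solve_cmf_two_label(cap, max_iter=2000, tol=1e-6)
        assert np.all(state.Fs <= cap.Cs + 1e-9)
        assert np.all(state.Ft <= cap.Ct + 1e-9)
        norm = np.hypot(state.F[0], state.F[1])
        assert np.all(norm <= np.asarray(cap.C) + 1e-9)

    def test_scale_covariance(self):
        cap = _random_two_label(3)
        u1, _, e1 = solve_cmf_two_label(cap, tv="anisotropic",
                                        max_iter=2000, tol=1e-7)
        cap4 = CapacityField(Cs=4 * cap.Cs, Ct=4 * cap.Ct, C=4 * cap.C)
        u4, _, e4 = solve_cmf_two_label(cap4, tv="anisotropic",
                                        max_iter=2000, tol=1e-7)
        assert e4.total == pytest.approx(4 * e1.total, rel=1e-2)
        np.testing.assert_array_equal(threshold_labels(u1),
                                      threshold_labels(u4))

    def test_nonconvergence_flagged(self):
        cap = _random_two_label(0)
        _, state, _ = solve_cmf_two_label(cap, max_iter=3, tol=1e-12)
        assert not state.converged


class TestPottsSolver:
    def test_single_pixel_pointwise_minimum(self):
        cap = CapacityField(rho=np.array([[[0.5]], [[0.2]], [[0.9]]]), C=0.0)
        u, state, energy = solve_cmf_potts(cap, max_iter=2000)
        assert threshold_labels(u)[0, 0] == 1
        assert energy.total == pytest.approx(0.2, abs=5e-3)

    def test_uniform_costs_degenerate_tie(self):
        cap = CapacityField(rho=np.full((3, 4, 4), 0.7), C=0.0)
        u, state, energy = solve_cmf_potts(cap, max_iter=500)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-6)
        assert energy.total == pytest.approx(0.7 * 16, rel=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration(self, seed):
        gen = np.random.default_rng(100 + seed)
        cap = CapacityField(rho=gen.uniform(0, 1, (3, 3, 3)), C=0.15)
        u, state, energy = solve_cmf_potts(cap, tv="anisotropic",
                                           max_iter=3000, tol=1e-7)
        oracle = potts_bruteforce_energy(cap, tv="anisotropic")
        assert abs(energy.total - oracle) / oracle <= 0.02

    def test_simplex_constraint_at_convergence(self):
        gen = np.random.default_rng(5)
        cap = CapacityField(rho=gen.uniform(0, 1, (4, 6, 6)), C=0.1)
        u, state, _ = solve_cmf_potts(cap, max_iter=3000, tol=1e-7)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-3)
        assert u.min() >= -1e-3

    def test_requires_rho(self):
        cap = CapacityField(Cs=np.ones((2, 2)), Ct=np.ones((2, 2)), C=1.0)
        with pytest.raises(ValueError):
            solve_cmf_potts(cap)


class TestThresholdLabels:
    def test_above_level(self):
        assert threshold_labels(np.array([[0.7]]), 0.5)[0, 0] == 1

    def test_exactly_at_level_is_foreground(self):
        assert threshold_labels(np.array([[0.5]]), 0.5)[0, 0] == 1

    def test_nlabel_tie_break_lowest_index(self):
        u = np.array([0.4, 0.4, 0.2]).reshape(3, 1, 1)
        assert threshold_labels(u)[0, 0] == 0
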