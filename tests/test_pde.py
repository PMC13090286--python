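from math import factorial

import numpy as np
import pytest

from lineagetraj.pde import (Grid, solve_biased_system, solve_fokker_planck,
                             solve_generation_system, survival_probability)

from conftest import make_model, quadratic_potential


@pytest.fixture(scope="module")
def grid1d():
    return Grid([np.linspace(-6, 6, 241)])


class TestFokkerPlanck:
    def test_flat_potential_matches_heat_kernel(self, grid1d):
        m = make_model(tau=0.2)
        p0 = grid1d.gaussian([0.0], [0.3])
        p1 = solve_fokker_planck(m, p0, 1.0, grid1d)
        pts = grid1d.points()[:, 0]
        var = 0.3 ** 2 + 0.2 * 1.0
        exact = np.exp(-pts ** 2 / (2 * var)) / np.sqrt(2 * np.pi * var)
        assert grid1d.integrate(np.abs(p1 - exact)) <= 1e-2
        assert grid1d.integrate(p1) == pytest.approx(1.0, abs=1e-6)

    def test_quadratic_potential_relaxes_to_gibbs(self, grid1d):
        m = make_model(potential=quadratic_potential(0.5), tau=0.4)
        p0 = grid1d.gaussian([1.5], [0.3])
        p_inf = solve_fokker_planck(m, p0, 8.0, grid1d)
        pts = grid1d.points()[:, 0]
        gibbs = np.exp(-2 * (0.5 * pts ** 2) / 0.4)
        gibbs /= grid1d.integrate(gibbs.reshape(grid1d.shape))
        assert grid1d.integrate(np.abs(p_inf - gibbs)) <= 1e-2

    def test_zero_time_returns_initial(self, grid1d):
        m = make_model(tau=0.2)
        p0 = grid1d.gaussian([0.5], [0.4])
        np.testing.assert_allclose(solve_fokker_planck(m, p0, 0.0, grid1d), p0)


class TestGenerationSystem:
    def test_no_branching_reduces_to_fokker_planck(self, grid1d):
        m = make_model(tau=0.2)
        p0 = grid1d.gaussian([0.0], [0.3])
        gd = solve_generation_system(m, p0, 0.8, grid1d, M_max=5)
        fp = solve_fokker_planck(m, p0, 0.8, grid1d)
        assert grid1d.integrate(np.abs(gd.rho[0] - fp)) <= 1e-6
        assert np.all(gd.rho[1:] == 0)

    def test_yule_generation_masses_poissonian(self, grid1d):
        # flat potential, constant b, d=0: mass of generation m at time t is
        # e^{-bt} (2bt)^m / m! ... divided by ... total e^{bt}; per-generation
        # masses (intensity) are e^{-bt}(2bt)^m/m!
        b, t = 0.8, 1.0
        m = make_model(b=b, tau=0.2)
        p0 = grid1d.gaussian([0.0], [0.3])
        gd = solve_generation_system(m, p0, t, grid1d, M_max=25)
        masses = gd.masses()
        exact = np.exp(-b * t) * (2 * b * t) ** np.arange(26) \
            / np.array([float(factorial(k)) for k in range(26)])
        sig = exact > 1e-3
        rel = np.abs(masses[sig] - exact[sig]) / exact[sig]
        assert rel.max() <= 1e-2
        # total mass solves the growth equation; dyadic mass is conserved
        assert grid1d.integrate(gd.total()) == pytest.approx(np.exp(b * t), rel=1e-3)
        assert grid1d.integrate(gd.reweighted()) == pytest.approx(1.0, abs=1e-6)

    def test_tail_truncation_error_raises(self, grid1d):
        m = make_model(b=2.0, tau=0.2)
        p0 = grid1d.gaussian([0.0], [0.3])
        with pytest.raises(ValueError, match="truncation"):
            solve_generation_system(m, p0, 1.5, grid1d, M_max=4)


class TestSurvivalProbability:
    def test_no_death_full_observation_is_one(self, grid1d):
        m = make_model(b=0.8, tau=0.2)
        S = survival_probability(m, 1.0, grid1d)
        assert np.all(S(0.0) >= 1.0 - 1e-9)

    def test_birth_death_extinction_closed_form(self, grid1d):
        b, d, t_i = 0.8, 0.4, 1.0
        m = make_model(b=b, d=d, tau=0.2)
        S = survival_probability(m, t_i, grid1d)
        ext = d * (np.exp((b - d) * t_i) - 1) / (b * np.exp((b - d) * t_i) - d)
        got = S(0.0)
        assert np.abs(got - (1 - ext)).max() / (1 - ext) <= 1e-2

    def test_pure_subsampling_gives_q(self, grid1d):
        m = make_model(q=0.3)
        S = survival_probability(m, 1.0, grid1d)
        np.testing.assert_allclose(S(0.0), 0.3, atol=1e-9)
        np.testing.assert_allclose(S(0.7), 0.3, atol=1e-9)

    def test_monte_carlo_branch_survival(self, grid1d):
        # S(0, x) vs the fraction of simulated trees leaving >= 1 observed leaf
        from lineagetraj.simulate import observe_tree, simulate_tree
        b, d, q, t_i = 1.0, 0.6, 0.7, 1.0
        m = make_model(b=b, d=d, q=q, T=t_i)
        S = survival_probability(m, t_i, grid1d)
        rng = np.random.default_rng(2)
        n = 400
        surv = 0
        for _ in range(n):
            tree = simulate_tree(m, np.array([0.0]), 0.0, t_i, 0.004, rng)
            retained, _ = observe_tree(tree, q, rng)
            surv += bool(retained)
        frac = surv / n
        se = np.sqrt(frac * (1 - frac) / n)
        mid = float(S(0.0)[grid1d.shape[0] // 2])
        assert abs(frac - mid) <= 3 * se + 0.01


class TestBiasedSystem:
    def test_reduces_to_generation_system_without_bias(self, grid1d):
        m = make_model(b=0.8, tau=0.2)
        p0 = grid1d.gaussian([0.0], [0.3])
        biased = solve_biased_system(m, 0.8, grid1d, p0, M_max=20)
        plain = solve_generation_system(m, p0, 0.8, grid1d, M_max=20)
        # without death/subsampling the conditioned process is the plain one
        pm = plain.masses()
        bm = biased.masses()
        sig = pm > 1e-3
        assert (np.abs(bm[sig] - pm[sig]) / pm[sig]).max() <= 2e-2

    def test_dyadic_sum_solves_biased_fokker_planck(self, grid1d):
        # Cor.-11-style consistency: the reweighted sum of the biased ladder
        # solves the drift-biased Fokker-Planck with the S-weighted start
        b, d, t_i = 0.8, 0.4, 1.0
        m = make_model(b=b, d=d, tau=0.2, q=0.6)
        p0 = grid1d.gaussian([0.0], [0.3])
        S = survival_probability(m, t_i, grid1d)
        biased = solve_biased_system(m, t_i, grid1d, p0, M_max=20, S=S)
        rw = biased.reweighted()
        rw = rw / grid1d.integrate(rw)
        # flat potential + spatially constant rates: S is constant in x, the
        # bias drift vanishes, and the reference is the plain heat evolution
        ref = solve_fokker_planck(m, p0 * S(0.0), t_i, grid1d)
        ref = ref / grid1d.integrate(ref)
        assert grid1d.integrate(np.abs(rw - ref)) <= 5e-3
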