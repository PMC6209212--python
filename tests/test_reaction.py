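"""Reaction dynamics: aggregate identity, RK4 accuracy, equilibria, HW limit."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from drivespread.genetics import allele_frequency, mcr_frequencies
from drivespread.reaction import (
    ModelParameters,
    equilibrium_population,
    logistic_closed_form,
    reaction_rhs,
    rk4_integrate,
    trajectory_table,
    vital_rates_from_daily,
)


class TestModelParameters:
    def test_derived_rates(self, params):
        assert params.gamma == pytest.approx(1.2)
        assert params.delta == pytest.approx(4.4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(epsilon=-1.0),
            dict(delta2=0.0),
            dict(delta1=5.0),  # gamma = 0.1 < delta2
            dict(C=-10.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)


class TestReactionRHS:
    def test_extinction_is_absorbing(self, params, mendel):
        np.testing.assert_array_equal(
            reaction_rhs(np.zeros(3), params, mendel), np.zeros(3)
        )

    def test_wild_only_equilibrium(self, params, mendel):
        Nstar = equilibrium_population(params)
        du = reaction_rhs(np.array([Nstar, 0.0, 0.0]), params, mendel)
        np.testing.assert_allclose(du, 0.0, atol=1e-9)

    def test_negative_density_rejected(self, params, mendel):
        with pytest.raises(ValueError):
            reaction_rhs(np.array([-1.0, 0.0, 0.0]), params, mendel)

    def test_aggregate_reduces_to_logistic_with_harvest(self, params, mendel, mcr14, rng):
        """Summing the three genotype equations gives the logistic-harvest law."""
        for freqs in (mendel, mcr14):
            u = rng.uniform(0, 2000, size=(3, 20))
            du = reaction_rhs(u, params, freqs)
            N = u.sum(axis=0)
            expected = params.gamma * N * (1 - N / params.C) - params.delta2 * N
            np.testing.assert_allclose(du.sum(axis=0), expected, rtol=1e-11)

    def test_fixed_point_at_specific_census(self, params, mendel):
        # sum of du at u = (100, 100, 0) matches the aggregate law at N = 200
        du = reaction_rhs(np.array([100.0, 100.0, 0.0]), params, mendel)
        N = 200.0
        assert du.sum() == pytest.approx(
            params.gamma * N * (1 - N / params.C) - params.delta2 * N, rel=1e-12
        )


class TestRK4:
    def test_zero_state_stays_zero(self, params, mendel):
        _, states = rk4_integrate(np.zeros(3), params, mendel, 1.0, 0.01)
        np.testing.assert_array_equal(states[-1], np.zeros(3))

    def test_wild_only_matches_logistic_closed_form(self, params, mendel):
        times, states = rk4_integrate(np.array([10.0, 0.0, 0.0]), params, mendel, 12.0, 0.01)
        N = states.sum(axis=1)
        np.testing.assert_allclose(N, logistic_closed_form(10.0, params, times), rtol=1e-6)

    def test_against_adaptive_integrator(self, params, mcr14):
        """Independent oracle: scipy's adaptive RK45 at tight tolerance."""
        u0 = np.array([800.0, 300.0, 50.0])
        sol = solve_ivp(
            lambda t, u: reaction_rhs(np.maximum(u, 0), params, mcr14),
            (0, 6.0),
            u0,
            rtol=1e-11,
            atol=1e-9,
            dense_output=True,
        )
        _, states = rk4_integrate(u0, params, mcr14, 6.0, 0.01)
        np.testing.assert_allclose(states[-1], sol.sol(6.0), rtol=1e-6)

    def test_mendelian_transgene_frequency_invariant(self, params, mendel):
        """Random mating without drive conserves the allele frequency q."""
        _, states = rk4_integrate(np.array([1000.0, 1000.0, 0.0]), params, mendel, 12.0, 0.01)
        q = np.array([allele_frequency(*u).q for u in states])
        np.testing.assert_allclose(q, 0.25, atol=1e-8)

    def test_genotypes_settle_at_hardy_weinberg(self, params, mendel):
        _, states = rk4_integrate(np.array([1000.0, 1000.0, 0.0]), params, mendel, 12.0, 0.01)
        props = states[-1] / states[-1].sum()
        np.testing.assert_allclose(props, [0.5625, 0.375, 0.0625], atol=0.005)

    def test_drive_fixes_transgene(self, params):
        """With conversion f > 0, q increases monotonically toward 1."""
        freqs = mcr_frequencies(0.14)
        _, states = rk4_integrate(np.array([2000.0, 860.0, 140.0]), params, freqs, 12.0, 0.01)
        q = np.array([allele_frequency(*u).q for u in states])
        assert np.all(np.diff(q) >= -1e-12)
        assert q[0] == pytest.approx(0.19)
        assert q[-1] > 0.99

    def test_positivity_over_long_horizon(self, params, mcr14):
        _, states = rk4_integrate(np.array([2000.0, 860.0, 140.0]), params, mcr14, 40.0, 0.01)
        assert states.min() >= 0.0

    def test_convergence_to_equilibrium(self, params, mendel):
        _, states = rk4_integrate(np.array([10.0, 0.0, 0.0]), params, mendel, 40.0, 0.01)
        assert states[-1].sum() == pytest.approx(equilibrium_population(params), rel=1e-3)


class TestAggregateAnalytics:
    def test_equilibrium_value(self, params):
        assert equilibrium_population(params) == pytest.approx(2500 * (1 - 0.5 / 1.2))

    def test_no_harvest_equilibrium_is_capacity(self):
        p = ModelParameters(delta2=1e-9)
        assert equilibrium_population(p) == pytest.approx(2500.0)

    def test_logistic_equilibrium_is_fixed(self, params):
        K = equilibrium_population(params)
        assert logistic_closed_form(K, params, 7.0) == pytest.approx(K)
        assert logistic_closed_form(0.0, params, 7.0) == 0.0

    def test_logistic_against_fine_integration(self, params):
        sol = solve_ivp(
            lambda t, N: params.gamma * N * (1 - N / params.C) - params.delta2 * N,
            (0, 5.0),
            [100.0],
            rtol=1e-11,
            atol=1e-12,
        )
        assert logistic_closed_form(100.0, params, 5.0) == pytest.approx(
            sol.y[0, -1], rel=1e-8
        )


class TestVitalRates:
    def test_weekly_rates_from_daily_increase(self):
        vr = vital_rates_from_daily(1.19)
        assert vr.weekly_finite_reported == pytest.approx(3.38)
        assert vr.gamma_reported == pytest.approx(1.2)
        assert vr.weekly_finite == pytest.approx(1.19**7)

    def test_stationary_population(self):
        vr = vital_rates_from_daily(1.0)
        assert vr.weekly_finite == 1.0 and vr.gamma == 0.0


def test_trajectory_table_columns(params, mendel):
    times, states = rk4_integrate(np.array([100.0, 50.0, 0.0]), params, mendel, 1.0, 0.1)
    table = trajectory_table(times, states)
    assert list(table.columns) == ["time", "u1", "u2", "u3", "N", "q"]
    np.testing.assert_allclose(table["N"], states.sum(axis=1))
    assert table["q"].iloc[0] == pytest.approx(50 / 300)
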