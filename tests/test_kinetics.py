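"""Closed-form growth rate, exponential law, branching process, mass-action ODE."""

import math

import numpy as np
import pytest

from exparkit import (
    DomainError,
    IntegrationError,
    MechanisticRates,
    RateParameters,
    amplicon_concentration,
    beta_growth_rate,
    expected_cycle_outcome,
    simulate_branching,
    simulate_mass_action,
)
from exparkit.kinetics import time_to_reach


class TestBetaGrowthRate:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            # balanced production and 5'-waste terms cancel exactly
            (dict(gamma=1, epsilon=1, lam=1, alpha=0, phi=0.5, c_T0=1), 0.0),
            # hand-substituted instance: (8/3 - 1/12 - 0.1) * 0.5
            (dict(gamma=2, epsilon=1, lam=2, alpha=0.1, phi=0.8, c_T0=0.5),
             (8.0 / 3.0 - 1.0 / 12.0 - 0.1) * 0.5),
        ],
    )
    def test_closed_form_values(self, kwargs, expected):
        assert beta_growth_rate(RateParameters(**kwargs)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("gamma,lam,alpha,c_T0", [(1, 1, 0, 1), (3.2, 0.7, 0.4, 2e-7)])
    def test_phi_one_drops_waste_term_exactly(self, gamma, lam, alpha, c_T0):
        p = RateParameters(gamma=gamma, epsilon=1.3, lam=lam, alpha=alpha, phi=1.0, c_T0=c_T0)
        ideal = (gamma * lam**2 / (1.3 * (lam + 1)) - alpha) * c_T0
        assert beta_growth_rate(p) == pytest.approx(ideal, rel=1e-15)

    def test_monotone_in_phi(self):
        phis = np.linspace(0.05, 1.0, 20)
        for gamma in (0.5, 1.0, 2.0):
            for lam in (0.5, 1.0, 3.0):
                betas = [
                    beta_growth_rate(RateParameters(gamma=gamma, lam=lam, phi=ph, c_T0=1.0))
                    for ph in phis
                ]
                assert np.all(np.diff(betas) > 0)

    def test_zero_phi_rejected_with_symbol_named(self):
        with pytest.raises(DomainError, match="phi"):
            beta_growth_rate(RateParameters(phi=0.0))

    def test_zero_epsilon_rejected_with_symbol_named(self):
        with pytest.raises(DomainError, match="epsilon"):
            beta_growth_rate(RateParameters(epsilon=0.0))

    @pytest.mark.parametrize("bad", [dict(phi=-0.1), dict(phi=1.5), dict(lam=0), dict(c_T0=0), dict(gamma=-1)])
    def test_parameter_invariants(self, bad):
        with pytest.raises(DomainError):
            RateParameters(**bad)


class TestAmpliconConcentration:
    def test_initial_value(self):
        p = RateParameters(c_X0=2.5e-15)
        assert amplicon_concentration(p, 0.0) == 2.5e-15

    def test_flat_when_beta_zero(self):
        p = RateParameters(gamma=1, epsilon=1, lam=1, alpha=0, phi=0.5, c_T0=1, c_X0=1e-12)
        for t in (1.0, 10.0, 100.0):
            assert amplicon_concentration(p, t) == pytest.approx(1e-12, rel=1e-12)

    def test_doubling_time_arithmetic(self):
        # beta = ln 2 per minute: with phi=1, lam=1, alpha=0, eps=1, c_T0=1
        # beta reduces to gamma/2, so gamma = 2 ln 2
        p = RateParameters(gamma=2 * math.log(2), epsilon=1, lam=1, alpha=0, phi=1, c_T0=1, c_X0=1.0)
        assert amplicon_concentration(p, 3.0) == pytest.approx(8.0, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            amplicon_concentration(RateParameters(), -1.0)


class TestCycleOutcome:
    @pytest.mark.parametrize("n", range(0, 31))
    def test_ideal_and_standard_laws_exact(self, n):
        assert expected_cycle_outcome(1.0, n) == 2.0**n
        assert expected_cycle_outcome(0.5, n) == 1.5**n

    @pytest.mark.parametrize("phi", [0.0, 0.3, 1.0])
    def test_zero_cycles_identity(self, phi):
        assert expected_cycle_outcome(phi, 0) == 1.0

    @pytest.mark.parametrize("n", [-1, 2.5, "3"])
    def test_bad_cycle_count_rejected(self, n):
        with pytest.raises(DomainError):
            expected_cycle_outcome(0.5, n)


class TestBranching:
    def test_no_amplification_at_phi_zero(self):
        for seed in range(5):
            tr = simulate_branching(0.0, 8, 7, seed=seed)
            assert tr.final_count == 7
            assert np.all(tr.counts == 7)

    def test_deterministic_doubling_at_phi_one(self):
        tr = simulate_branching(1.0, 5, 1, seed=42)
        assert list(tr.counts) == [1, 2, 4, 8, 16, 32]

    def test_reproducible_for_fixed_seed(self):
        a = simulate_branching(0.5, 12, 10, seed=9)
        b = simulate_branching(0.5, 12, 10, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_counts_non_decreasing(self):
        tr = simulate_branching(0.3, 20, 5, seed=1)
        assert np.all(np.diff(tr.counts) >= 0)

    def test_mean_matches_closed_form(self):
        n, n0, reps, phi = 10, 100, 1000, 0.5
        finals = np.array([simulate_branching(phi, n, n0, seed=s).final_count for s in range(reps)])
        expect = n0 * expected_cycle_outcome(phi, n)
        se = finals.std(ddof=1) / math.sqrt(reps)
        assert abs(finals.mean() - expect) < 3 * se


class TestMassAction:
    grid = np.linspace(0.0, 20.0, 201)
    mech = MechanisticRates(k_on5=0.1, k_off5=0.5, k_anneal=0.5, k_ext=2.0, k_nick=2.0)

    def test_absorbing_zero_without_trigger(self):
        p = RateParameters(c_T0=1.0, c_X0=0.0)
        states = simulate_mass_action(p, self.mech, self.grid)
        assert all(s.conc_X == 0 for s in states)

    def test_all_rates_zero_is_constant(self):
        p = RateParameters(c_T0=1.0, c_X0=0.5)
        states = simulate_mass_action(p, MechanisticRates(0, 0, 0, 0, 0), self.grid)
        assert all(s.conc_T == pytest.approx(1.0) and s.conc_X == pytest.approx(0.5) for s in states)

    def test_template_conservation(self):
        p = RateParameters(c_T0=1.0, c_X0=1e-3)
        states = simulate_mass_action(p, self.mech, self.grid)
        for s in states:
            assert s.total_template == pytest.approx(1.0, rel=1e-9)

    def test_early_phase_log_linear(self):
        p = RateParameters(c_T0=1.0, c_X0=1e-6)
        small = MechanisticRates(k_on5=0.01, k_off5=0.05, k_anneal=0.05, k_ext=0.2, k_nick=0.2)
        states = simulate_mass_action(p, small, np.linspace(0, 120, 601))
        x = np.array([s.conc_X for s in states])
        # exponential phase: fit log-concentration once the initial transient
        # has passed but while X is still tiny against the template pool
        sel = (x > 1e-5) & (x < 1e-4)
        t = np.array([s.t for s in states])[sel]
        logx = np.log(x[sel])
        resid = logx - np.polyval(np.polyfit(t, logx, 1), t)
        assert np.max(np.abs(resid)) < 0.05

    def test_faster_annealing_reaches_threshold_sooner(self):
        p = RateParameters(c_T0=1.0, c_X0=1e-6)
        slow = MechanisticRates(k_on5=0.01, k_off5=0.05, k_anneal=0.05, k_ext=0.2, k_nick=0.2)
        fast = MechanisticRates(k_on5=0.01, k_off5=0.05, k_anneal=0.10, k_ext=0.2, k_nick=0.2)
        grid = np.linspace(0, 120, 1201)
        t_slow = time_to_reach(simulate_mass_action(p, slow, grid), 1e-5)
        t_fast = time_to_reach(simulate_mass_action(p, fast, grid), 1e-5)
        assert t_fast < t_slow

    @pytest.mark.parametrize("bad_grid", [[0.0], [1.0, 2.0], [0.0, 1.0, 1.0]])
    def test_bad_grids_rejected(self, bad_grid):
        with pytest.raises(DomainError):
            simulate_mass_action(RateParameters(c_T0=1.0), self.mech, bad_grid)
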