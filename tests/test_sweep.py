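"""Single-gene sweep dynamics and the fixation/extinction closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import metasweep as ms

from conftest import seeded


def make_two_patch_state(carrier_on=0):
    state = ms.new_monomorphic_state(2)
    state.innovate(1)  # two distinct species
    state.patch_carrier[carrier_on] = True
    state.arrivals_seen = 1
    return state


class TestIntroduceGene:
    def test_single_carrier(self, rng):
        st_ = ms.new_monomorphic_state(10)
        ms.introduce_gene(st_, rng)
        assert st_.B == 1

    def test_specific_patch(self):
        st_ = ms.new_monomorphic_state(10)
        ms.introduce_gene(st_, patch=3)
        assert st_.patch_carrier[3] and st_.B == 1

    def test_double_introduction_rejected(self, rng):
        st_ = ms.new_monomorphic_state(10)
        ms.introduce_gene(st_, rng)
        with pytest.raises(ValueError):
            ms.introduce_gene(st_, rng)


class TestSweepStep:
    def test_forced_migration_sweep(self):
        # M=2, carrier on 0 with a distinct species: pair (0,1) with p_m=1
        # replaces species and gene together
        for seed in range(20):
            state = make_two_patch_state()
            ms.sweep_step(state, 1.0, 0.0, seeded(seed))
            if state.B == 2:  # the (0,1) pair was drawn
                assert state.S == 1
                return
        raise AssertionError("carrier->non-carrier pair never drawn in 20 seeds")

    def test_forced_hgt_preserves_diversity(self):
        for seed in range(20):
            state = make_two_patch_state()
            ms.sweep_step(state, 0.0, 1.0, seeded(seed))
            if state.B == 2:
                assert state.S == 2
                return
        raise AssertionError("carrier->non-carrier pair never drawn in 20 seeds")

    def test_carrier_second_is_noop(self):
        # the ordered pair (non-carrier, carrier) must leave the state alone
        state = make_two_patch_state(carrier_on=1)
        before = (state.patch_species.copy(), state.patch_carrier.copy())
        for seed in range(20):
            ms.sweep_step(state, 1.0, 0.0, seeded(seed))
            if state.B == 2:
                break
        # every no-op draw left species/carriers unchanged until the (1,0) draw
        assert state.patch_carrier[1]


class TestRunUntilFixation:
    def test_pure_hgt_preserves_all_diversity(self):
        for r in range(5):
            rng = seeded(300 + r)
            state = ms.sample_equilibrium_state(50, 0.05, rng)
            ms.introduce_gene(state, rng)
            _, summary = ms.run_until_fixation(state, 0.0, 1.0, rng)
            assert summary.S_f == summary.S_i
            assert not summary.truncated

    def test_pure_migration_removes_all_diversity(self):
        for r in range(5):
            rng = seeded(400 + r)
            state = ms.sample_equilibrium_state(50, 0.05, rng)
            ms.introduce_gene(state, rng)
            _, summary = ms.run_until_fixation(state, 1.0, 0.0, rng)
            assert summary.S_f == 1

    def test_fixation_time_scale(self):
        # empirical mean fixation time is of the order of the logistic scale
        M = 300
        times = []
        for r in range(100):
            rng = seeded(500 + r)
            state = ms.new_monomorphic_state(M)
            ms.introduce_gene(state, rng)
            _, summary = ms.run_until_fixation(state, 0.9, 0.1, rng)
            times.append(summary.fixation_step)
        ratio = np.mean(times) / ms.tau_fix(M, 0.9, 0.1)
        assert 0.5 < ratio < 2.0

    def test_truncation_flag(self, rng):
        state = ms.new_monomorphic_state(200)
        ms.introduce_gene(state, rng)
        _, summary = ms.run_until_fixation(state, 0.5, 0.0, rng, max_steps=10)
        assert summary.truncated and summary.fixation_step is None

    def test_requires_single_carrier(self, rng):
        state = ms.new_monomorphic_state(10)
        with pytest.raises(ValueError):
            ms.run_until_fixation(state, 0.5, 0.1, rng)


class TestCarriersLogistic:
    def test_boundary_conditions(self):
        M = 1000
        assert ms.carriers_logistic(0.0, M, 0.9, 0.1) == pytest.approx(1.0)
        assert ms.carriers_logistic(ms.tau_fix(M, 0.9, 0.1), M, 0.9, 0.1) == pytest.approx(
            M - 1, rel=1e-9
        )

    def test_monotone_to_saturation(self):
        t = np.linspace(0, 5e5, 200)
        b = ms.carriers_logistic(t, 1000, 0.9, 0.1)
        assert np.all(np.diff(b) >= 0)
        assert np.all(np.diff(b[:10]) > 0)  # strictly rising before saturation
        assert b[-1] == pytest.approx(1000, rel=1e-6)

    def test_ode_residual(self):
        # central differences recover dB/dt = (pm+ph)(B/M)(1-B/M)
        M, pm, ph = 1000, 0.9, 0.1
        t = np.linspace(0.0, ms.tau_fix(M, pm, ph), 400)
        h = 1e-3
        dB = (ms.carriers_logistic(t + h, M, pm, ph) - ms.carriers_logistic(t - h, M, pm, ph)) / (
            2 * h
        )
        b = ms.carriers_logistic(t, M, pm, ph)
        rhs = (pm + ph) * (b / M) * (1 - b / M)
        assert np.max(np.abs(dB - rhs) / rhs) < 1e-4


class TestTauFix:
    def test_values(self):
        assert ms.tau_fix(10_000, 0.5, 0.5) == pytest.approx(2 * 10_000 * math.log(9999))
        assert ms.tau_fix(1000, 0.5, 0.5) == pytest.approx(2 * 1000 * math.log(999))

    def test_inverse_rate_proportionality(self):
        assert ms.tau_fix(1000, 0.25, 0.25) == pytest.approx(2 * ms.tau_fix(1000, 0.5, 0.5))

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            ms.tau_fix(1000, 0.0, 0.0)


class TestNoncarrierDecay:
    def test_initial_condition_and_no_displacement_limit(self):
        assert ms.noncarrier_species_decay(0.0, 1000, 10, 0.9, 0.1) == pytest.approx(10.0)
        t = np.linspace(0, 1e5, 50)
        assert np.allclose(ms.noncarrier_species_decay(t, 1000, 10, 0.0, 1.0), 10.0)

    def test_matches_ode_integration(self):
        M, m0, pm, ph = 1000, 10, 0.9, 0.1
        tf = ms.tau_fix(M, pm, ph)

        def rhs(t, d):
            return -pm * (ms.carriers_logistic(t, M, pm, ph) / M) * (d / M)

        sol = solve_ivp(rhs, (0, tf), [float(m0)], rtol=1e-10, atol=1e-12, dense_output=True)
        closed = ms.noncarrier_species_decay(tf, M, m0, pm, ph)
        assert abs(closed - sol.y[0, -1]) / sol.y[0, -1] < 1e-3

    def test_monotone_vanishing(self):
        t = np.linspace(0, 1e6, 300)
        d = ms.noncarrier_species_decay(t, 1000, 10, 0.9, 0.1)
        assert np.all(np.diff(d) <= 0)
        assert d[-1] < 1e-6


class TestExpectedGainsAndExtinction:
    def test_gain_values(self):
        assert ms.expected_total_gains(5, 0.8, 0.2) == pytest.approx(1.25)
        assert ms.expected_total_gains(5, 0.8, 0.0) == 0.0

    def test_gains_match_quadrature(self):
        # integral of the HGT gain rate p_h (B/M)(D/M) over the sweep
        M, m0, pm, ph = 1000, 10, 0.9, 0.1

        def gain_rate(t):
            return (
                ph
                * (ms.carriers_logistic(t, M, pm, ph) / M)
                * (ms.noncarrier_species_decay(t, M, m0, pm, ph) / M)
            )

        total, _ = quad(gain_rate, 0, 60 * ms.tau_fix(M, pm, ph), limit=400)
        assert abs(total - ms.expected_total_gains(m0, pm, ph)) / total < 1e-3

    def test_extinction_values(self):
        assert ms.extinction_probability(10, 0.9, 0.1) == pytest.approx(math.exp(-10 / 9))
        assert ms.extinction_probability(10, 0.9, 0.0) == 1.0

    def test_divergent_cases_rejected(self):
        with pytest.raises(ValueError):
            ms.expected_total_gains(5, 0.0, 0.2)
        with pytest.raises(ValueError):
            ms.extinction_probability(5, 0.0, 0.2)


class TestFisherLogSeries:
    def test_singleton_mass(self):
        assert ms.fisher_logseries_pmf(1, 0.01) == pytest.approx(0.99 / math.log(100))

    def test_normalised(self):
        m = np.arange(1, 10_000)
        assert float(np.sum(ms.fisher_logseries_pmf(m, 0.01))) == pytest.approx(1.0, abs=1e-10)

    def test_approximates_normalised_ewens_spectrum(self):
        M, nu = 10_000, 0.01
        n = np.arange(1, 21)
        ew = ms.ewens_expected_abundance(M, nu, np.arange(1, M + 1))
        ew_norm = ms.ewens_expected_abundance(M, nu, n) / ew.sum()
        fisher = ms.fisher_logseries_pmf(n, nu)
        assert np.max(np.abs(fisher - ew_norm) / ew_norm) < 0.05


class TestSweepParameter:
    def test_reference_values(self):
        assert ms.sweep_parameter_Q0(0.01, 1.0, 0.1) == pytest.approx(0.509, abs=5e-4)
        assert ms.sweep_parameter_Q0(0.02, 0.8, 0.2) == pytest.approx(0.6317, abs=5e-5)

    def test_pure_migration_limit(self):
        assert ms.sweep_parameter_Q0(0.01, 1.0, 0.0) == 0.0

    def test_matches_mixture_series(self):
        # direct summation of the Fisher-weighted extinction mixture
        nu, pm, ph = 0.02, 0.8, 0.2
        m = np.arange(1, 10**6 + 1)
        series = 1.0 - float(
            np.sum(ms.fisher_logseries_pmf(m, nu) * np.exp(-m * ph / pm))
        )
        assert ms.sweep_parameter_Q0(nu, pm, ph) == pytest.approx(series, abs=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(
        nu=st.floats(1e-4, 0.5),
        pm=st.floats(1e-3, 1.0),
        ratio=st.floats(0.0, 5.0),
    )
    def test_bounded_in_unit_interval(self, nu, pm, ratio):
        q = ms.sweep_parameter_Q0(nu, pm, ratio * pm)
        assert 0.0 <= q <= 1.0

    def test_monotonicity_grid(self):
        ratios = np.linspace(0.01, 2.0, 30)
        for nu in (0.005, 0.01, 0.05):
            q = [ms.sweep_parameter_Q0(nu, 1.0, r) for r in ratios]
            assert np.all(np.diff(q) > 0)
        for ratio in (0.1, 0.5, 1.0):
            q = [ms.sweep_parameter_Q0(nu, 1.0, ratio) for nu in (0.001, 0.01, 0.1)]
            assert np.all(np.diff(q) < 0)

    def test_degenerate_rates(self):
        assert ms.sweep_parameter_Q0(0.01, 0.0, 0.1) == 1.0
        with pytest.raises(ValueError):
            ms.sweep_parameter_Q0(0.01, 0.0, 0.0)


class TestSimulationInvariants:
    def test_carriers_monotone_and_diversity_nonincreasing(self, rng):
        state = ms.sample_equilibrium_state(200, 0.02, rng)
        ms.introduce_gene(state, rng)
        traj, summary = ms.run_until_fixation(state, 0.7, 0.3, rng, record_every=50)
        assert np.all(np.diff(traj.B) >= 0)
        assert np.all(np.diff(traj.S) <= 0)
        assert traj.B[-1] == 200
        assert summary.S_min <= summary.S_mean <= summary.S_max
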