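import numpy as np
import pytest
from scipy.optimize import brentq

import nanodiss as nd

PI6 = np.pi / 6


def monodisperse_scenario(cm, x0, do, V_l=1e-3, **kwargs):
    m = do * cm.s0 * V_l
    count = m / (cm.density * PI6 * x0**3)
    dpsd = nd.DiscretePSD(
        class_sizes=np.array([x0]),
        volume_fractions=np.array([1.0]),
        particle_counts=np.array([count]),
    )
    return nd.Scenario(dpsd=dpsd, m_total=m, V_l=V_l, cm=cm, **kwargs)


def fine_scenario(cm, n=199, m=0.25e-3, V_l=1e-3, **kwargs):
    """Finest reference PSD at moderate dose number, reduced class count."""
    dpsd = nd.attach_mass(nd.discretize(nd.LogNormalPSD(79e-9, 0.402), n), m, cm.density)
    return nd.Scenario(dpsd=dpsd, m_total=m, V_l=V_l, cm=cm, **kwargs)


def analytic_monodisperse_equilibrium(cm, x0, m, count, V_l):
    """Independent oracle: solve s_app(x) = (m - N rho pi/6 x^3)/V_l by bisection."""

    def f(x):
        return cm.s0 * np.exp(cm.kelvin_length / x) - (m - count * cm.density * PI6 * x**3) / V_l

    xs = np.linspace(x0 * 0.999999, 1e-9, 100001)
    vals = np.array([f(x) for x in xs])
    crossings = np.where(np.diff(np.sign(vals)) != 0)[0]
    assert crossings.size, "no equilibrium with remaining solid for these parameters"
    lo, hi = xs[crossings[0] + 1], xs[crossings[0]]
    x_eq = brentq(f, lo, hi, xtol=1e-18)
    return x_eq, cm.s0 * np.exp(cm.kelvin_length / x_eq)


class TestStep:
    def test_initial_shrink_rate_matches_analytic_derivative(self, compound):
        sc = monodisperse_scenario(compound, 200e-9, do=5)
        state = sc.initial_state()
        dt = 1e-7
        new = nd.step(state, sc, dt)
        x = 200e-9
        s_app = nd.apparent_solubility(x, compound)
        expected = -4 * compound.diffusion_coefficient() * s_app / (compound.density * x)
        observed = (new.sizes[0] - x) / dt
        assert observed == pytest.approx(expected, rel=1e-3)

    def test_equilibrium_is_fixed_point(self, compound):
        # state whose concentration already exceeds every class solubility
        sc = fine_scenario(compound, n=19)
        state0 = sc.initial_state()
        saturated = nd.DissolutionState(
            t=1.0, sizes=state0.sizes, counts=state0.counts, c_l=10 * compound.s0
        )
        after = nd.step(saturated, sc, 1e-3)
        assert after.t == pytest.approx(1.0 + 1e-3)
        np.testing.assert_array_equal(after.sizes, saturated.sizes)
        assert after.c_l == saturated.c_l

    def test_mass_balance_after_any_step(self, compound):
        sc = fine_scenario(compound, n=19)
        state = sc.initial_state()
        for dt in (1e-6, 1e-4, 1e-2):
            state = nd.step(state, sc, dt)
            total = state.total_solid(compound.density) + state.c_l * sc.V_l
            assert total == pytest.approx(sc.m_total, rel=1e-12)

    def test_nonpositive_dt_rejected(self, compound):
        sc = fine_scenario(compound, n=9)
        with pytest.raises(nd.DomainError):
            nd.step(sc.initial_state(), sc, 0.0)


class TestSimulate:
    def test_monodisperse_matches_bisection_oracle(self, compound):
        x0 = 200e-9
        sc = monodisperse_scenario(compound, x0, do=5)
        res = nd.simulate(sc)
        x_eq, c_eq = analytic_monodisperse_equilibrium(
            compound, x0, sc.m_total, sc.dpsd.particle_counts[0], sc.V_l
        )
        assert res.summary.c_eq == pytest.approx(c_eq, rel=1e-3)
        assert res.summary.smallest_surviving_size == pytest.approx(x_eq, rel=1e-3)

    def test_sub_unity_dose_number_dissolves_completely(self, compound):
        sc = fine_scenario(compound, n=199, m=25e-6, V_l=0.9e-3)  # Do = 0.99
        res = nd.simulate(sc)
        assert res.summary.fully_dissolved
        assert res.summary.dissolved_fraction == pytest.approx(1.0, abs=1e-9)
        assert res.summary.c_eq == pytest.approx(25e-6 / 0.9e-3, rel=1e-9)

    def test_concentration_monotone_and_sizes_shrink(self, compound):
        res = nd.simulate(fine_scenario(compound, n=199))
        c = res.timeseries.c_l
        assert np.all(np.diff(c) >= 0)
        assert np.all(res.timeseries.dissolved_fraction <= 1.0)
        assert np.all(res.timeseries.final_sizes <= res.timeseries.initial_sizes + 1e-18)

    def test_mass_conserved_over_full_run(self, compound):
        sc = fine_scenario(compound, n=199)
        res = nd.simulate(sc)
        total = res.final_state.total_solid(compound.density) + res.summary.c_eq * sc.V_l
        assert total == pytest.approx(sc.m_total, rel=1e-9)

    def test_equilibrium_matches_smallest_surviving_class(self, compound):
        """When solid remains, c_eq pins the Ostwald-Freundlich solubility of
        the smallest surviving class, up to the mass of the few finest
        classes that emptied after that class froze (discretization error)."""
        sc = fine_scenario(compound, n=199)
        res = nd.simulate(sc)
        x_min = res.summary.smallest_surviving_size
        s_min = nd.apparent_solubility(x_min, compound)
        c_eq = res.summary.c_eq
        assert s_min <= c_eq * (1 + 1e-6)
        class_mass_conc = sc.m_total / sc.dpsd.n_classes / sc.V_l
        assert c_eq - s_min <= 5 * class_mass_conc

    def test_equilibrium_concentration_nondecreasing_in_dose_number(self, compound):
        c_eqs = []
        for do in (2.0, 5.0, 20.0):
            m = do * compound.s0 * 1e-3
            res = nd.simulate(fine_scenario(compound, n=99, m=m))
            c_eqs.append(res.summary.c_eq)
        assert c_eqs[0] <= c_eqs[1] <= c_eqs[2]

    def test_fixed_step_halving_changes_equilibrium_below_0p1_percent(self, compound):
        ref = {}
        for dt in (2e-4, 1e-4):
            res = nd.simulate(fine_scenario(compound, n=99, dt=dt))
            ref[dt] = res.summary.c_eq
        assert abs(ref[1e-4] - ref[2e-4]) / ref[1e-4] < 1e-3

    def test_class_refinement_changes_equilibrium_below_0p5_percent(self, compound):
        c199 = nd.simulate(fine_scenario(compound, n=199)).summary.c_eq
        c399 = nd.simulate(fine_scenario(compound, n=399)).summary.c_eq
        assert abs(c399 - c199) / c399 < 0.005

    def test_step_budget_exhaustion_raises_with_diagnostics(self, compound):
        sc = fine_scenario(compound, n=99, max_steps=10)
        with pytest.raises(nd.ConvergenceError) as err:
            nd.simulate(sc)
        assert "steps" in err.value.diagnostics

    def test_particle_counts_constant(self, compound):
        sc = fine_scenario(compound, n=99)
        res = nd.simulate(sc)
        np.testing.assert_array_equal(res.final_state.counts, sc.dpsd.particle_counts)


class TestDissolvedFraction:
    def test_zero_at_start_one_at_full_dissolution(self, compound):
        sc = fine_scenario(compound, n=19)
        assert nd.dissolved_fraction(sc.initial_state(), sc) == 0.0
        final = nd.DissolutionState(
            t=1.0,
            sizes=np.zeros(19),
            counts=sc.dpsd.particle_counts,
            c_l=sc.m_total / sc.V_l,
        )
        assert nd.dissolved_fraction(final, sc) == 1.0

    def test_zero_mass_scenario_is_fully_dissolved(self, compound):
        dpsd = nd.discretize(nd.LogNormalPSD(79e-9, 0.402), 9)
        dpsd = nd.attach_mass(dpsd, 1e-9, compound.density)
        sc = nd.Scenario(dpsd=dpsd, m_total=0.0, V_l=1e-3, cm=compound)
        state = nd.DissolutionState(t=0.0, sizes=dpsd.class_sizes, counts=dpsd.particle_counts, c_l=0.0)
        assert nd.dissolved_fraction(state, sc) == 1.0

    def test_equilibrium_fraction_bounded_below_by_inverse_dose_number(self, compound):
        # c_eq >= s0, so the dissolved fraction at Do is at least 1/Do
        do = 8.9
        res = nd.simulate(fine_scenario(compound, n=99, m=do * compound.s0 * 1e-3))
        assert res.summary.dissolved_fraction >= 1.0 / do
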