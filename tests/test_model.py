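"""Structural model: closed forms, ODE agreement, steady state, derived
time quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venpk.errors import InvalidParameterError, NumericalError, ValidationError
from venpk.model import (
    DoseEvent,
    Regimen,
    StructuralParams,
    amounts_ode,
    conc_metabolite,
    conc_parent,
    elimination_half_life,
    mean_absorption_time,
    steady_state_conc,
)

from _oracles import richardson_rk4_amounts


def _draw_params(rng) -> StructuralParams:
    f = np.exp(rng.uniform(np.log(0.25), np.log(4.0), size=5))
    return StructuralParams(80.9 * f[0], 628.0 * f[1], 22.1 * f[2],
                            238.0 * f[3], 0.63 * f[4], rng.uniform(0.0, 1.0))


class TestStructuralParams:
    def test_rate_constants_derived_from_clearances(self, table2_params):
        assert table2_params.kp == pytest.approx(80.9 / 628.0)
        assert table2_params.km == pytest.approx(22.1 / 238.0)

    @pytest.mark.parametrize("field,value", [
        ("cl_f", -1.0), ("v_f", 0.0), ("ka", np.nan), ("fp", 1.5), ("fp", -0.1),
    ])
    def test_invalid_parameters_rejected(self, table2_params, field, value):
        with pytest.raises(InvalidParameterError):
            table2_params.replace(**{field: value})

    def test_regimen_requires_sorted_times(self):
        with pytest.raises(ValidationError):
            Regimen((DoseEvent(10.0, 50.0), DoseEvent(0.0, 50.0)))

    def test_repeat_dosing_requires_interval(self):
        with pytest.raises(ValidationError):
            DoseEvent(0.0, 50.0, n_additional_doses=3)


class TestAmountsOde:
    def test_initial_condition_dose_in_depot(self, table2_params):
        am = amounts_ode(table2_params, Regimen.single(50.0), [0.0])
        assert am.depot[0] == pytest.approx(50.0)
        assert am.parent[0] == 0.0
        assert am.metabolite[0] == 0.0

    def test_complete_presystemic_conversion_bypasses_parent(self, table2_params):
        p = table2_params.replace(fp=1.0)
        am = amounts_ode(p, Regimen.single(50.0), np.linspace(0.5, 24.0, 8))
        assert np.all(np.abs(am.parent) < 1e-9)
        # metabolite follows the one-compartment oral-absorption solution
        ka, km = p.ka, p.km
        t = am.times
        bateman = 50.0 * ka / (ka - km) * (np.exp(-km * t) - np.exp(-ka * t))
        np.testing.assert_allclose(am.metabolite, bateman, rtol=1e-8)

    def test_amounts_match_richardson_rk4_reference(self, table2_params):
        am = amounts_ode(table2_params, Regimen.single(50.0), [2.0],
                         rtol=1e-12, atol=1e-14)
        ref = richardson_rk4_amounts(table2_params, 50.0, 2.0)
        got = np.array([am.depot[0], am.parent[0], am.metabolite[0]])
        np.testing.assert_allclose(got, ref, rtol=1e-8)

    def test_mass_balance_at_all_outputs(self, table2_params):
        t = np.linspace(0.0, 48.0, 25)
        am = amounts_ode(table2_params, Regimen.single(50.0), t)
        total = am.depot + am.parent + am.metabolite + am.eliminated
        np.testing.assert_allclose(total, 50.0, rtol=1e-8)

    def test_mass_balance_multiple_doses(self, table2_params):
        reg = Regimen((DoseEvent(0.0, 50.0), DoseEvent(24.0, 100.0)))
        am = amounts_ode(table2_params, reg, [12.0, 30.0])
        total = am.depot + am.parent + am.metabolite + am.eliminated
        np.testing.assert_allclose(total, [50.0, 150.0], rtol=1e-8)


class TestClosedFormConcentrations:
    def test_zero_at_dose_time_and_before(self, table2_params):
        reg = Regimen.single(50.0, time=2.0)
        assert conc_parent(table2_params, reg, 2.0) == 0.0
        assert conc_parent(table2_params, reg, 1.0) == 0.0
        assert conc_metabolite(table2_params, reg, 2.0) == 0.0

    def test_dose_linearity_exact(self, table2_params):
        t = np.linspace(0.5, 36.0, 12)
        c1 = conc_parent(table2_params, Regimen.single(50.0), t)
        c2 = conc_parent(table2_params, Regimen.single(100.0), t)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-14)

    def test_parent_matches_ode_oracle(self, table2_params):
        am = amounts_ode(table2_params, Regimen.single(50.0), [6.0],
                         rtol=1e-12, atol=1e-14)
        c = conc_parent(table2_params, Regimen.single(50.0), 6.0)
        assert c == pytest.approx(1000.0 * am.parent[0] / table2_params.v_f,
                                  rel=1e-6)

    def test_metabolite_matches_ode_oracle(self, table2_params):
        am = amounts_ode(table2_params, Regimen.single(50.0), [12.0],
                         rtol=1e-12, atol=1e-14)
        c = conc_metabolite(table2_params, Regimen.single(50.0), 12.0)
        assert c == pytest.approx(1000.0 * am.metabolite[0] / table2_params.vm_f,
                                  rel=1e-6)

    def test_fast_parent_passthrough_limit(self, table2_params):
        # with no pre-systemic conversion and a parent that converts much
        # faster than it absorbs, the metabolite profile approaches a drug
        # absorbed at ka and eliminated at km
        ka = table2_params.ka
        p = table2_params.replace(fp=0.0, v_f=table2_params.cl_f / (100.0 * ka))
        assert p.kp == pytest.approx(100.0 * ka)
        # below ~1.5 h the parent transit delay (~1/kp) is still visible
        t = np.linspace(1.5, 24.0, 10)
        c = conc_metabolite(p, Regimen.single(50.0), t)
        km = p.km
        bateman = (1000.0 * 50.0 * ka / (p.vm_f * (ka - km))
                   * (np.exp(-km * t) - np.exp(-ka * t)))
        np.testing.assert_allclose(c, bateman, rtol=1e-2)

    def test_regimen_superposition_is_additive(self, table2_params):
        t = np.linspace(0.0, 60.0, 17)
        r1 = Regimen.single(50.0, time=0.0)
        r2 = Regimen.single(75.0, time=24.0)
        both = Regimen((r1.doses[0], r2.doses[0]))
        for fn in (conc_parent, conc_metabolite):
            np.testing.assert_allclose(
                fn(table2_params, both, t),
                fn(table2_params, r1, t) + fn(table2_params, r2, t),
                rtol=1e-12, atol=1e-12,
            )

    def test_closed_form_vs_ode_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = _draw_params(rng)
            t = np.sort(rng.uniform(0.01, 48.0, 10))
            am = amounts_ode(p, Regimen.single(50.0), t, rtol=1e-12, atol=1e-14)
            cp = conc_parent(p, Regimen.single(50.0), t)
            cm = conc_metabolite(p, Regimen.single(50.0), t)
            np.testing.assert_allclose(
                cp, 1000.0 * am.parent / p.v_f, rtol=1e-6, atol=1e-6)
            np.testing.assert_allclose(
                cm, 1000.0 * am.metabolite / p.vm_f, rtol=1e-6, atol=1e-6)


class TestSteadyState:
    def test_huge_interval_reduces_to_single_dose(self, table2_params):
        t_half = elimination_half_life(table2_params, "VEN")
        tau = 60.0 * t_half
        for analyte in ("VEN", "ODV"):
            ss = steady_state_conc(table2_params, 50.0, tau, 6.0, analyte)
            single = {"VEN": conc_parent, "ODV": conc_metabolite}[analyte](
                table2_params, Regimen.single(50.0), 6.0)
            assert ss == pytest.approx(single, rel=1e-9)

    def test_trough_matches_brute_force_superposition(self, table2_params):
        reg = Regimen((DoseEvent(0.0, 150.0, 24.0, 59),))
        for analyte, fn in (("VEN", conc_parent), ("ODV", conc_metabolite)):
            ss = steady_state_conc(table2_params, 150.0, 24.0, 24.0, analyte)
            brute = fn(table2_params, reg, 59 * 24.0 + 24.0)
            assert ss == pytest.approx(brute, rel=1e-6)

    def test_accumulation_ratio_at_least_one(self, table2_params):
        for analyte, fn in (("VEN", conc_parent), ("ODV", conc_metabolite)):
            ss = steady_state_conc(table2_params, 150.0, 24.0, 24.0, analyte)
            single = fn(table2_params, Regimen.single(150.0), 24.0)
            assert ss >= single

    def test_trough_decreases_with_parent_clearance(self, table2_params):
        cls = [40.0, 60.0, 80.9, 120.0, 160.0]
        troughs = [
            steady_state_conc(table2_params.replace(cl_f=cl), 150.0, 24.0, 24.0, "VEN")
            for cl in cls
        ]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))

    def test_underflow_interval_flagged(self, table2_params):
        with pytest.raises(NumericalError):
            steady_state_conc(table2_params.replace(cl_f=1e-10, v_f=1e5),
                              50.0, 1e-9, 0.5, "VEN")


class TestDerivedQuantities:
    def test_parent_half_life_matches_published_value(self, table2_params):
        assert round(elimination_half_life(table2_params, "VEN"), 1) == 5.4

    def test_metabolite_half_life_cross_checked_by_terminal_slope(self, table2_params):
        t_half = elimination_half_life(table2_params, "ODV")
        assert t_half == pytest.approx(np.log(2.0) * 238.0 / 22.1)
        # in the terminal phase the metabolite amount halves every t_half
        # (by 200 h the faster parent mode has decayed away)
        t0 = 200.0
        am = amounts_ode(table2_params, Regimen.single(50.0),
                         [t0, t0 + t_half], rtol=1e-12, atol=1e-14)
        assert am.metabolite[1] / am.metabolite[0] == pytest.approx(0.5, rel=1e-3)

    def test_half_life_scale_invariance(self, table2_params):
        doubled = table2_params.replace(cl_f=2 * 80.9, v_f=2 * 628.0)
        assert elimination_half_life(doubled, "VEN") == pytest.approx(
            elimination_half_life(table2_params, "VEN"))

    @pytest.mark.parametrize("ka,expected", [(0.63, 1.6), (1.0, 1.0)])
    def test_mean_absorption_time(self, table2_params, ka, expected):
        assert round(mean_absorption_time(table2_params.replace(ka=ka)), 1) == expected

    def test_mean_absorption_time_reciprocal_scaling(self, table2_params):
        assert mean_absorption_time(table2_params.replace(ka=0.315)) == pytest.approx(
            2.0 * mean_absorption_time(table2_params.replace(ka=0.63)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    cl=st.floats(20.0, 320.0), v=st.floats(150.0, 2500.0),
    clm=st.floats(5.0, 90.0), vm=st.floats(60.0, 950.0),
    fp=st.floats(0.0, 1.0), t=st.floats(0.0, 72.0),
)
def test_concentrations_nonnegative(cl, v, clm, vm, fp, t):
    p = StructuralParams(cl, v, clm, vm, 0.63, fp)
    reg = Regimen.single(50.0)
    assert conc_parent(p, reg, t) >= 0.0
    assert conc_metabolite(p, reg, t) >= 0.0
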