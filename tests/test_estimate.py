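"""FOCEI machinery: eta modes, objective value, fitting and uncertainty."""

import warnings

import numpy as np
import pandas as pd
import pytest

from venpk.covariates import CovariateEffect
from venpk.data import CovariateSet, Dataset
from venpk.engine import Design
from venpk.estimate import (
    FitOptions,
    FoceiEvaluator,
    ModelSpec,
    RandomEffectsSpec,
    ResidualSpec,
    eta_mode,
    fit,
    focei_objective,
    rse,
)
from venpk.model import Regimen, StructuralParams, conc_parent
from venpk.simulate import GeneratorConfig, generate_combined, generate_study1
from venpk.data import apply_blq_rules

from conftest import make_dataset, make_subject_records
from _oracles import aghq_ofv_one_eta, grid_eta_mode

TIMES = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])


def _one_subject_dataset(params, dose=50.0, times=TIMES, eta=0.0, noise=None,
                         subject_id=1):
    p = params.replace(cl_f=params.cl_f * np.exp(eta))
    f = conc_parent(p, Regimen.single(dose), times)
    dv = f if noise is None else f * (1.0 + noise)
    return make_dataset(make_subject_records(subject_id, dose, times, dv))


class TestEtaMode:
    def test_typical_observations_give_zero_mode(self, table2_params):
        """With data exactly at the typical predictions the mode sits at
        zero up to the interaction tilt of the ln h(eta) term, which
        vanishes with the residual variance."""
        ds = _one_subject_dataset(table2_params)
        last = np.inf
        for sigma2 in (0.04, 1e-3, 1e-5):
            model = ModelSpec(params=table2_params,
                              random_effects=RandomEffectsSpec(("cl_f",), (0.2,)),
                              residual=ResidualSpec(sigma2, sigma2))
            eta, _ = eta_mode(ds, 1, model)
            assert np.abs(eta).max() < last
            last = np.abs(eta).max()
        assert last < 1e-5

    def test_vanishing_iiv_forces_zero_mode(self, table2_params, one_eta_model):
        ds = _one_subject_dataset(table2_params, eta=0.4)
        tight = ModelSpec(params=table2_params,
                          random_effects=RandomEffectsSpec(("cl_f",), (1e-8,)),
                          residual=one_eta_model.residual)
        eta, _ = eta_mode(ds, 1, tight)
        assert np.abs(eta).max() < 1e-3

    def test_mode_matches_grid_search_oracle(self, table2_params):
        rng = np.random.default_rng(5)
        times = np.array([2.0, 12.0])
        noise = rng.normal(0.0, 0.15, size=2)
        ds = _one_subject_dataset(table2_params, times=times, eta=0.5, noise=noise)
        model = ModelSpec(params=table2_params,
                          random_effects=RandomEffectsSpec(("cl_f",), (0.2,)),
                          residual=ResidualSpec(0.04, 0.04))
        eta, obj = eta_mode(ds, 1, model)
        ref_eta, ref_obj = grid_eta_mode(
            times, ds.df[ds.df["EVID"] == 0]["DV"].to_numpy(), 50.0,
            table2_params, 0.2, 0.04,
        )
        assert eta[0] == pytest.approx(ref_eta, abs=1e-4)
        assert obj == pytest.approx(ref_obj, abs=1e-6)

    def test_subject_without_informative_observations_is_skipped(self, table2_params,
                                                                 one_eta_model):
        # a lone pre-dose sample is structurally uninformative
        ds = make_dataset(make_subject_records(1, 50.0, [0.0], [0.0]))
        assert eta_mode(ds, 1, one_eta_model) is None


class TestFoceiObjective:
    def test_zero_omega_reduces_to_extended_least_squares(self, table2_params):
        rng = np.random.default_rng(11)
        recs = []
        for sid in (1, 2, 3):
            noise = rng.normal(0.0, 0.1, size=len(TIMES))
            f = conc_parent(table2_params, Regimen.single(50.0), TIMES)
            recs += make_subject_records(sid, 50.0, TIMES, f * (1 + noise))
        ds = make_dataset(recs)
        sigma2 = 0.04
        model = ModelSpec(params=table2_params,
                          random_effects=RandomEffectsSpec(("cl_f",), (0.0,)),
                          residual=ResidualSpec(sigma2, sigma2))
        ofv = focei_objective(ds, model)
        f = conc_parent(table2_params, Regimen.single(50.0), TIMES)
        y = ds.df[ds.df["EVID"] == 0]["DV"].to_numpy().reshape(3, -1)
        expected = sum(
            np.sum(np.log(sigma2 * f**2) + (yi - f) ** 2 / (sigma2 * f**2))
            for yi in y
        )
        assert ofv == pytest.approx(expected, rel=1e-12)

    def test_duplicating_every_subject_doubles_ofv(self, table2_params, one_eta_model):
        rng = np.random.default_rng(3)
        recs = []
        for sid in (1, 2):
            noise = rng.normal(0.0, 0.15, size=len(TIMES))
            recs += make_subject_records(
                sid, 50.0, TIMES,
                conc_parent(table2_params, Regimen.single(50.0), TIMES) * (1 + noise))
        ds = make_dataset(recs)
        df2 = ds.df.copy()
        df2["ID"] += 10
        doubled = Dataset(pd.concat([ds.df, df2], ignore_index=True), ds.rules)
        o1 = focei_objective(ds, one_eta_model)
        o2 = focei_objective(doubled, one_eta_model)
        assert o2 == pytest.approx(2.0 * o1, rel=1e-9)

    def test_subject_order_invariance(self, table2_params, one_eta_model):
        rng = np.random.default_rng(4)
        recs = []
        for sid in (1, 2, 3, 4):
            noise = rng.normal(0.0, 0.15, size=len(TIMES))
            recs += make_subject_records(
                sid, 50.0, TIMES,
                conc_parent(table2_params, Regimen.single(50.0), TIMES) * (1 + noise))
        ds = make_dataset(recs)
        blocks = [ds.df[ds.df["ID"] == sid] for sid in (3, 1, 4, 2)]
        permuted = Dataset(pd.concat(blocks, ignore_index=True), ds.rules)
        assert focei_objective(permuted, one_eta_model) == pytest.approx(
            focei_objective(ds, one_eta_model), abs=1e-8)

    def test_matches_adaptive_quadrature_on_one_eta_toys(self, table2_params):
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(3):
            omega2 = float(rng.uniform(0.05, 0.4))
            sigma2 = float(rng.uniform(0.01, 0.08))
            eta_true = rng.normal(0.0, np.sqrt(omega2))
            noise = rng.normal(0.0, np.sqrt(sigma2), size=len(TIMES))
            ds = _one_subject_dataset(table2_params, eta=eta_true, noise=noise)
            model = ModelSpec(params=table2_params,
                              random_effects=RandomEffectsSpec(("cl_f",), (omega2,)),
                              residual=ResidualSpec(sigma2, sigma2))
            ofv = focei_objective(ds, model)
            ref = aghq_ofv_one_eta(
                TIMES, ds.df[ds.df["EVID"] == 0]["DV"].to_numpy(), 50.0,
                table2_params, omega2, sigma2)
            worst = max(worst, abs(ofv - ref))
        assert worst <= 0.5


class TestFit:
    def test_self_consistency_small_noise(self, table2_params):
        """Refitting data simulated at the initial values with small noise
        recovers those values to within a few design-predicted SEs."""
        rng = np.random.default_rng(8)
        omega2, sigma2 = 0.005, 0.002
        recs = []
        n = 40
        for sid in range(1, n + 1):
            eta = rng.normal(0.0, np.sqrt(omega2))
            p = table2_params.replace(cl_f=table2_params.cl_f * np.exp(eta))
            f = conc_parent(p, Regimen.single(50.0), TIMES)
            dv = f * (1.0 + rng.normal(0.0, np.sqrt(sigma2), size=len(TIMES)))
            recs += make_subject_records(sid, 50.0, TIMES, dv)
        ds = make_dataset(recs)
        model = ModelSpec(
            params=table2_params,
            random_effects=RandomEffectsSpec(("cl_f",), (omega2,)),
            residual=ResidualSpec(sigma2, sigma2),
            fixed=frozenset({"ka", "fp", "clm_f", "vm_f"}),
        )
        init_ofv = focei_objective(ds, model)
        res = fit(ds, model, FitOptions(maxiter=60))
        assert res.ofv <= init_ofv + 1e-6
        # cl_f SE ~ sqrt(omega2/n) ~ 1.1%; allow 3 SEs
        assert res.estimates["cl_f"] == pytest.approx(80.9, rel=0.034)
        assert res.estimates["v_f"] == pytest.approx(628.0, rel=0.034)
        assert len(res.etas) == n

    def test_too_few_subjects_rejected(self, table2_params, one_eta_model):
        ds = _one_subject_dataset(table2_params)
        with pytest.raises(Exception):
            fit(ds, one_eta_model)


class TestRse:
    def _simple_dataset(self, table2_params, n, seed=0):
        rng = np.random.default_rng(seed)
        omega2, sigma2 = 0.1, 0.02
        times = np.array([1.0, 4.0, 12.0, 24.0])
        recs = []
        for sid in range(1, n + 1):
            eta = rng.normal(0.0, np.sqrt(omega2))
            p = table2_params.replace(cl_f=table2_params.cl_f * np.exp(eta))
            f = conc_parent(p, Regimen.single(50.0), times)
            dv = f * (1.0 + rng.normal(0.0, np.sqrt(sigma2), size=len(times)))
            recs += make_subject_records(sid, 50.0, times, dv)
        model = ModelSpec(
            params=table2_params,
            random_effects=RandomEffectsSpec(("cl_f",), (omega2,)),
            residual=ResidualSpec(sigma2, sigma2),
            fixed=frozenset({"ka", "fp", "clm_f", "vm_f"}),
        )
        return make_dataset(recs), model

    def test_fixed_ka_reported_not_applicable(self, table2_params):
        ds, model = self._simple_dataset(table2_params, 12)
        res = fit(ds, model, FitOptions(maxiter=40))
        rses, method = rse(res, ds)
        assert np.isnan(rses["theta:ka"])
        assert method.startswith("hessian")
        assert all(v > 0 for k, v in rses.items() if not np.isnan(v))

    def test_rse_halves_with_quadrupled_subjects(self, table2_params):
        """CLT scaling: four times the subjects at the same design gives
        half the relative standard error."""
        out = {}
        for n in (12, 48):
            ds, model = self._simple_dataset(table2_params, n, seed=1)
            res = fit(ds, model, FitOptions(maxiter=40))
            rses, _ = rse(res, ds)
            out[n] = rses["theta:cl_f"]
        assert out[48] == pytest.approx(out[12] / 2.0, rel=0.25)

    def test_bootstrap_fallback_produces_estimates(self, table2_params):
        ds, model = self._simple_dataset(table2_params, 8, seed=2)
        res = fit(ds, model, FitOptions(maxiter=30))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rses, method = rse(res, ds, FitOptions(maxiter=20),
                               method="bootstrap", n_bootstrap=4)
        assert method == "bootstrap"
        assert np.isfinite(rses["theta:cl_f"])


class TestRecoveryAtScale:
    def test_base_parameters_recovered_within_sampling_noise(self, table2_params,
                                                             final_effects):
        """Simulate-and-refit replicates of a reduced two-study design:
        median relative bias of the well-identified parameters stays within
        the design's own sampling noise."""
        bias = {k: [] for k in ("cl_f", "v_f", "clm_f")}
        for seed in (101, 102, 103):
            cfg = GeneratorConfig(n_healthy=10, n_patients=50)
            ds, _ = generate_combined(cfg, seed=seed)
            clean, _ = apply_blq_rules(ds)
            model = ModelSpec(
                params=table2_params,
                random_effects=RandomEffectsSpec(
                    ("cl_f", "v_f", "clm_f", "vm_f"), (0.219, 0.106, 0.156, 1.38)),
                residual=ResidualSpec(0.123, 0.101),
                covariate_effects=final_effects,
            )
            res = fit(clean, model, FitOptions(maxiter=50, fast_inner=True))
            for k in bias:
                bias[k].append(abs(res.estimates[k] / getattr(table2_params, k) - 1.0))
        # SE(log cl) ~ sqrt(0.219/10) ~ 15%: allow twice that for the median
        assert np.median(bias["cl_f"]) < 0.30
        assert np.median(bias["v_f"]) < 0.25
        assert np.median(bias["clm_f"]) < 0.15
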