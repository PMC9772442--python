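"""Synthetic study generator.

Two designs are emulated so that the whole pipeline can be exercised
without any external data:

* **Study 1** - an intensive single-dose crossover design in 24 healthy male
  volunteers: 50 mg orally in each of two periods separated by a 7-day
  washout, with 15 scheduled parent-drug samples per period (pre-dose and
  0.5-36 h post-dose) and a 0.2 ng/ml lower limit of quantification.
* **Study 2** - a naturalistic therapeutic-drug-monitoring design in 127
  psychiatric patients at steady state: morning trough samples of both
  parent and metabolite on 2-4 visit days, daily doses of 25-300 mg given
  once daily (sustained-release) or split twice daily (rapid-release), and
  quantitation ranges of 4-400 ng/ml (parent) and 20-2000 ng/ml
  (metabolite).

Covariate frequencies and moments follow the pooled demographic summary of
the two studies; in the default deterministic-frequency mode each binary
covariate is assigned to an exact rounded count of patients (stable for
testing), with a Bernoulli mode available.  Laboratory covariates are
generated but carry no effect on any parameter - they exist to exercise
null-covariate behaviour in the selection machinery.

The generator's truth (structural parameters, covariate effects, variance
components and every subject's etas) is emitted alongside the dataset for
recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .covariates import CovariateEffect, apply_covariates
from .data import CovariateSet, Dataset, PKRecord
from .errors import ConfigurationError
from .model import Regimen, StructuralParams, conc

STUDY1_SCHEDULE = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0, 36.0)

#: Default "true" covariate effects of the final model.
DEFAULT_EFFECTS = (
    CovariateEffect("cl_f", "morbid", "linear", -0.617),
    CovariateEffect("cl_f", "amisulpride", "linear", -0.392),
    CovariateEffect("clm_f", "amisulpride", "linear", 0.593),
)

# Patient-population covariate frequencies (fractions of 127).
_PATIENT_FREQ = {
    "sex": 0.5512,
    "formulation": 0.8362,  # sustained-release
    "smoking": 0.0787,
    "drinking": 0.0472,
    "valproic_acid": 0.1816,
    "quetiapine": 0.2338,
    "clozapine": 0.1567,
    "olanzapine": 0.2450,
    "risperidone": 0.1318,
    "amisulpride": 0.0547,
}

# Laboratory moments (mean, sd, low, high) per study.
_LABS_HEALTHY = {
    "alt": (21.67, 7.15, 7.0, 41.0),
    "ast": (19.21, 5.64, 15.0, 42.0),
    "bun": (4.35, 0.97, 2.63, 5.84),
    "cr": (76.13, 12.41, 51.0, 106.0),
}
_LABS_PATIENT = {
    "alt": (22.92, 18.36, 3.0, 112.0),
    "ast": (22.22, 14.13, 9.0, 116.0),
    "bun": (3.91, 1.36, 1.21, 8.61),
    "cr": (68.23, 16.15, 6.38, 129.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """True parameters and design descriptors for the synthetic studies."""

    params: StructuralParams = StructuralParams(
        cl_f=80.9, v_f=628.0, clm_f=22.1, vm_f=238.0, ka=0.63, fp=0.048
    )
    effects: tuple[CovariateEffect, ...] = DEFAULT_EFFECTS
    iiv_params: tuple[str, ...] = ("cl_f", "v_f", "clm_f", "vm_f")
    omega2: tuple[float, ...] = (0.219, 0.106, 0.156, 1.38)
    sigma2_ven: float = 0.123
    sigma2_odv: float = 0.101
    n_healthy: int = 24
    n_patients: int = 127
    schedule: tuple[float, ...] = STUDY1_SCHEDULE
    n_periods: int = 2
    washout_h: float = 168.0
    study1_dose_mg: float = 50.0
    dose_mean: float = 132.86
    dose_sd: float = 64.20
    dose_range: tuple[float, float] = (25.0, 300.0)
    dose_step: float = 12.5
    visits_range: tuple[int, int] = (2, 4)
    visit_day_range: tuple[int, int] = (3, 30)
    deterministic_frequencies: bool = True
    master_seed: int = 978202

    def __post_init__(self) -> None:
        if len(self.iiv_params) != len(self.omega2):
            raise ConfigurationError("omega2 length must match iiv_params")
        if self.n_healthy < 1 or self.n_patients < 1:
            raise ConfigurationError("need at least one subject per study")


@dataclass(frozen=True)
class SubjectProfile:
    """Design assignment for one synthetic subject."""

    subject_id: int
    study: int
    covariates: CovariateSet
    regimen: Regimen
    sampling_times: dict[str, np.ndarray]


def _trunc_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _assign_binary(rng, n: int, frac: float, deterministic: bool) -> np.ndarray:
    if deterministic:
        k = int(round(frac * n))
        out = np.zeros(n)
        out[rng.permutation(n)[:k]] = 1.0
        return out
    return (rng.random(n) < frac).astype(float)


def _true_subject_params(
    config: GeneratorConfig, cov: CovariateSet, eta: np.ndarray
) -> StructuralParams:
    typical = apply_covariates(config.params, config.effects, cov)
    changes = {
        p: getattr(typical, p) * float(np.exp(e))
        for p, e in zip(config.iiv_params, eta)
    }
    return typical.replace(**changes)


def _observe(rng, f: np.ndarray, sigma2: float) -> np.ndarray:
    eps = rng.normal(0.0, np.sqrt(sigma2), size=f.shape) if sigma2 > 0 else 0.0
    return np.maximum(f * (1.0 + eps), 0.0)


@dataclass
class Truth:
    """Generator truth for recovery testing."""

    config_seed: int
    params: dict[str, float]
    effects: list[dict]
    iiv_params: list[str]
    omega2: list[float]
    sigma2_ven: float
    sigma2_odv: float
    etas: dict[int, list[float]]

    def write(self, path: str | Path) -> None:
        payload = {
            "config_seed": self.config_seed,
            "params": self.params,
            "effects": self.effects,
            "iiv_params": self.iiv_params,
            "omega2": self.omega2,
            "sigma2_ven": self.sigma2_ven,
            "sigma2_odv": self.sigma2_odv,
            "etas": {str(k): v for k, v in self.etas.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "Truth":
        payload = json.loads(Path(path).read_text())
        payload["etas"] = {int(k): v for k, v in payload["etas"].items()}
        return cls(**payload)


def _struct_dict(p: StructuralParams) -> dict[str, float]:
    return {k: getattr(p, k) for k in ("cl_f", "v_f", "clm_f", "vm_f", "ka", "fp")}


def generate_study1(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    id_offset: int = 0,
) -> tuple[Dataset, Truth]:
    """Intensive healthy-volunteer crossover study (parent analyte only)."""
    config = config or GeneratorConfig()
    seed = config.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_healthy
    ages = rng.integers(18, 28, size=n).astype(float)
    weights = _trunc_normal(rng, 62.5, 6.9, 54.0, 80.0, n)
    labs = {k: _trunc_normal(rng, *m, n) for k, m in _LABS_HEALTHY.items()}
    omega = np.sqrt(np.asarray(config.omega2))
    etas = rng.normal(0.0, 1.0, size=(n, len(omega))) * omega
    records: list[PKRecord] = []
    truth_etas: dict[int, list[float]] = {}
    for i in range(n):
        sid = id_offset + i + 1
        cov = CovariateSet(
            morbid=0.0, sex=0.0, age=ages[i], weight=float(weights[i]),
            formulation=0.0,
            alt=float(labs["alt"][i]), ast=float(labs["ast"][i]),
            bun=float(labs["bun"][i]), cr=float(labs["cr"][i]),
        )
        truth_etas[sid] = [float(e) for e in etas[i]]
        p_i = _true_subject_params(config, cov, etas[i])
        dose_times = [k * config.washout_h for k in range(config.n_periods)]
        regimen = Regimen.from_events(
            [  # two independent occasions, full washout, no carryover
                _dose_event(t, config.study1_dose_mg) for t in dose_times
            ]
        )
        obs_times = np.concatenate(
            [t0 + np.asarray(config.schedule) for t0 in dose_times]
        )
        f = conc(p_i, regimen, obs_times, "VEN")
        dv = _observe(rng, f, config.sigma2_ven)
        for t0 in dose_times:
            records.append(
                PKRecord(subject_id=sid, time=t0, event_type="dose",
                         amount=config.study1_dose_mg, covariates=cov)
            )
            sel = (obs_times >= t0) & (obs_times <= t0 + config.schedule[-1])
            for t, v in zip(obs_times[sel], dv[sel]):
                records.append(
                    PKRecord(subject_id=sid, time=float(t), event_type="observation",
                             analyte="VEN", dv=float(v), covariates=cov)
                )
    dataset = Dataset.from_records(records)
    truth = Truth(
        config_seed=seed, params=_struct_dict(config.params),
        effects=[{"parameter": e.parameter, "covariate": e.covariate,
                  "form": e.form, "theta": e.theta, "reference": e.reference}
                 for e in config.effects],
        iiv_params=list(config.iiv_params), omega2=list(config.omega2),
        sigma2_ven=config.sigma2_ven, sigma2_odv=config.sigma2_odv,
        etas=truth_etas,
    )
    return dataset, truth


def _dose_event(time: float, amount: float):
    from .model import DoseEvent

    return DoseEvent(time=time, amount=amount)


def generate_study2(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    id_offset: int = 0,
) -> tuple[Dataset, Truth]:
    """Sparse steady-state trough study in psychiatric patients (both
    analytes)."""
    from .model import DoseEvent

    config = config or GeneratorConfig()
    seed = config.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_patients
    det = config.deterministic_frequencies
    binaries = {k: _assign_binary(rng, n, p, det) for k, p in _PATIENT_FREQ.items()}
    ages = _trunc_normal(rng, 37.86, 17.59, 14.0, 86.0, n)
    weights = _trunc_normal(rng, 61.95, 11.02, 38.0, 93.0, n)
    labs = {k: _trunc_normal(rng, *m, n) for k, m in _LABS_PATIENT.items()}
    lo, hi = config.dose_range
    daily = _trunc_normal(rng, config.dose_mean, config.dose_sd, lo, hi, n)
    daily = np.clip(np.round(daily / config.dose_step) * config.dose_step, lo, hi)
    omega = np.sqrt(np.asarray(config.omega2))
    etas = rng.normal(0.0, 1.0, size=(n, len(omega))) * omega
    records: list[PKRecord] = []
    truth_etas: dict[int, list[float]] = {}
    v_lo, v_hi = config.visits_range
    d_lo, d_hi = config.visit_day_range
    for i in range(n):
        sid = id_offset + i + 1
        cov = CovariateSet(
            morbid=1.0, sex=binaries["sex"][i], age=float(ages[i]),
            weight=float(weights[i]), formulation=binaries["formulation"][i],
            smoking=binaries["smoking"][i], drinking=binaries["drinking"][i],
            valproic_acid=binaries["valproic_acid"][i],
            quetiapine=binaries["quetiapine"][i],
            clozapine=binaries["clozapine"][i],
            olanzapine=binaries["olanzapine"][i],
            risperidone=binaries["risperidone"][i],
            amisulpride=binaries["amisulpride"][i],
            alt=float(labs["alt"][i]), ast=float(labs["ast"][i]),
            bun=float(labs["bun"][i]), cr=float(labs["cr"][i]),
        )
        truth_etas[sid] = [float(e) for e in etas[i]]
        p_i = _true_subject_params(config, cov, etas[i])
        sustained = binaries["formulation"][i] == 1.0
        tau = 24.0 if sustained else 12.0
        amount = float(daily[i]) if sustained else float(daily[i]) / 2.0
        regimen = Regimen.from_events(
            [DoseEvent(time=0.0, amount=amount, interdose_interval=tau,
                       steady_state=True)]
        )
        n_visits = int(rng.integers(v_lo, v_hi + 1))
        days = rng.choice(np.arange(d_lo, d_hi + 1), size=n_visits, replace=False)
        days.sort()
        # morning trough: sampled up to 1 h before the scheduled dose
        times = days * 24.0 - rng.uniform(0.0, 1.0, size=n_visits)
        f_ven = conc(p_i, regimen, times, "VEN")
        f_odv = conc(p_i, regimen, times, "ODV")
        dv_ven = _observe(rng, f_ven, config.sigma2_ven)
        dv_odv = _observe(rng, f_odv, config.sigma2_odv)
        records.append(
            PKRecord(subject_id=sid, time=0.0, event_type="dose", amount=amount,
                     steady_state=True, interdose_interval=tau, covariates=cov)
        )
        for t, cv, co in zip(times, dv_ven, dv_odv):
            records.append(
                PKRecord(subject_id=sid, time=float(t), event_type="observation",
                         analyte="VEN", dv=float(cv), covariates=cov)
            )
            records.append(
                PKRecord(subject_id=sid, time=float(t), event_type="observation",
                         analyte="ODV", dv=float(co), covariates=cov)
            )
    dataset = Dataset.from_records(records)
    truth = Truth(
        config_seed=seed, params=_struct_dict(config.params),
        effects=[{"parameter": e.parameter, "covariate": e.covariate,
                  "form": e.form, "theta": e.theta, "reference": e.reference}
                 for e in config.effects],
        iiv_params=list(config.iiv_params), omega2=list(config.omega2),
        sigma2_ven=config.sigma2_ven, sigma2_odv=config.sigma2_odv,
        etas=truth_etas,
    )
    return dataset, truth


def generate_combined(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> tuple[Dataset, Truth]:
    """Both studies pooled with disjoint subject ids (1-24 healthy,
    25-151 patients by default)."""
    import pandas as pd

    config = config or GeneratorConfig()
    seed = config.master_seed if seed is None else seed
    ds1, t1 = generate_study1(config, seed=seed, id_offset=0)
    ds2, t2 = generate_study2(config, seed=seed + 1, id_offset=config.n_healthy)
    df = pd.concat([ds1.df, ds2.df], ignore_index=True)
    rules = dict(ds1.rules)
    rules.update(ds2.rules)
    etas = dict(t1.etas)
    etas.update(t2.etas)
    truth = Truth(
        config_seed=seed, params=t1.params, effects=t1.effects,
        iiv_params=t1.iiv_params, omega2=t1.omega2,
        sigma2_ven=t1.sigma2_ven, sigma2_odv=t1.sigma2_odv, etas=etas,
    )
    return Dataset(df, rules), truth
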