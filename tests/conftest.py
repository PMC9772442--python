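import numpy as np
import pytest

from venpk.covariates import CovariateEffect
from venpk.data import CovariateSet, Dataset, PKRecord
from venpk.estimate import ModelSpec, RandomEffectsSpec, ResidualSpec
from venpk.model import StructuralParams


@pytest.fixture
def table2_params() -> StructuralParams:
    """Published final-model typical values used as the generator truth."""
    return StructuralParams(cl_f=80.9, v_f=628.0, clm_f=22.1, vm_f=238.0,
                            ka=0.63, fp=0.048)


@pytest.fixture
def final_effects() -> tuple[CovariateEffect, ...]:
    return (
        CovariateEffect("cl_f", "morbid", "linear", -0.617),
        CovariateEffect("cl_f", "amisulpride", "linear", -0.392),
        CovariateEffect("clm_f", "amisulpride", "linear", 0.593),
    )


def make_subject_records(
    subject_id: int,
    dose: float,
    times,
    dvs,
    analyte: str = "VEN",
    covariates: CovariateSet | None = None,
    steady_state: bool = False,
    interval: float = 0.0,
) -> list[PKRecord]:
    cov = covariates or CovariateSet()
    records = [
        PKRecord(subject_id=subject_id, time=0.0, event_type="dose", amount=dose,
                 steady_state=steady_state, interdose_interval=interval,
                 covariates=cov)
    ]
    for t, dv in zip(times, dvs):
        records.append(
            PKRecord(subject_id=subject_id, time=float(t),
                     event_type="observation", analyte=analyte,
                     dv=float(dv), covariates=cov)
        )
    return records


def make_dataset(records) -> Dataset:
    return Dataset.from_records(records)


@pytest.fixture
def one_eta_model(table2_params) -> ModelSpec:
    """Single IIV on parent clearance, proportional parent error."""
    return ModelSpec(
        params=table2_params,
        random_effects=RandomEffectsSpec(("cl_f",), (0.2,)),
        residual=ResidualSpec(0.04, 0.04),
    )
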