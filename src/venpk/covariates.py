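"""Covariate effects on typical pharmacokinetic parameters.

Two functional forms are supported:

* categorical (``linear``): ``TV * (1 + theta * X)`` with X in {0, 1} and a
  signed theta, so a printed "decrease of 61.7%" corresponds to
  ``theta = -0.617``;
* continuous (``power``): ``TV * (X / ref)^theta`` with the reference value
  normally the pooled median of the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import CovariateSet
from .errors import ValidationError
from .model import StructuralParams

_STRUCTURAL_FIELDS = ("cl_f", "v_f", "clm_f", "vm_f", "ka", "fp")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation.

    ``parameter`` is a structural parameter name (``cl_f``, ``v_f``,
    ``clm_f``, ``vm_f``, ``ka`` or ``fp``); ``covariate`` is a
    :class:`~venpk.data.CovariateSet` field name.
    """

    parameter: str
    covariate: str
    form: str = "linear"  # "linear" (categorical) | "power" (continuous)
    theta: float = 0.0
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in _STRUCTURAL_FIELDS:
            raise ValidationError(f"unknown target parameter {self.parameter!r}")
        if self.form == "linear":
            if self.theta <= -1.0:
                raise ValidationError(
                    f"categorical effect needs 1 + theta*X > 0 over X in {{0,1}}; "
                    f"theta={self.theta!r}"
                )
        elif self.form == "power":
            if self.reference is None or not self.reference > 0.0:
                raise ValidationError("power effect needs a positive reference value")
        else:
            raise ValidationError(f"unknown effect form {self.form!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.parameter, self.covariate)

    def factor(self, x):
        """Multiplicative factor on the typical value at covariate value x."""
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            f = 1.0 + self.theta * x
            if np.any(f <= 0.0):
                raise ValidationError(
                    f"effect {self.covariate}->{self.parameter}: 1 + theta*X <= 0"
                )
            return f
        if np.any(x <= 0.0):
            raise ValidationError(
                f"power effect {self.covariate}->{self.parameter} needs positive "
                "covariate values"
            )
        return (x / self.reference) ** self.theta

    def with_theta(self, theta: float) -> "CovariateEffect":
        return CovariateEffect(self.parameter, self.covariate, self.form, theta, self.reference)


def apply_covariates(
    params: StructuralParams,
    effects: Sequence[CovariateEffect],
    covariates: CovariateSet,
) -> StructuralParams:
    """Individual typical parameters after applying every covariate effect."""
    cov = covariates.as_dict()
    changes: dict[str, float] = {}
    for eff in effects:
        if eff.covariate not in cov:
            raise ValidationError(f"covariate {eff.covariate!r} not available")
        base = changes.get(eff.parameter, getattr(params, eff.parameter))
        changes[eff.parameter] = base * float(eff.factor(cov[eff.covariate]))
    return params.replace(**changes) if changes else params


def percent_change(effect: CovariateEffect, value: float | None = None) -> float:
    """Signed percent change in the typical parameter caused by the effect.

    For a categorical effect this is ``100 * theta`` (the change when the
    indicator switches on); for a power effect the covariate ``value`` at
    which to evaluate the change relative to the reference is required.
    """
    if effect.form == "linear":
        return 100.0 * effect.theta
    if value is None:
        raise ValidationError("percent_change of a power effect needs a covariate value")
    return 100.0 * (float(effect.factor(value)) - 1.0)


def covariate_factor_arrays(
    effects: Sequence[CovariateEffect],
    cov_arrays: Mapping[str, np.ndarray],
    n_subjects: int,
) -> dict[str, np.ndarray]:
    """Per-subject multiplicative factors on each structural parameter.

    Vectorised counterpart of :func:`apply_covariates` used by the
    estimation engine; returns a factor array of shape ``(n_subjects,)`` per
    targeted parameter.
    """
    factors: dict[str, np.ndarray] = {}
    for eff in effects:
        if eff.covariate not in cov_arrays:
            raise ValidationError(f"covariate {eff.covariate!r} not in design")
        f = factors.get(eff.parameter, np.ones(n_subjects))
        factors[eff.parameter] = f * eff.factor(cov_arrays[eff.covariate])
    return factors
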