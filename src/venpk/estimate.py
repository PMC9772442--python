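"""FOCEI estimation of the joint parent-metabolite mixed-effects model.

Inter-individual variability is log-normal (``P_i = P_tv * exp(eta)``) with
diagonal variance matrix Omega; the residual model is proportional per
analyte (an additive component can be configured).  Estimation follows the
first-order conditional approach with interaction:

* per subject, the empirical-Bayes eta mode minimises the conditional
  objective ``sum_j [(y_j - f_j(eta))^2 / h_j(eta) + ln h_j(eta)]
  + eta' Omega^-1 eta`` with ``h = sigma^2 f^2`` evaluated at the
  conditional estimate (the "interaction" part);
* the marginal -2 log-likelihood is approximated by linearising ``f`` around
  the mode: with ``G = df/deta`` at the mode,
  ``C = G Omega G' + diag(h)``, ``r = y - f(eta) + G eta``, the subject
  contribution is ``ln|C| + r' C^-1 r`` (the additive ``n ln 2pi`` constant
  is omitted, as is conventional for NONMEM-style objective function
  values);
* the outer problem optimises transformed parameters (log for positive
  quantities, logit for the conversion fraction, log(1+theta) for
  categorical covariate effects) by quasi-Newton with numerical gradients.

Uncertainty is reported as RSE% from the inverse of half the numerically
differentiated OFV Hessian, with a case-resampling bootstrap fallback when
that Hessian is not positive definite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .covariates import CovariateEffect, covariate_factor_arrays
from .data import DVID_VEN, Dataset
from .engine import Design
from .errors import ConfigurationError, ValidationError, VenpkError
from .model import StructuralParams

_STRUCT_NAMES = ("cl_f", "v_f", "clm_f", "vm_f", "ka", "fp")
_F_FLOOR = 1e-12


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which structural parameters carry IIV, and their log-scale variances."""

    iiv_params: tuple[str, ...] = ("cl_f", "v_f", "clm_f", "vm_f")
    omega2: tuple[float, ...] = (0.1, 0.1, 0.1, 0.1)

    def __post_init__(self) -> None:
        if len(self.iiv_params) != len(self.omega2):
            raise ConfigurationError("omega2 length must match iiv_params")
        if any(w < 0 for w in self.omega2):
            raise ConfigurationError("omega2 entries must be >= 0")
        bad = [p for p in self.iiv_params if p not in _STRUCT_NAMES]
        if bad:
            raise ConfigurationError(f"unknown IIV parameters {bad}")


@dataclass(frozen=True)
class ResidualSpec:
    """Proportional (optionally combined) residual variance per analyte."""

    sigma2_ven: float = 0.05
    sigma2_odv: float = 0.05
    additive_ven: float = 0.0
    additive_odv: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma2_ven > 0 and self.sigma2_odv > 0):
            raise ConfigurationError("proportional residual variances must be > 0")
        if self.additive_ven < 0 or self.additive_odv < 0:
            raise ConfigurationError("additive residual variances must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """Structural values, random-effects and residual specification, and the
    covariate map.  ``fixed`` lists structural parameters excluded from the
    estimated vector (the absorption rate constant by default)."""

    params: StructuralParams
    random_effects: RandomEffectsSpec = RandomEffectsSpec()
    residual: ResidualSpec = ResidualSpec()
    covariate_effects: tuple[CovariateEffect, ...] = ()
    fixed: frozenset[str] = frozenset({"ka"})

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, key: tuple[str, str]) -> "ModelSpec":
        kept = tuple(e for e in self.covariate_effects if e.key != key)
        return replace(self, covariate_effects=kept)


@dataclass
class FitOptions:
    maxiter: int = 200
    outer_eps: float = 1e-5        # finite-difference step of the outer gradient
    outer_ftol: float = 1e-8       # relative OFV change at outer convergence
    inner_gtol: float = 1e-5       # scaled gradient norm at the eta mode
    inner_maxiter: int = 80
    # skip the exact-Newton polish phase during outer objective evaluations
    # (the final reported OFV of a fit is always computed at full precision)
    fast_inner: bool = False


@dataclass
class FitResult:
    """Estimates, objective value, empirical-Bayes etas and metadata."""

    model: ModelSpec
    estimates: dict[str, float]
    ofv: float
    etas: pd.DataFrame
    converged: bool
    message: str
    n_obj_evals: int
    n_obs: int
    n_subjects: int
    n_dropped_structural_zero: int
    skipped_subjects: list[int]
    rse: dict[str, float] | None = None
    rse_method: str | None = None
    iterations: list[tuple[int, float]] = field(default_factory=list)

    def to_report(self) -> dict:
        """Machine-readable summary (JSON-serialisable)."""
        return {
            "ofv": self.ofv,
            "converged": self.converged,
            "message": self.message,
            "estimates": self.estimates,
            "rse_percent": self.rse,
            "rse_method": self.rse_method,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "etas": {str(k): list(map(float, v)) for k, v in self.etas.iterrows()},
        }


# ---------------------------------------------------------------------------
# Evaluator: holds the flattened design and computes inner modes and the
# FOCEI objective for a given parameter configuration.
# ---------------------------------------------------------------------------


class FoceiEvaluator:
    def __init__(self, design: Design, model: ModelSpec, options: FitOptions | None = None):
        self.design = design
        self.model = model
        self.options = options or FitOptions()
        self._eta_warm: np.ndarray | None = None
        self.set_params(model.params, model.covariate_effects,
                        np.asarray(model.random_effects.omega2, dtype=float),
                        model.residual)

    # -- parameter configuration ------------------------------------------
    def set_params(
        self,
        params: StructuralParams,
        effects: Sequence[CovariateEffect],
        omega2: np.ndarray,
        residual: ResidualSpec,
    ) -> None:
        """One parameter configuration shared by every (virtual) subject."""
        d = self.design
        S = d.n_subjects
        factors = covariate_factor_arrays(effects, d.cov, S)
        self.tv = {
            name: np.full(S, getattr(params, name)) * factors.get(name, 1.0)
            for name in _STRUCT_NAMES
        }
        self.params = params
        self.effects = tuple(effects)
        iiv = self.model.random_effects.iiv_params
        omega2 = np.asarray(omega2, dtype=float)
        self.active = np.nonzero(omega2 > 0.0)[0]
        self.eta_params = tuple(iiv[i] for i in self.active)
        self.omega2 = np.tile(omega2[self.active], (S, 1))
        self.omega2_full = omega2
        self.residual = residual
        self.s2 = d.sigma2_per_obs(residual.sigma2_ven, residual.sigma2_odv)
        self.add2 = np.where(
            d.obs_dvid == DVID_VEN, residual.additive_ven, residual.additive_odv
        )

    def set_params_multi(self, configs: Sequence[tuple]) -> None:
        """One configuration per design block (see :meth:`Design.tile`).

        ``configs`` holds ``(params, effects, omega2, residual)`` tuples,
        one per block, so a whole finite-difference stencil is evaluated in
        a single vectorised pass.
        """
        d = self.design
        base = getattr(d, "base", d)
        S0 = base.n_subjects
        if len(configs) * S0 != d.n_subjects:
            raise ConfigurationError("configs must match the design's block count")
        iiv = self.model.random_effects.iiv_params
        tvs: dict[str, list] = {name: [] for name in _STRUCT_NAMES}
        om_parts, s2_parts, add_parts = [], [], []
        active = None
        for params, effects, omega2, residual in configs:
            factors = covariate_factor_arrays(effects, base.cov, S0)
            for name in _STRUCT_NAMES:
                tvs[name].append(
                    np.full(S0, getattr(params, name)) * factors.get(name, 1.0)
                )
            omega2 = np.asarray(omega2, dtype=float)
            act = np.nonzero(omega2 > 0.0)[0]
            if active is None:
                active = act
            elif not np.array_equal(active, act):
                raise ConfigurationError("blocks must share the IIV structure")
            om_parts.append(np.tile(omega2[act], (S0, 1)))
            s2_parts.append(
                base.sigma2_per_obs(residual.sigma2_ven, residual.sigma2_odv)
            )
            add_parts.append(
                np.where(base.obs_dvid == DVID_VEN,
                         residual.additive_ven, residual.additive_odv)
            )
        self.params, self.effects, self.residual = configs[0][0], tuple(configs[0][1]), configs[0][3]
        self.active = active
        self.eta_params = tuple(iiv[i] for i in active)
        self.omega2 = np.concatenate(om_parts, axis=0)
        self.omega2_full = np.asarray(configs[0][2], dtype=float)
        self.tv = {name: np.concatenate(parts) for name, parts in tvs.items()}
        self.s2 = np.concatenate(s2_parts)
        self.add2 = np.concatenate(add_parts)

    @property
    def n_eta(self) -> int:
        return len(self.active)

    # -- prediction --------------------------------------------------------
    def predict(self, etas: np.ndarray) -> np.ndarray:
        """Concentrations; ``etas`` has shape ``leading + (S, n_eta)``."""
        p = {k: v for k, v in self.tv.items()}
        lead = etas.shape[:-2]
        if lead:
            p = {k: np.broadcast_to(v, lead + v.shape) for k, v in p.items()}
        for j, name in enumerate(self.eta_params):
            p[name] = p[name] * np.exp(etas[..., j])
        return self.design.predict(
            p["cl_f"], p["v_f"], p["clm_f"], p["vm_f"], p["ka"], p["fp"]
        )

    def _h(self, f: np.ndarray) -> np.ndarray:
        return self.s2 * f * f + self.add2

    def _per_obs_loss(self, f: np.ndarray) -> np.ndarray:
        y = self.design.y
        h = self._h(f)
        r = y - f
        return r * r / h + np.log(h)

    def subject_objectives(self, etas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Conditional objective per subject, and the predictions."""
        f = np.maximum(self.predict(etas), _F_FLOOR)
        loss = self._per_obs_loss(f)
        per_sub = np.bincount(
            self.design.obs_subject, weights=loss, minlength=self.design.n_subjects
        )
        if self.n_eta:
            per_sub = per_sub + np.sum(etas * etas / self.omega2, axis=-1)
        return per_sub, f

    # -- inner problem -----------------------------------------------------
    def _f_and_jac(self, etas: np.ndarray, delta: float = 1e-4, central: bool = True):
        """Predictions and their eta-Jacobian by finite differences.

        All perturbed eta configurations are stacked along a leading axis
        and evaluated in a single vectorised pass.
        """
        n, k = self.design.n_obs, self.n_eta
        if k == 0:
            return np.maximum(self.predict(etas), _F_FLOOR), np.zeros((n, 0))
        b = 2 * k + 1 if central else k + 1
        stack = np.repeat(etas[None], b, axis=0)
        for j in range(k):
            if central:
                stack[1 + 2 * j, :, j] += delta
                stack[2 + 2 * j, :, j] -= delta
            else:
                stack[1 + j, :, j] += delta
        F = self.predict(stack)
        f0 = np.maximum(F[0], _F_FLOOR)
        if central:
            J = (F[1::2] - F[2::2]).T / (2.0 * delta)
        else:
            J = (F[1:] - F[0]).T / delta
        return f0, J

    def eta_modes(
        self,
        eta0: np.ndarray | None = None,
        gtol: float | None = None,
        max_iter: int | None = None,
        fast: bool = False,
    ):
        """Batched Gauss-Newton search for all subjects' eta modes.

        Returns ``(etas, subject_objectives, f, J, converged_mask)``.
        """
        d = self.design
        S, k = d.n_subjects, self.n_eta
        gtol = self.options.inner_gtol if gtol is None else gtol
        max_iter = self.options.inner_maxiter if max_iter is None else max_iter
        if k == 0:
            etas = np.zeros((S, 0))
            obj, f = self.subject_objectives(etas)
            return etas, obj, f, np.zeros((d.n_obs, 0)), np.ones(S, dtype=bool)
        etas = np.zeros((S, k)) if eta0 is None else np.array(eta0, dtype=float)
        obj, _ = self.subject_objectives(etas)
        inv_w = 1.0 / self.omega2
        y = d.y
        state = {"f": None, "J": None}

        def gradient_and_pieces(etas, central=True):
            f0, J = self._f_and_jac(etas, central=central)
            state["f"], state["J"] = f0, J
            h = self._h(f0)
            r = y - f0
            hp = 2.0 * self.s2 * f0
            dldf = -2.0 * r / h - r * r * hp / (h * h) + hp / h
            grad = np.zeros((S, k))
            for j in range(k):
                grad[:, j] = np.bincount(
                    d.obs_subject, weights=J[:, j] * dldf, minlength=S
                )
            grad += 2.0 * etas * inv_w
            return grad, f0, J, h, r, hp, dldf

        def weights(exact, f0, h, r, hp, dldf):
            hpp = 2.0 * self.s2
            if not exact:
                # positive-definite Gauss-Newton weight (second derivative
                # at zero residual); globally safe
                return np.maximum(2.0 / h + hpp / h - hp * hp / (h * h), 1e-10)
            # exact d2(loss)/df2 plus the f-curvature term d2f/deta2
            # approximated by J_a J_b / f (exact for log-linear f, which the
            # multiplicative parameter model nearly is); gives quadratic
            # terminal convergence so the modes are path-independent
            d2l = (
                2.0 / h
                + 4.0 * r * hp / (h * h)
                - r * r * hpp / (h * h)
                + 2.0 * r * r * hp * hp / (h * h * h)
                + hpp / h
                - hp * hp / (h * h)
            )
            return d2l + dldf / np.maximum(f0, _F_FLOOR)

        if fast:
            gtol = gtol * 100.0
        converged = np.zeros(S, dtype=bool)
        for phase, exact in ((0, False), (1, True)):
            lam = np.zeros(S)
            # phase 0: globally-safe Gauss-Newton to get near the modes;
            # phase 1: exact-curvature Newton for quadratic terminal
            # convergence (and hence path-independent modes)
            stall_thresh = 1e-6 * max(1, S) if phase == 0 else 1e-11 * max(1, S)
            n_iter = min(15, max_iter) if phase == 0 else max_iter
            for _ in range(n_iter):
                grad, f0, J, h, r, hp, dldf = gradient_and_pieces(etas, central=False)
                gnorm = np.abs(grad).max(axis=1)
                scale_ = np.maximum(1.0, np.abs(obj))
                converged = gnorm < gtol * scale_
                if converged.all():
                    break
                w = weights(exact, f0, h, r, hp, dldf)
                H = np.zeros((S, k, k))
                for a in range(k):
                    for b in range(a, k):
                        hh = np.bincount(
                            d.obs_subject, weights=w * J[:, a] * J[:, b], minlength=S
                        )
                        H[:, a, b] = hh
                        H[:, b, a] = hh
                H[:, np.arange(k), np.arange(k)] *= (1.0 + lam)[:, None]
                H[:, np.arange(k), np.arange(k)] += 2.0 * inv_w + lam[:, None]
                try:
                    step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
                except np.linalg.LinAlgError:
                    H[:, np.arange(k), np.arange(k)] += 1e-4
                    step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
                # trust cap: stiff observations (near-zero predictions) can
                # make the raw Newton step overshoot by orders of magnitude
                norm = np.abs(step).max(axis=1)
                cap = np.where(norm > 1.0, 1.0 / np.maximum(norm, 1e-300), 1.0)
                step *= cap[:, None]
                descent = np.einsum("sk,sk->s", grad, step)
                step[descent > 0.0] *= -1.0  # indefinite H: flip to descent
                alpha = np.ones(S)
                active = ~converged
                best_obj = obj.copy()
                best_eta = etas.copy()
                step_size = np.abs(step).max(axis=1)
                for _trial in range(16):
                    trial_eta = etas + (alpha * active)[:, None] * step
                    trial_obj, _ = self.subject_objectives(trial_eta)
                    improved = active & (trial_obj < best_obj - 1e-14 * scale_)
                    best_eta[improved] = trial_eta[improved]
                    best_obj[improved] = trial_obj[improved]
                    active = active & ~improved
                    if not active.any():
                        break
                    alpha[active] *= 0.5
                    if (alpha * step_size)[active].max() < 1e-9:
                        break
                made_progress = best_obj < obj - 1e-14 * scale_
                lam = np.where(made_progress, lam / 3.0, np.maximum(lam * 10.0, 1e-4))
                lam = np.where(lam < 1e-6, 0.0, lam)
                total_gain = obj.sum() - best_obj.sum()
                etas, obj = best_eta, best_obj
                if total_gain < stall_thresh and not made_progress.any():
                    break
        # refresh everything at the final etas (the loop may exit right
        # after an update) and settle the convergence labels
        grad, f0, J, h, r, hp, dldf = gradient_and_pieces(etas, central=False)
        gnorm = np.abs(grad).max(axis=1)
        scale_ = np.maximum(1.0, np.abs(obj))
        # subjects within two orders of the tolerance are at the finite-
        # difference resolution limit and are accepted
        converged = gnorm < 100 * gtol * scale_
        return etas, obj, f0, J, converged

    # -- FOCEI objective ---------------------------------------------------
    @property
    def _size_groups(self):
        """Subjects grouped by observation count, for batched linalgebra."""
        if getattr(self, "_groups_cache", None) is None:
            groups: dict[int, list[int]] = {}
            for s, sl in enumerate(self.design.subject_slices):
                groups.setdefault(sl.stop - sl.start, []).append(s)
            cache = []
            for m, subs in groups.items():
                idx = np.array(
                    [np.arange(self.design.subject_slices[s].start,
                               self.design.subject_slices[s].stop) for s in subs]
                )
                cache.append((np.array(subs), idx))
            self._groups_cache = cache
        return self._groups_cache

    def focei_subject_terms(self, etas, f, J):
        """Per-subject ``ln|C| + r' C^-1 r`` and the (C, r) pieces.

        Returns ``(terms (S,), C (per-subject list), r (per-subject list))``
        with batched Cholesky factorisations grouped by observation count.
        """
        d = self.design
        h = self._h(f)
        S = d.n_subjects
        terms = np.empty(S)
        C_out: list[np.ndarray | None] = [None] * S
        r_out: list[np.ndarray | None] = [None] * S
        for subs, idx in self._size_groups:
            g, m = idx.shape
            G = J[idx]  # (g, m, k)
            if self.n_eta:
                C = np.einsum("gmk,gnk->gmn", G * self.omega2[subs][:, None, :], G)
                r = d.y[idx] - f[idx] + np.einsum("gmk,gk->gm", G, etas[subs])
            else:
                C = np.zeros((g, m, m))
                r = d.y[idx] - f[idx]
            C[:, np.arange(m), np.arange(m)] += h[idx]
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                warnings.warn("singular marginal covariance; ridge-stabilised")
                ridge = 1e-10 * np.maximum(
                    1.0, np.trace(C, axis1=1, axis2=2) / m
                )
                C[:, np.arange(m), np.arange(m)] += ridge[:, None]
                L = np.linalg.cholesky(C)
            x = np.linalg.solve(L, r[:, :, None])[:, :, 0]
            vals = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1) + np.sum(
                x * x, axis=1
            )
            terms[subs] = vals
            for i, s in enumerate(subs):
                C_out[s] = C[i]
                r_out[s] = r[i]
        return terms, C_out, r_out

    def focei_ofv_from_modes(self, etas, f, J) -> float:
        terms, _, _ = self.focei_subject_terms(etas, f, J)
        return float(terms.sum())

    def ofv(self, eta0: np.ndarray | None = None, warm: bool = True) -> float:
        start = self._eta_warm if (warm and eta0 is None) else eta0
        etas, _, f, J, _ = self.eta_modes(eta0=start)
        if warm:
            self._eta_warm = etas.copy()
        return self.focei_ofv_from_modes(etas, f, J)

    def ofv_blocks(self, warm: bool = True) -> np.ndarray:
        """OFV per design block (one per parameter configuration)."""
        start = self._eta_warm if warm else None
        etas, _, f, J, _ = self.eta_modes(eta0=start, fast=self.options.fast_inner)
        if warm:
            self._eta_warm = etas.copy()
        terms, _, _ = self.focei_subject_terms(etas, f, J)
        b = getattr(self.design, "n_blocks", 1)
        return terms.reshape(b, -1).sum(axis=1)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def eta_mode(dataset: Dataset, subject_id: int, model: ModelSpec):
    """Empirical-Bayes eta mode for one subject.

    Returns ``(eta, inner objective)`` or ``None`` when the subject has no
    informative observations (e.g. everything excluded as BLQ).
    """
    sub_df = dataset.df[dataset.df["ID"] == subject_id]
    if sub_df.empty:
        raise ValidationError(f"subject {subject_id} not in dataset")
    design = Design.from_dataset(Dataset(sub_df, dataset.rules))
    if design.n_subjects == 0:
        return None
    ev = FoceiEvaluator(design, model)
    etas, obj, _, _, _ = ev.eta_modes()
    if ev.n_eta:
        # polish to a tight gradient norm with a generic quasi-Newton pass
        def scalar_obj(e):
            val, _ = ev.subject_objectives(e[None, :])
            return float(val[0])

        res = scipy.optimize.minimize(
            scalar_obj, etas[0], method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
        )
        if res.fun <= obj[0]:
            etas = res.x[None, :]
            obj = np.array([res.fun])
    return etas[0], float(obj[0])


def focei_objective(dataset: Dataset, model: ModelSpec) -> float:
    """Deterministic FOCEI OFV at the model's current parameter values.

    Eta modes are searched from a cold start, so the value depends only on
    the data and the parameters (subject order is immaterial up to float
    summation noise).
    """
    design = Design.from_dataset(dataset)
    ev = FoceiEvaluator(design, model)
    return ev.ofv(eta0=np.zeros((design.n_subjects, ev.n_eta)), warm=False)


# -- parameter packing -------------------------------------------------------


class _Packer:
    """Bijective map between a ModelSpec and the transformed outer vector."""

    def __init__(self, model: ModelSpec):
        self.model = model
        self.names: list[str] = []
        for name in _STRUCT_NAMES:
            if name not in model.fixed:
                self.names.append(f"theta:{name}")
        for eff in model.covariate_effects:
            self.names.append(f"beta:{eff.parameter}:{eff.covariate}")
        self.omega_idx = [
            i for i, w in enumerate(model.random_effects.omega2) if w > 0.0
        ]
        for i in self.omega_idx:
            self.names.append(f"omega2:{model.random_effects.iiv_params[i]}")
        self.names.append("sigma2:VEN")
        self.names.append("sigma2:ODV")

    def pack(self, model: ModelSpec) -> np.ndarray:
        x: list[float] = []
        for name in _STRUCT_NAMES:
            if name in model.fixed:
                continue
            v = getattr(model.params, name)
            x.append(np.log(v / (1.0 - v)) if name == "fp" else np.log(v))
        for eff in model.covariate_effects:
            x.append(np.log1p(eff.theta) if eff.form == "linear" else eff.theta)
        w = model.random_effects.omega2
        x.extend(np.log(w[i]) for i in self.omega_idx)
        x.append(np.log(model.residual.sigma2_ven))
        x.append(np.log(model.residual.sigma2_odv))
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> ModelSpec:
        m = self.model
        # wild optimizer excursions must still map to finite parameters
        x = np.clip(np.asarray(x, dtype=float), -50.0, 50.0)
        i = 0
        changes: dict[str, float] = {}
        for name in _STRUCT_NAMES:
            if name in m.fixed:
                continue
            changes[name] = (
                1.0 / (1.0 + np.exp(-x[i])) if name == "fp" else float(np.exp(x[i]))
            )
            i += 1
        params = m.params.replace(**changes) if changes else m.params
        effects = []
        for eff in m.covariate_effects:
            if eff.form == "linear":
                # keep 1 + theta strictly positive even when expm1 underflows
                theta = max(float(np.expm1(x[i])), -1.0 + 1e-12)
            else:
                theta = float(x[i])
            effects.append(eff.with_theta(theta))
            i += 1
        omega2 = list(m.random_effects.omega2)
        for j in self.omega_idx:
            omega2[j] = float(np.exp(x[i]))
            i += 1
        residual = replace(
            m.residual,
            sigma2_ven=float(np.exp(x[i])),
            sigma2_odv=float(np.exp(x[i + 1])),
        )
        return replace(
            m,
            params=params,
            covariate_effects=tuple(effects),
            random_effects=replace(m.random_effects, omega2=tuple(omega2)),
            residual=residual,
        )

    def raw_values(self, model: ModelSpec) -> np.ndarray:
        """Natural-scale values in packing order (for RSE reporting)."""
        vals: list[float] = []
        for name in _STRUCT_NAMES:
            if name not in model.fixed:
                vals.append(getattr(model.params, name))
        vals.extend(e.theta for e in model.covariate_effects)
        vals.extend(model.random_effects.omega2[i] for i in self.omega_idx)
        vals.append(model.residual.sigma2_ven)
        vals.append(model.residual.sigma2_odv)
        return np.array(vals, dtype=float)

    def raw_jacobian(self, model: ModelSpec) -> np.ndarray:
        """d(raw)/d(transformed), elementwise (the transforms are scalar)."""
        d: list[float] = []
        for name in _STRUCT_NAMES:
            if name in model.fixed:
                continue
            v = getattr(model.params, name)
            d.append(v * (1.0 - v) if name == "fp" else v)
        d.extend(1.0 + e.theta for e in model.covariate_effects)
        d.extend(model.random_effects.omega2[i] for i in self.omega_idx)
        d.append(model.residual.sigma2_ven)
        d.append(model.residual.sigma2_odv)
        return np.array(d, dtype=float)


def _estimate_dict(model: ModelSpec) -> dict[str, float]:
    out = {name: float(getattr(model.params, name)) for name in _STRUCT_NAMES}
    for eff in model.covariate_effects:
        out[f"beta:{eff.parameter}:{eff.covariate}"] = float(eff.theta)
    for p, w in zip(model.random_effects.iiv_params, model.random_effects.omega2):
        out[f"omega2:{p}"] = float(w)
    out["sigma2:VEN"] = float(model.residual.sigma2_ven)
    out["sigma2:ODV"] = float(model.residual.sigma2_odv)
    return out


def fit(
    dataset: Dataset,
    model: ModelSpec,
    options: FitOptions | None = None,
    design: Design | None = None,
) -> FitResult:
    """Maximum-likelihood (FOCEI) fit of the model to the dataset.

    The outer search runs on transformed parameters with L-BFGS-B and
    finite-difference gradients; eta modes are warm-started between
    objective evaluations.  On non-convergence the best iterate found is
    returned with ``converged=False``.
    """
    options = options or FitOptions()
    if design is None:
        design = Design.from_dataset(dataset)
    if design.n_subjects < 2:
        raise ValidationError("need at least 2 subjects with observations")
    packer = _Packer(model)
    x0 = packer.pack(model)
    p = len(x0)
    # the objective and its whole forward-difference gradient are computed
    # in one vectorised pass over a (p+1)-fold tiled design
    bev = FoceiEvaluator(design.tile(p + 1), model, options)

    n_evals = 0
    trace: list[tuple[int, float]] = []
    best: dict = {"ofv": np.inf, "x": x0}
    h = options.outer_eps

    def _config(x: np.ndarray):
        m = packer.unpack(x)
        return (m.params, m.covariate_effects,
                np.asarray(m.random_effects.omega2), m.residual)

    def fun_and_grad(x: np.ndarray):
        nonlocal n_evals
        n_evals += 1
        xs = [x] + [np.concatenate([x[:i], [x[i] + h], x[i + 1:]]) for i in range(p)]
        try:
            bev.set_params_multi([_config(xi) for xi in xs])
            vals = bev.ofv_blocks(warm=True)
        except (VenpkError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12, np.zeros(p)
        if not np.all(np.isfinite(vals)):
            return 1e12, np.zeros(p)
        if vals[0] < best["ofv"]:
            best.update(ofv=float(vals[0]), x=x.copy())
        trace.append((n_evals, float(vals[0])))
        return float(vals[0]), (vals[1:] - vals[0]) / h

    res = scipy.optimize.minimize(
        fun_and_grad,
        x0,
        method="L-BFGS-B",
        jac=True,
        options={
            "maxiter": options.maxiter,
            "ftol": options.outer_ftol,
            "maxcor": 20,
        },
    )
    x_best = best["x"] if best["ofv"] < res.fun else res.x
    final_model = packer.unpack(x_best)
    ev = FoceiEvaluator(design, final_model, options)

    # final deterministic evaluation (cold start) + EBEs
    ev.set_params(final_model.params, final_model.covariate_effects,
                  np.asarray(final_model.random_effects.omega2), final_model.residual)
    etas, _, f, J, inner_ok = ev.eta_modes(eta0=np.zeros((design.n_subjects, ev.n_eta)))
    ofv = ev.focei_ofv_from_modes(etas, f, J)
    eta_df = pd.DataFrame(
        etas, index=design.subject_ids,
        columns=[f"eta:{p}" for p in ev.eta_params],
    )
    converged = bool(res.success) and bool(inner_ok.all())
    return FitResult(
        model=final_model,
        estimates=_estimate_dict(final_model),
        ofv=float(ofv),
        etas=eta_df,
        converged=converged,
        message=str(res.message),
        n_obj_evals=n_evals,
        n_obs=design.n_obs,
        n_subjects=design.n_subjects,
        n_dropped_structural_zero=design.n_dropped_structural_zero,
        skipped_subjects=design.skipped_subjects,
        iterations=trace,
    )


def _ofv_at_points(
    design: Design,
    model: ModelSpec,
    options: FitOptions,
    packer: "_Packer",
    points: np.ndarray,
    chunk: int = 24,
) -> np.ndarray:
    """OFV at many transformed parameter vectors, evaluated in vectorised
    chunks over a tiled design."""
    points = np.asarray(points)
    out = np.empty(len(points))
    bev = FoceiEvaluator(design.tile(chunk), model, options)

    def _config(x):
        m = packer.unpack(x)
        return (m.params, m.covariate_effects,
                np.asarray(m.random_effects.omega2), m.residual)

    for start in range(0, len(points), chunk):
        block = points[start : start + chunk]
        pad = chunk - len(block)
        xs = list(block) + [block[-1]] * pad
        bev.set_params_multi([_config(x) for x in xs])
        vals = bev.ofv_blocks(warm=True)
        out[start : start + len(block)] = vals[: len(block)]
    return out


def rse(
    fit_result: FitResult,
    dataset: Dataset,
    options: FitOptions | None = None,
    method: str = "auto",
    n_bootstrap: int = 50,
    bootstrap_seed: int = 0,
    design: Design | None = None,
) -> tuple[dict[str, float], str]:
    """Relative standard errors (100 * SE / |estimate|) per estimated
    parameter.

    SEs come from the inverse of half the central-difference OFV Hessian,
    computed in transformed coordinates and mapped back by the delta method.
    If that Hessian is not positive definite the function falls back to a
    case-resampling bootstrap over subjects (flagged in the returned method
    string).  Fixed parameters are reported as NaN.
    """
    options = options or FitOptions()
    model = fit_result.model
    if design is None:
        design = Design.from_dataset(dataset)
    packer = _Packer(model)
    x = packer.pack(model)
    p = len(x)
    if method in ("auto", "hessian"):
        # ~2% steps on the transformed (log/logit) scale: large enough that
        # the curvature dominates the objective's numerical noise floor
        h = np.full(p, 0.02)
        points = [x]
        for i in range(p):
            e = np.zeros(p); e[i] = h[i]
            points += [x + e, x - e]
        pair_index: dict[tuple[int, int], int] = {}
        for i in range(p):
            for j in range(i + 1, p):
                ei = np.zeros(p); ei[i] = h[i]
                ej = np.zeros(p); ej[j] = h[j]
                pair_index[(i, j)] = len(points)
                points += [x + ei + ej, x - ei - ej]
        vals = _ofv_at_points(design, model, options, packer, np.array(points))
        f0 = vals[0]
        f_plus = vals[1 : 2 * p + 1 : 2]
        f_minus = vals[2 : 2 * p + 1 : 2]
        H = np.zeros((p, p))
        for i in range(p):
            H[i, i] = (f_plus[i] - 2.0 * f0 + f_minus[i]) / h[i] ** 2
        for (i, j), k0 in pair_index.items():
            fpp, fmm = vals[k0], vals[k0 + 1]
            H[i, j] = H[j, i] = (
                fpp - f_plus[i] - f_plus[j] + 2.0 * f0 - f_minus[i] - f_minus[j] + fmm
            ) / (2.0 * h[i] * h[j])
        half = H / 2.0
        try:
            np.linalg.cholesky(half)
            used = "hessian"
        except np.linalg.LinAlgError:
            # a marginally indefinite Hessian (flat ridge, finite-difference
            # noise) is repaired by eigenvalue clipping; a substantially
            # indefinite one falls through to the bootstrap
            eigval, eigvec = np.linalg.eigh(half)
            if eigval.min() > -1e-3 * eigval.max():
                floor = 1e-6 * eigval.max()
                half = (eigvec * np.maximum(eigval, floor)) @ eigvec.T
                used = "hessian-clipped"
                warnings.warn("OFV Hessian marginally indefinite; clipped")
            elif method == "hessian":
                raise
            else:
                used = "bootstrap"
        if used != "bootstrap":
            cov_t = np.linalg.inv(half)
            se_t = np.sqrt(np.diag(cov_t))
            deriv = packer.raw_jacobian(model)
            se_raw = np.abs(deriv) * se_t
    else:
        used = "bootstrap"

    if used == "bootstrap":
        warnings.warn("OFV Hessian not positive definite; bootstrap SEs")
        rng = np.random.default_rng(bootstrap_seed)
        ids = dataset.subject_ids
        reps = []
        boot_opts = replace(options, maxiter=max(20, options.maxiter // 4))
        for _ in range(n_bootstrap):
            chosen = rng.choice(ids, size=len(ids), replace=True)
            frames = []
            for new_id, sid in enumerate(chosen, start=1):
                block = dataset.df[dataset.df["ID"] == sid].copy()
                block["ID"] = new_id
                frames.append(block)
            boot = Dataset(pd.concat(frames, ignore_index=True), dataset.rules)
            try:
                fb = fit(boot, model, boot_opts)
            except Exception:
                continue
            reps.append(packer.raw_values(fb.model))
        if len(reps) < 3:
            raise ConfigurationError("bootstrap produced too few successful fits")
        se_raw = np.std(np.array(reps), axis=0, ddof=1)

    raw = packer.raw_values(model)
    out: dict[str, float] = {}
    for name, est, se in zip(packer.names, raw, se_raw):
        out[name] = float(100.0 * se / abs(est)) if est != 0 else float("inf")
    for name in model.fixed:
        out[f"theta:{name}"] = float("nan")
    return out, used
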