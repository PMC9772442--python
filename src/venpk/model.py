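"""Joint one-compartment parent-metabolite structural model with pre-systemic
conversion.

The model describes an orally dosed parent drug (venlafaxine, VEN) and its
major active metabolite (O-desmethylvenlafaxine, ODV).  Drug in a depot
compartment is absorbed at a first-order rate ``ka``.  A fraction ``fp`` of
the absorbed dose is converted to metabolite pre-systemically (gut/liver
first pass) and enters the metabolite compartment directly; the remainder
enters the parent compartment.  Parent drug leaves its compartment by
first-order conversion to metabolite at rate ``kp = cl_f / v_f`` and the
metabolite is eliminated at rate ``km = clm_f / vm_f``:

    dA0/dt = -ka * A0
    dA1/dt = (1 - fp) * ka * A0 - kp * A1
    dA2/dt =      fp  * ka * A0 + kp * A1 - km * A2

All systemic parent elimination is treated as conversion to metabolite, the
standard identifiability constraint for metabolite data after oral dosing;
the metabolite clearance and volume are apparent quantities that absorb the
unknown formed fraction and the parent/metabolite molar-mass ratio.

Units: amounts in mg of the labelled (hydrochloride) dose, volumes in L,
times in h, concentrations in ng/ml (hence the factor 1000 = mg/L -> ng/ml).
Everything is linear, so doses superpose and steady state under repeated
dosing has the usual geometric accumulation ``1 / (1 - exp(-lambda * tau))``
per exponential term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, NumericalError, ValidationError

VEN = "VEN"
ODV = "ODV"

#: Minimum admissible lambda*tau product before steady-state accumulation
#: factors are considered numerically meaningless.
_MIN_LAMBDA_TAU = 1e-12


@dataclass(frozen=True)
class StructuralParams:
    """Apparent structural parameters of the joint model.

    Parameters
    ----------
    cl_f, v_f:
        Apparent clearance (L/h) and volume (L) of the parent drug.
    clm_f, vm_f:
        Apparent clearance (L/h) and volume (L) of the metabolite.
    ka:
        First-order absorption rate constant (1/h).
    fp:
        Fraction of the absorbed dose converted pre-systemically (0-1).

    The rate constants ``kp`` and ``km`` are always derived from the
    clearances and volumes; they are never stored independently.
    """

    cl_f: float
    v_f: float
    clm_f: float
    vm_f: float
    ka: float = 0.63
    fp: float = 0.048

    def __post_init__(self) -> None:
        for name in ("cl_f", "v_f", "clm_f", "vm_f", "ka"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0.0):
                raise InvalidParameterError(
                    f"{name} must be finite and strictly positive, got {value!r}"
                )
        if not (np.isfinite(self.fp) and 0.0 <= self.fp <= 1.0):
            raise InvalidParameterError(f"fp must lie in [0, 1], got {self.fp!r}")

    @property
    def kp(self) -> float:
        """Parent elimination/conversion rate constant (1/h)."""
        return self.cl_f / self.v_f

    @property
    def km(self) -> float:
        """Metabolite elimination rate constant (1/h)."""
        return self.clm_f / self.vm_f

    def replace(self, **changes: float) -> "StructuralParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class DoseEvent:
    """One oral dosing event.

    ``steady_state`` marks a regimen that has been running every
    ``interdose_interval`` hours long enough to be at steady state by
    ``time``; ``n_additional_doses`` encodes a finite train of repeats.
    """

    time: float
    amount: float
    interdose_interval: float = 0.0
    n_additional_doses: int = 0
    steady_state: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amount) and self.amount > 0.0):
            raise ValidationError(f"dose amount must be > 0, got {self.amount!r}")
        if self.time < 0.0 or not np.isfinite(self.time):
            raise ValidationError(f"dose time must be finite and >= 0, got {self.time!r}")
        if (self.n_additional_doses > 0 or self.steady_state) and not (
            self.interdose_interval > 0.0
        ):
            raise ValidationError(
                "interdose_interval must be > 0 for repeated or steady-state dosing"
            )
        if self.n_additional_doses < 0:
            raise ValidationError("n_additional_doses must be >= 0")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of dose events for one subject."""

    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [d.time for d in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("dose times must be non-decreasing")

    @classmethod
    def single(cls, amount: float, time: float = 0.0) -> "Regimen":
        return cls((DoseEvent(time=time, amount=amount),))

    @classmethod
    def from_events(cls, events: Iterable[DoseEvent]) -> "Regimen":
        return cls(tuple(events))

    @property
    def first_dose_time(self) -> float:
        if not self.doses:
            raise ValidationError("regimen has no doses")
        return self.doses[0].time


# ---------------------------------------------------------------------------
# Low-level vectorised kernels.  These operate on flat arrays of
# (dose, time-since-dose, interval) triples and broadcast against per-pair
# parameter arrays, so the same code serves the scalar API, the population
# prediction engine and replicate-simulation for NPDE.
# ---------------------------------------------------------------------------


def _phi(x: np.ndarray) -> np.ndarray:
    """expm1(x)/x, continuous at 0 (equals 1).  Stable for all x."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0.0
    out = np.where(nz, np.divide(np.expm1(x), np.where(nz, x, 1.0)), 1.0)
    return out


def _acc(lam: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Steady-state accumulation factor 1/(1 - exp(-lam*tau)).

    ``tau = inf`` (single dose) gives exactly 1.  Raises
    :class:`NumericalError` when ``lam*tau`` underflows to a meaningless
    magnitude for a finite interval.
    """
    lam_tau = lam * tau
    finite = np.isfinite(tau)
    if np.any(finite & (lam_tau < _MIN_LAMBDA_TAU)):
        raise NumericalError(
            "lambda*tau underflow in steady-state accumulation "
            "(rate constant or interval too small)"
        )
    return -1.0 / np.expm1(-lam_tau)


def _separate(b: np.ndarray, a: np.ndarray, rel: float = 1e-8) -> np.ndarray:
    """Nudge rate ``b`` away from ``a`` when the two nearly coincide.

    Partial-fraction coefficients carry 1/(a-b) factors; exact coincidence is
    a measure-zero configuration, and a relative nudge of ``rel`` keeps the
    evaluation finite with an error of the same order.
    """
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    tol = rel * np.maximum(np.abs(a), np.abs(b))
    d = b - a
    need = np.abs(d) < tol
    if not np.any(need):
        return b
    return np.where(need, a + np.where(d >= 0.0, tol, -tol), b)


def parent_conc_pairs(dose, dt, tau, ka, kp, fp, v):
    """Parent concentration (ng/ml) contributed by one dose per pair.

    ``dt`` is time since that dose (entries < 0 contribute 0); ``tau`` is the
    interdose interval for steady-state doses and ``inf`` otherwise.  The
    absorption/elimination rate degeneracy ``ka == kp`` is handled exactly
    through the expm1 limit form (which reduces to ``t * ka * exp(-ka t)``)
    for single doses, and by a relative rate nudge for steady-state doses.
    """
    dose, dt, tau, ka, kp, fp, v = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (dose, dt, tau, ka, kp, fp, v))
    )
    live = dt >= 0.0
    dtp = np.where(live, dt, 0.0)
    ss = np.isfinite(tau)
    x = (ka - kp) * dtp
    near = ~ss & (np.abs(x) < 1e-2)  # cancellation regime of the plain form
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # near ka == kp: (e^-kp t - e^-ka t)/(ka-kp) = e^-ka t * t * phi(x),
        # which tends to the L'Hopital limit t * e^-ka t
        stable = np.exp(-ka * dtp) * dtp * _phi(np.clip(x, -1.0, 1.0))
        kps = _separate(kp, ka)
        plain = (
            np.exp(-kps * dtp) * _acc(kps, tau) - np.exp(-ka * dtp) * _acc(ka, tau)
        ) / (ka - kps)
    diff = np.where(near, stable, plain)
    conc = 1000.0 * (1.0 - fp) * dose * ka / v * diff
    return np.where(live, conc, 0.0)


def metabolite_conc_pairs(dose, dt, tau, ka, kp, km, fp, vm):
    """Metabolite concentration (ng/ml) contributed by one dose per pair.

    Tri-exponential closed form: the metabolite amount is

        A2 = D*ka*[ fp*D(ka,km) + (1-fp)*kp/(ka-kp)*(D(kp,km) - D(ka,km)) ]

    with D(a,b) = (e^-at - e^-bt)/(b-a), each exponential accumulating
    independently at steady state.  The three rates are nudged apart by a
    relative 1e-8 when they (nearly) coincide; away from that measure-zero
    configuration the divided differences are evaluated in their stable
    expm1 forms where cancellation could occur.
    """
    dose, dt, tau, ka, kp, km, fp, vm = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (dose, dt, tau, ka, kp, km, fp, vm))
    )
    live = dt >= 0.0
    dtp = np.where(live, dt, 0.0)
    ss = np.isfinite(tau)
    kps = _separate(kp, ka)
    kms = _separate(_separate(km, ka), kps)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        e_a = np.exp(-ka * dtp) * _acc(ka, tau)
        e_p = np.exp(-kps * dtp) * _acc(kps, tau)
        e_m = np.exp(-kms * dtp) * _acc(kms, tau)

        def delta(e_1, e_2, a, b):
            x = (b - a) * dtp
            near = ~ss & (np.abs(x) < 1e-2)
            plain = (e_1 - e_2) / (b - a)
            if not near.any():
                return plain
            stab = e_2 * dtp * _phi(np.clip(x, -1.0, 1.0))
            return np.where(near, stab, plain)

        d_am = delta(e_a, e_m, ka, kms)
        d_pm = delta(e_p, e_m, kps, kms)
    amount = dose * ka * (fp * d_am + (1.0 - fp) * kps * (d_pm - d_am) / (ka - kps))
    return np.where(live, 1000.0 * amount / vm, 0.0)


def dose_pairs(regimen: Regimen, times: np.ndarray):
    """Expand a regimen against observation times into (obs, dose) pairs.

    Returns ``(obs_idx, dose, dt, tau, event_idx)`` flat arrays.
    Finite-repeat doses (``n_additional_doses``) are expanded explicitly;
    steady-state events map each later observation onto its position within
    the dosing interval.  ``event_idx`` tracks which :class:`DoseEvent` a
    pair originates from (an additional-dose train is one event), so callers
    can treat dose events as independent occasions when appropriate.
    """
    times = np.asarray(times, dtype=float)
    obs_idx_parts: list[np.ndarray] = []
    dose_parts: list[np.ndarray] = []
    dt_parts: list[np.ndarray] = []
    tau_parts: list[np.ndarray] = []
    ev_parts: list[np.ndarray] = []
    all_idx = np.arange(times.size)
    for ev_i, ev in enumerate(regimen.doses):
        if ev.steady_state:
            rel = times - ev.time
            mask = rel >= 0.0
            obs_idx_parts.append(all_idx[mask])
            dose_parts.append(np.full(mask.sum(), ev.amount))
            dt_parts.append(np.mod(rel[mask], ev.interdose_interval))
            tau_parts.append(np.full(mask.sum(), ev.interdose_interval))
            ev_parts.append(np.full(mask.sum(), ev_i, dtype=int))
        else:
            for j in range(ev.n_additional_doses + 1):
                t_dose = ev.time + j * ev.interdose_interval
                rel = times - t_dose
                mask = rel >= 0.0
                if not np.any(mask):
                    continue
                obs_idx_parts.append(all_idx[mask])
                dose_parts.append(np.full(mask.sum(), ev.amount))
                dt_parts.append(rel[mask])
                tau_parts.append(np.full(mask.sum(), np.inf))
                ev_parts.append(np.full(mask.sum(), ev_i, dtype=int))
    if not obs_idx_parts:
        empty = np.empty(0)
        return np.empty(0, dtype=int), empty, empty, empty, np.empty(0, dtype=int)
    return (
        np.concatenate(obs_idx_parts),
        np.concatenate(dose_parts),
        np.concatenate(dt_parts),
        np.concatenate(tau_parts),
        np.concatenate(ev_parts),
    )


def _conc(params: StructuralParams, regimen: Regimen, times, analyte: str):
    t = np.asarray(times, dtype=float)
    scalar = t.ndim == 0
    flat = np.atleast_1d(t).ravel()
    obs_idx, dose, dt, tau, _ = dose_pairs(regimen, flat)
    if analyte == VEN:
        c = parent_conc_pairs(dose, dt, tau, params.ka, params.kp, params.fp, params.v_f)
    elif analyte == ODV:
        c = metabolite_conc_pairs(
            dose, dt, tau, params.ka, params.kp, params.km, params.fp, params.vm_f
        )
    else:
        raise ValidationError(f"unknown analyte {analyte!r}")
    out = np.bincount(obs_idx, weights=c, minlength=flat.size)
    out = out.reshape(np.atleast_1d(t).shape)
    return float(out[0]) if scalar else out


def conc_parent(params: StructuralParams, regimen: Regimen, times):
    """Parent (VEN) plasma concentration in ng/ml.

    Times before the first dose return 0 by convention.
    """
    return _conc(params, regimen, times, VEN)


def conc_metabolite(params: StructuralParams, regimen: Regimen, times):
    """Metabolite (ODV) plasma concentration in ng/ml."""
    return _conc(params, regimen, times, ODV)


def conc(params: StructuralParams, regimen: Regimen, times, analyte: str):
    """Concentration of either analyte (``"VEN"`` or ``"ODV"``)."""
    return _conc(params, regimen, times, analyte)


def steady_state_conc(
    params: StructuralParams,
    dose: float,
    tau: float,
    t_after_dose,
    analyte: str,
):
    """Concentration at steady state under repeated dosing every ``tau`` h.

    ``t_after_dose`` is folded into the dosing interval, so the trough at
    ``t_after_dose == tau`` equals the value immediately before the next
    dose.
    """
    if not (tau > 0.0 and np.isfinite(tau)):
        raise ValidationError(f"tau must be finite and > 0, got {tau!r}")
    regimen = Regimen(
        (DoseEvent(time=0.0, amount=dose, interdose_interval=tau, steady_state=True),)
    )
    return _conc(params, regimen, t_after_dose, analyte)


def elimination_half_life(params: StructuralParams, analyte: str) -> float:
    """Terminal elimination half-life ln(2) * V / CL for the analyte, in h."""
    if analyte == VEN:
        return math.log(2.0) * params.v_f / params.cl_f
    if analyte == ODV:
        return math.log(2.0) * params.vm_f / params.clm_f
    raise ValidationError(f"unknown analyte {analyte!r}")


def mean_absorption_time(params: StructuralParams) -> float:
    """Mean absorption time 1/ka, in h."""
    return 1.0 / params.ka


# ---------------------------------------------------------------------------
# ODE evaluation.  Serves as the in-package oracle for the closed form and as
# the reference for mass-balance checks; an adaptive integrator with tight
# tolerances integrates the three amounts plus the cumulative metabolite
# elimination between dose times.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmountTrajectories:
    """Amount (mg) trajectories of depot, parent, metabolite compartments.

    ``eliminated`` is the cumulative metabolite amount eliminated, so that
    ``depot + parent + metabolite + eliminated`` equals the total dose
    administered up to each time.
    """

    times: np.ndarray
    depot: np.ndarray
    parent: np.ndarray
    metabolite: np.ndarray
    eliminated: np.ndarray


def _expand_dose_times(params: StructuralParams, regimen: Regimen, t_max: float):
    """Explicit (time, amount) pairs; steady-state events are expanded to a
    pre-dose train long enough (>= 25 terminal half-lives) to be at steady
    state, which may start at negative times."""
    events: list[tuple[float, float]] = []
    t_half = math.log(2.0) / min(params.ka, params.kp, params.km)
    for ev in regimen.doses:
        if ev.steady_state:
            n_pre = int(math.ceil(25.0 * t_half / ev.interdose_interval)) + 1
            n_post = int(math.ceil(max(0.0, t_max - ev.time) / ev.interdose_interval)) + 1
            for j in range(-n_pre, n_post + 1):
                t = ev.time + j * ev.interdose_interval
                if t <= t_max:
                    events.append((t, ev.amount))
        else:
            for j in range(ev.n_additional_doses + 1):
                t = ev.time + j * ev.interdose_interval
                if t <= t_max:
                    events.append((t, ev.amount))
    events.sort(key=lambda e: e[0])
    return events


def amounts_ode(
    params: StructuralParams,
    regimen: Regimen,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> AmountTrajectories:
    """Integrate the three-compartment amount system numerically.

    Times before the first dose return zero amounts.  Dose amounts are added
    to the depot at their event times; a requested time coinciding with a
    dose time reports the post-dose state (so at t=0 with a dose at 0 the
    depot holds the full dose).
    """
    t_req = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t_req < 0.0):
        raise ValidationError("requested times must be >= 0")
    order = np.argsort(t_req, kind="stable")
    t_sorted = t_req[order]
    t_max = float(t_sorted[-1]) if t_sorted.size else 0.0
    events = _expand_dose_times(params, regimen, t_max)
    if not events:
        raise ValidationError("regimen has no doses at or before the requested times")

    ka, kp, km, fp = params.ka, params.kp, params.km, params.fp

    def rhs(_t, y):
        a0, a1, a2, _ = y
        return [
            -ka * a0,
            (1.0 - fp) * ka * a0 - kp * a1,
            fp * ka * a0 + kp * a1 - km * a2,
            km * a2,
        ]

    out = np.zeros((4, t_sorted.size))
    state = np.zeros(4)
    for i, (t_ev, amount) in enumerate(events):
        state[0] += amount
        last = i + 1 == len(events)
        seg_end = max(t_max, t_ev) if last else events[i + 1][0]
        if last:
            sel = (t_sorted >= t_ev) & (t_sorted <= seg_end)
        else:
            sel = (t_sorted >= t_ev) & (t_sorted < seg_end)
        if seg_end <= t_ev:
            out[:, sel] = state[:, None]
            continue
        uniq = np.unique(t_sorted[sel])
        t_eval = np.unique(np.concatenate([uniq, [seg_end]]))
        # solve_ivp requires t_eval within the span, starting at or after t_ev
        sol = solve_ivp(
            rhs,
            (t_ev, seg_end),
            state,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        if not sol.success:
            raise NumericalError(f"ODE integration failed: {sol.message}")
        if uniq.size:
            col = np.searchsorted(sol.t, t_sorted[sel])
            out[:, sel] = sol.y[:, col]
        state = sol.y[:, -1].copy()

    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    out = out[:, inv]
    return AmountTrajectories(
        times=t_req,
        depot=out[0],
        parent=out[1],
        metabolite=out[2],
        eliminated=out[3],
    )
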