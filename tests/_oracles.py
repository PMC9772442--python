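"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's computational paths: a fixed-step
RK4 integrator with Richardson extrapolation for the amount system, an
adaptive Gauss-Hermite quadrature of the exact marginal likelihood for
one-random-effect subjects, and a brute-force grid search for eta modes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import logsumexp


def rk4_amounts(params, dose: float, t_end: float, n_steps: int) -> np.ndarray:
    """Classic fixed-step RK4 for (depot, parent, metabolite) amounts after
    a single oral dose at t=0."""
    ka, kp, km, fp = params.ka, params.kp, params.km, params.fp

    def rhs(y):
        a0, a1, a2 = y
        return np.array([
            -ka * a0,
            (1.0 - fp) * ka * a0 - kp * a1,
            fp * ka * a0 + kp * a1 - km * a2,
        ])

    y = np.array([dose, 0.0, 0.0])
    h = t_end / n_steps
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return y


def richardson_rk4_amounts(params, dose: float, t_end: float, n_steps: int = 512) -> np.ndarray:
    """Richardson-extrapolated RK4 (orders combine to O(h^5))."""
    y1 = rk4_amounts(params, dose, t_end, n_steps)
    y2 = rk4_amounts(params, dose, t_end, 2 * n_steps)
    return (16.0 * y2 - y1) / 15.0


def parent_conc_reference(params, dose, times):
    """Textbook one-compartment first-order-absorption profile (ng/ml),
    written independently of the package kernels."""
    times = np.asarray(times, dtype=float)
    ka, kp = params.ka, params.kp
    c = (
        1000.0 * (1.0 - params.fp) * dose * ka
        / (params.v_f * (ka - kp))
        * (np.exp(-kp * times) - np.exp(-ka * times))
    )
    return np.where(times >= 0.0, c, 0.0)


def grid_eta_mode(times, y, dose, params, omega2, sigma2, lo=-2.0, hi=2.0, step=1e-4):
    """Brute-force eta mode for one subject with a single eta on parent
    clearance, minimising the conditional FOCEI objective on a grid."""
    etas = np.arange(lo, hi + step / 2.0, step)
    best_obj = np.inf
    best_eta = 0.0
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    for eta in etas:
        p = params.replace(cl_f=params.cl_f * math.exp(eta))
        f = parent_conc_reference(p, dose, times)
        h = sigma2 * f * f
        obj = np.sum((y - f) ** 2 / h + np.log(h)) + eta * eta / omega2
        if obj < best_obj:
            best_obj, best_eta = obj, eta
    return best_eta, best_obj


def aghq_ofv_one_eta(times, y, dose, params, omega2, sigma2, n_nodes=64):
    """-2 log marginal likelihood (minus the n*ln(2 pi) constant) for one
    subject with a single log-normal eta on parent clearance, by adaptive
    Gauss-Hermite quadrature."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)

    def loglik(eta):
        p = params.replace(cl_f=params.cl_f * math.exp(eta))
        f = parent_conc_reference(p, dose, times)
        h = sigma2 * f * f
        return (
            -0.5 * np.sum((y - f) ** 2 / h + np.log(2.0 * np.pi * h))
            - 0.5 * eta * eta / omega2
            - 0.5 * math.log(2.0 * math.pi * omega2)
        )

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(lambda e: -loglik(e), bounds=(-8.0, 8.0),
                          method="bounded", options={"xatol": 1e-12})
    mode = res.x
    d = 1e-4
    curv = -(loglik(mode + d) - 2.0 * loglik(mode) + loglik(mode - d)) / d**2
    sd = 1.0 / math.sqrt(curv)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    eta_q = mode + math.sqrt(2.0) * sd * nodes
    logs = (
        np.array([loglik(e) for e in eta_q])
        + nodes**2
        + np.log(weights)
        + math.log(math.sqrt(2.0) * sd)
    )
    log_marginal = logsumexp(logs)
    return -2.0 * log_marginal - len(y) * math.log(2.0 * math.pi)
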