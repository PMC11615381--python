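"""Shared optimization utilities for the FIML fits."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


class EstimationError(RuntimeError):
    """Raised when a correlation or quad model cannot be estimated."""


def minimize_nll(nll, x0, maxiter: int = 1000):
    """Quasi-Newton minimization of a negative log-likelihood.

    L-BFGS-B on the unbounded parameterization (correlations enter on the
    atanh scale), with an objective tolerance of 1e-8 relative (ftol) as the
    convergence criterion.
    """
    res = minimize(
        nll,
        np.asarray(x0, float),
        method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": maxiter, "maxfun": 20000},
    )
    return res


def numeric_hessian(f, x, step: float = 1e-4):
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, float)
    n = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                e = np.zeros(n)
                e[i] = h[i]
                H[i, i] = (f(x + e) - 2.0 * f0 + f(x - e)) / h[i] ** 2
            else:
                ei = np.zeros(n)
                ej = np.zeros(n)
                ei[i] = h[i]
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def se_from_hessian(nll, x_opt):
    """Standard errors from the observed information (numerical Hessian).

    Returns (se_vector, ok_flag); a non-invertible or non-PD Hessian yields
    NaN standard errors and ``ok=False`` rather than an exception.
    """
    H = numeric_hessian(nll, x_opt)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            return np.full(x_opt.size, np.nan), False
        return np.sqrt(d), True
    except np.linalg.LinAlgError:
        return np.full(len(np.atleast_1d(x_opt)), np.nan), False
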