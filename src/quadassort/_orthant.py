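"""Multivariate-normal orthant probabilities.

The liability-threshold likelihoods in this package reduce to rectangle
probabilities of standard (multivariate) normal vectors.  Dimensions one and
two are computed exactly (``ndtr`` and an Owen's-T expression of the bivariate
CDF); dimensions three and four use deterministic sequential conditioning:
Gauss-Legendre quadrature over the leading coordinate(s) with the exact
bivariate CDF for the conditional remainder.  Everything here is vectorized
and fully reproducible (no randomized integration).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr, ndtri, owens_t

__all__ = ["bvn_upper", "bvn_cdf", "mvn_upper_orthant"]

_EPS0 = 1e-13  # nudge for exact-zero thresholds in the Owen's-T formula
_RHO_LIM = 1.0 - 1e-12


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Vectorized over broadcastable ``h``, ``k``, ``rho``.  Uses the classical
    Owen's-T decomposition, which is exact up to the accuracy of
    :func:`scipy.special.owens_t`.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    h = h.copy()
    k = k.copy()
    out = np.empty(h.shape, float)

    # degenerate correlation
    hi = np.minimum(h, k)
    pos = rho >= _RHO_LIM
    neg = rho <= -_RHO_LIM
    out[pos] = ndtr(hi[pos])
    out[neg] = np.maximum(0.0, ndtr(h[neg]) + ndtr(k[neg]) - 1.0)

    gen = ~(pos | neg)
    if np.any(gen):
        hh = h[gen]
        kk = k[gen]
        rr = rho[gen]
        # exact closed form when both thresholds sit at zero
        both0 = (hh == 0.0) & (kk == 0.0)
        # nudge remaining zeros off the axis (continuity bounds the error by
        # phi(0) * _EPS0, far below the owens_t accuracy)
        hh = np.where(np.abs(hh) < _EPS0, _EPS0, hh)
        kk = np.where(np.abs(kk) < _EPS0, _EPS0, kk)
        sq = np.sqrt(1.0 - rr * rr)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ah = (kk - rr * hh) / (hh * sq)
            ak = (hh - rr * kk) / (kk * sq)
        beta = np.where(hh * kk > 0, 0.0, 0.5)
        val = 0.5 * (ndtr(hh) + ndtr(kk)) - owens_t(hh, ah) - owens_t(kk, ak) - beta
        val = np.where(both0, 0.25 + np.arcsin(rr) / (2.0 * np.pi), val)
        # infinite limits
        val = np.where(np.isneginf(hh) | np.isneginf(kk), 0.0, val)
        val = np.where(np.isposinf(hh), ndtr(kk), val)
        val = np.where(np.isposinf(kk), np.where(np.isposinf(hh), 1.0, ndtr(hh)), val)
        out[gen] = val
    return np.clip(out, 0.0, 1.0)


def bvn_upper(t1, t2, rho):
    """P(Z1 > t1, Z2 > t2) for a standard bivariate normal, vectorized."""
    return bvn_cdf(np.negative(t1), np.negative(t2), rho)


def _tail_nodes(p_lower, u):
    """Map Gauss-Legendre nodes u in (0,1) into the upper tail above quantile.

    Given P(Z <= a) = ``p_lower``, returns z(u) with Phi(z) = p_lower +
    u*(1-p_lower), computed through the upper tail for accuracy.
    """
    q = (1.0 - p_lower) * (1.0 - u)
    return -ndtri(np.clip(q, 1e-300, 1.0))


def _gl01(n):
    x, w = leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def mvn_upper_orthant(lower, corr, nodes: int = 32) -> float:
    """P(Z_j > lower_j for all j) for a standard MVN with correlation ``corr``.

    Supports dimensions 1-4.  Coordinates with ``lower = -inf`` are
    marginalized out; any ``+inf`` gives probability zero.  Deterministic.
    """
    lower = np.asarray(lower, float)
    corr = np.asarray(corr, float)
    if np.any(np.isposinf(lower)):
        return 0.0
    keep = ~np.isneginf(lower)
    lower = lower[keep]
    corr = corr[np.ix_(keep, keep)]
    d = lower.size
    if d == 0:
        return 1.0
    if d == 1:
        return float(ndtr(-lower[0]))
    if d == 2:
        return float(bvn_upper(lower[0], lower[1], corr[0, 1]))
    if d == 3:
        return _orthant3(lower, corr, nodes)
    if d == 4:
        return _orthant4(lower, corr, nodes)
    raise ValueError("orthant probabilities implemented for dimension <= 4")


def _orthant3(lower, corr, nodes):
    u, w = _gl01(nodes)
    p0 = ndtr(lower[0])
    z1 = _tail_nodes(p0, u)                       # (n,)
    s = np.sqrt(1.0 - corr[0, 1:] ** 2)           # conditional sds of Z2, Z3
    t2 = (lower[1] - corr[0, 1] * z1) / s[0]
    t3 = (lower[2] - corr[0, 2] * z1) / s[1]
    c23 = (corr[1, 2] - corr[0, 1] * corr[0, 2]) / (s[0] * s[1])
    c23 = np.clip(c23, -_RHO_LIM, _RHO_LIM)
    f = bvn_upper(t2, t3, c23)
    return float((1.0 - p0) * np.dot(w, f))


def _orthant4(lower, corr, nodes):
    u, w = _gl01(nodes)
    # innovations: Z1 = e1, Z2 = r12*e1 + s12*e2
    r12 = corr[0, 1]
    s12 = np.sqrt(max(1.0 - r12 * r12, 1e-12))
    p0 = ndtr(lower[0])
    z1 = _tail_nodes(p0, u)                       # (n,)
    c_e2 = (lower[1] - r12 * z1) / s12            # e2 lower limit, depends on z1
    p2 = ndtr(c_e2)                               # (n,)
    e2 = _tail_nodes(p2[:, None], u[None, :])     # (n, n)
    z2 = r12 * z1[:, None] + s12 * e2             # (n, n)

    S11 = corr[:2, :2]
    S21 = corr[2:, :2]
    B = S21 @ np.linalg.inv(S11)                  # (2, 2)
    C = corr[2:, 2:] - B @ S21.T
    sd = np.sqrt(np.maximum(np.diag(C), 1e-12))
    rho = np.clip(C[0, 1] / (sd[0] * sd[1]), -_RHO_LIM, _RHO_LIM)

    m3 = B[0, 0] * z1[:, None] + B[0, 1] * z2
    m4 = B[1, 0] * z1[:, None] + B[1, 1] * z2
    t3 = (lower[2] - m3) / sd[0]
    t4 = (lower[3] - m4) / sd[1]
    f = bvn_upper(t3, t4, rho)                    # (n, n)
    inner = (1.0 - p2) * (f @ w)                  # (n,)
    return float((1.0 - p0) * np.dot(w, inner))
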