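"""Four-person correlation structure, the in-law inflation factor, and tests.

A family quad consists of an index person, their partner, one full sibling of
each.  Under direct (phenotype-based) assortment the sibling-in-law
correlation is the product of the partner and sibling correlations, so the
in-law inflation factor

    IIF = r_inlaw / (r_sibling * r_partner)

equals 1; indirect assortment on a correlated latent trait or social
stratification push it above 1, while post-formation convergence pulls it
below.  The quad model fits the joint 4-variate liability by FIML (quads with
missing members contribute their marginal sub-model) either freely or with
the product constraint, and the two fits are compared by a 1-df likelihood
ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from ._fitting import EstimationError, minimize_nll, se_from_hessian
from ._orthant import mvn_upper_orthant
from .liability_correlation import CorrelationEstimate, TraitSpec

__all__ = [
    "ROLES",
    "QuadCorrelationStructure",
    "QuadModelFit",
    "DirectAssortmentTest",
    "ExpectedCorrelations",
    "iif",
    "bh_adjust",
    "fit_quad_model",
    "lrt_direct_assortment",
    "lrt_equal_correlations",
    "expected_relative_correlations",
]

ROLES = ("index", "partner", "sib_index", "sib_partner")


@dataclass
class QuadCorrelationStructure:
    """Relationship correlations of the quad.

    The two sibling pairs share ``r_sibling`` and the two in-law pairs share
    ``r_inlaw``; the co-sibling-in-law correlation is free.  When
    ``constrained`` is set, ``r_inlaw`` is the product r_partner * r_sibling
    by construction.
    """

    r_partner: float
    r_sibling: float
    r_inlaw: float
    r_cosib: float
    constrained: bool = False

    def to_matrix(self) -> np.ndarray:
        """Implied 4x4 correlation matrix in ROLES order."""
        rp, rs, ri, rc = self.r_partner, self.r_sibling, self.r_inlaw, self.r_cosib
        return np.array(
            [
                [1.0, rp, rs, ri],
                [rp, 1.0, ri, rs],
                [rs, ri, 1.0, rc],
                [ri, rs, rc, 1.0],
            ]
        )

    @property
    def iif(self) -> float:
        return iif(self.r_partner, self.r_sibling, self.r_inlaw)


@dataclass
class QuadModelFit:
    structure: QuadCorrelationStructure
    loglik: float
    n_quads: int
    converged: bool
    se: dict = field(default_factory=dict)


@dataclass
class DirectAssortmentTest:
    iif: float
    lrt_stat: float
    df: int
    p_raw: float
    p_bh: float = np.nan


def iif(r_partner: float, r_sibling: float, r_inlaw: float) -> float:
    """In-law inflation factor r_inlaw / (r_sibling * r_partner).

    Equals 1 under direct assortment; NaN when the denominator is zero.
    """
    denom = r_sibling * r_partner
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float(r_inlaw / denom)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone)."""
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ExpectedCorrelations:
    r_partner: float
    r_sibling: float
    r_inlaw: float
    iif: float


def expected_relative_correlations(params) -> ExpectedCorrelations:
    """Path-traced expected correlations and IIF for a mechanism.

    Direct assortment on the phenotype with copath m and sibling correlation
    r_s gives (m, r_s, m*r_s, 1).  Indirect assortment through a latent
    factor (loading a, copath mu, latent sibling correlation r_m, residual
    sibling correlation r_e with E = (1-a^2) r_e) gives (a^2 mu,
    a^2 r_m + E, a^2 mu r_m) and IIF = 1/(a^2 + E/r_m).  Social
    stratification with loading q gives q^2 everywhere and IIF = 1/q^2.
    A convergence overlay on a direct-assortment base adds a couple-shared
    environment (variance n2) and symmetric mutual influence (coefficient x)
    and deflates the IIF.
    """
    mech = params.mechanism
    if mech == "direct":
        m, rs = params.m, params.r_s
        _check_corr(m=m, r_s=rs)
        return ExpectedCorrelations(m, rs, m * rs, 1.0 if m * rs != 0 else float("nan"))
    if mech == "indirect":
        a2 = params.a**2
        _check_corr(a=params.a, mu=params.mu, r_m=params.r_m, r_e=params.r_e)
        E = (1.0 - a2) * params.r_e
        rp = a2 * params.mu
        rs = a2 * params.r_m + E
        ri = a2 * params.mu * params.r_m
        return ExpectedCorrelations(rp, rs, ri, iif(rp, rs, ri))
    if mech == "stratification":
        q = params.q
        _check_corr(q=q)
        q2 = q * q
        return ExpectedCorrelations(q2, q2, q2, 1.0 / q2 if q2 > 0 else float("nan"))
    if mech == "convergence_overlay":
        m, rs, n2, x = params.m, params.r_s, params.n2, params.x
        _check_corr(m=m, r_s=rs, x=x)
        if n2 < 0:
            raise ValueError("shared-environment variance n2 must be nonnegative")
        v = 1.0 + n2
        cp = m + n2
        # simultaneous mutual influence: A'' = (A + x * partner(A)) / (1 - x^2),
        # scale cancels in the correlations
        var_u = v * (1.0 + x * x) + 2.0 * x * cp
        cov_pp = cp * (1.0 + x * x) + 2.0 * x * v
        cov_sib = rs * (1.0 + x * m)
        cov_inlaw = rs * (m + x)
        rp = cov_pp / var_u
        rsb = cov_sib / np.sqrt(var_u)
        ri = cov_inlaw / np.sqrt(var_u)
        return ExpectedCorrelations(rp, rsb, ri, iif(rp, rsb, ri))
    raise ValueError(f"unknown mechanism {mech!r}")


def _check_corr(**kwargs):
    for name, v in kwargs.items():
        if v is None or not (-1.0 < v < 1.0):
            raise ValueError(f"parameter {name} must lie strictly inside (-1, 1)")


# ---------------------------------------------------------------------------
# quad model FIML


def _quad_data(quads: pd.DataFrame, trait: str, adjust):
    V = np.column_stack([quads[f"{trait}_{r}"].to_numpy(float) for r in ROLES])
    k = len(adjust)
    C = np.zeros((len(quads), 4, k))
    for ci, cov in enumerate(adjust):
        for ri, role in enumerate(ROLES):
            C[:, ri, ci] = quads[f"{cov}_{role}"].to_numpy(float)
    obs = np.isfinite(V)
    keep = obs.sum(axis=1) >= 1
    return V[keep], C[keep], obs[keep]


def _continuous_groups(V, C, obs):
    """Per-(missingness pattern x covariate pattern) sufficient statistics."""
    n, _, k = C.shape
    Cm = np.where(obs[:, :, None], np.nan_to_num(C), 0.0)
    key = np.column_stack([obs.astype(float), Cm.reshape(n, 4 * k)])
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    groups = []
    for g in range(len(uniq)):
        idx = np.nonzero(inv == g)[0]
        o = np.nonzero(uniq[g, :4] > 0)[0]
        sub = V[np.ix_(idx, o)]
        m = sub.mean(axis=0)
        d = sub - m
        S = d.T @ d
        covvals = uniq[g, 4:].reshape(4, k)[o]
        groups.append((o, float(len(idx)), m, S, covvals))
    return groups


def _structure_matrix(rp, rs, ri, rc):
    return np.array(
        [[1.0, rp, rs, ri], [rp, 1.0, ri, rs], [rs, ri, 1.0, rc], [ri, rs, rc, 1.0]]
    )


_LOG2PI = np.log(2.0 * np.pi)


def _make_continuous_nll(groups, k, constrained):
    nz = 3 if constrained else 4

    def unpack(p):
        mu = p[:4]
        slopes = p[4 : 4 + k]
        lsd = p[4 + k : 8 + k]
        zs = p[8 + k :]
        rp, rs = np.tanh(zs[0]), np.tanh(zs[1])
        rc = np.tanh(zs[-1])
        ri = rp * rs if constrained else np.tanh(zs[2])
        return mu, slopes, np.exp(lsd), (rp, rs, ri, rc)

    def nll(p):
        mu, slopes, sd, (rp, rs, ri, rc) = unpack(p)
        R = _structure_matrix(rp, rs, ri, rc)
        w = np.linalg.eigvalsh(R)[0]
        if w < 1e-8:
            return 1e8 * (1e-8 - w) + 1e6
        Sigma = R * np.outer(sd, sd)
        total = 0.0
        for o, n_g, m, S, covvals in groups:
            So = Sigma[np.ix_(o, o)]
            mu_o = mu[o] + covvals @ slopes
            try:
                L = np.linalg.cholesky(So)
            except np.linalg.LinAlgError:
                return 1e10
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            Sinv_S = np.linalg.solve(So, S)
            delta = m - mu_o
            quad = delta @ np.linalg.solve(So, delta)
            total += 0.5 * (n_g * (len(o) * _LOG2PI + logdet + quad) + np.trace(Sinv_S))
        return float(total)

    return nll, unpack, 8 + k + nz


def _binary_groups(V, C, obs):
    n, _, k = C.shape
    Vm = np.where(obs, np.nan_to_num(V), -1.0)
    Cm = np.where(obs[:, :, None], np.nan_to_num(C), 0.0)
    key = np.column_stack([obs.astype(float), Vm, Cm.reshape(n, 4 * k)])
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    groups = []
    for g in range(len(uniq)):
        o = np.nonzero(uniq[g, :4] > 0)[0]
        cells = uniq[g, 4:8][o]
        signs = np.where(cells == 1.0, 1.0, -1.0)
        covvals = uniq[g, 8:].reshape(4, k)[o]
        groups.append((o, signs, covvals, float(counts[g])))
    return groups


def _make_binary_nll(groups, k, constrained, nodes):
    nz = 3 if constrained else 4

    def unpack(p):
        tau = p[:4]
        slopes = p[4 : 4 + k]
        zs = p[4 + k :]
        rp, rs = np.tanh(zs[0]), np.tanh(zs[1])
        rc = np.tanh(zs[-1])
        ri = rp * rs if constrained else np.tanh(zs[2])
        return tau, slopes, (rp, rs, ri, rc)

    def nll(p):
        tau, slopes, (rp, rs, ri, rc) = unpack(p)
        R = _structure_matrix(rp, rs, ri, rc)
        w = np.linalg.eigvalsh(R)[0]
        if w < 1e-8:
            return 1e8 * (1e-8 - w) + 1e6
        total = 0.0
        for o, signs, covvals, cnt in groups:
            t = tau[o] + covvals @ slopes
            Ro = R[np.ix_(o, o)] * np.outer(signs, signs)
            pr = mvn_upper_orthant(signs * t, Ro, nodes=nodes)
            total -= cnt * np.log(max(pr, 1e-300))
        return float(total)

    return nll, unpack, 4 + k + nz


def fit_quad_model(
    quads: pd.DataFrame,
    trait: TraitSpec,
    constrained: bool = False,
    adjust: tuple = (),
    compute_se: bool = True,
    nodes: int = 20,
) -> QuadModelFit:
    """FIML fit of the 4-variate liability model for one trait.

    Continuous traits use multivariate-normal FIML on per-pattern sufficient
    statistics; binary traits use 4-dimensional orthant probabilities (exact
    bivariate CDFs combined with deterministic conditioning quadrature).
    Quads with missing members contribute their marginal sub-model.  With
    ``constrained`` the in-law correlation is reparameterized as the product
    r_partner * r_sibling (exact nesting).  Covariates (``adjust``, e.g.
    ``("sex",)``) enter means/thresholds with shared slopes; they should be
    categorical for the grouped likelihood to stay compact.
    """
    adjust = tuple(adjust)
    V, C, obs = _quad_data(quads, trait.name, adjust)
    if len(V) == 0:
        raise EstimationError("no quads with at least one observed member")
    k = len(adjust)
    if trait.kind == "continuous":
        sds = np.nanstd(V, axis=0)
        if np.any(sds == 0):
            raise EstimationError("degenerate data: a role has zero variance")
        groups = _continuous_groups(V, C, obs)
        nll, unpack, npar = _make_continuous_nll(groups, k, constrained)
        x0 = np.zeros(npar)
        x0[:4] = np.nanmean(V, axis=0)
        x0[4 + k : 8 + k] = np.log(sds)
        x0[8 + k :] = 0.05
    else:
        prev = np.nanmean(V, axis=0)
        if np.any((prev <= 0) | (prev >= 1)):
            raise EstimationError("degenerate data: a role is all-affected or all-unaffected")
        groups = _binary_groups(V, C, obs)
        nll, unpack, npar = _make_binary_nll(groups, k, constrained, nodes)
        x0 = np.zeros(npar)
        x0[:4] = -ndtri(np.clip(prev, 1e-4, 1 - 1e-4))
        x0[4 + k :] = 0.05
    res = minimize_nll(nll, x0)
    if trait.kind == "continuous":
        _, _, _, corrs = unpack(res.x)
    else:
        _, _, corrs = unpack(res.x)
    rp, rs, ri, rc = corrs
    boundary = any(abs(v) > 0.999 for v in (rp, rs, ri, rc))
    se = {}
    ok = True
    if compute_se:
        se_all, ok = se_from_hessian(nll, res.x)
        zs = se_all[-(3 if constrained else 4):]
        names = ["r_partner", "r_sibling", "r_cosib"] if constrained else [
            "r_partner", "r_sibling", "r_inlaw", "r_cosib"
        ]
        vals = [rp, rs, rc] if constrained else [rp, rs, ri, rc]
        se = {nm: float((1 - v**2) * s) for nm, v, s in zip(names, vals, zs)}
    structure = QuadCorrelationStructure(
        float(rp), float(rs), float(ri), float(rc), constrained=constrained
    )
    return QuadModelFit(
        structure=structure,
        loglik=float(-res.fun),
        n_quads=int(len(V)),
        converged=bool(res.success) and not boundary and ok,
        se=se,
    )


def lrt_direct_assortment(
    free: QuadModelFit, constrained: QuadModelFit, tol: float = 1e-4
) -> DirectAssortmentTest:
    """1-df likelihood-ratio test of the product constraint r_inlaw = rp*rs.

    A low p-value signals poor fit of direct assortment.  The IIF is computed
    from the free fit's correlations.
    """
    if constrained.loglik > free.loglik + tol:
        raise EstimationError(
            "constrained log-likelihood exceeds the free one; refit required"
        )
    stat = max(0.0, 2.0 * (free.loglik - constrained.loglik))
    p = float(chi2.sf(stat, df=1))
    return DirectAssortmentTest(iif=free.structure.iif, lrt_stat=stat, df=1, p_raw=p)


def lrt_equal_correlations(fits_a, fits_b):
    """Joint test that two sets of correlations are pairwise equal.

    The statistic is the sum over traits of the squared standardized
    difference on the atanh scale (asymptotically the same chi-square as the
    likelihood-ratio test of the equality constraints), with df equal to the
    number of constrained correlations.
    """
    fits_a = list(fits_a)
    fits_b = list(fits_b)
    if len(fits_a) != len(fits_b):
        raise ValueError("the two correlation sets must cover the same traits")
    stat = 0.0
    for ea, eb in zip(fits_a, fits_b):
        za, zb = np.arctanh(ea.r), np.arctanh(eb.r)
        va = (ea.se / (1 - ea.r**2)) ** 2
        vb = (eb.se / (1 - eb.r**2)) ** 2
        if va + vb <= 0 or not np.isfinite(va + vb):
            raise ValueError("correlation estimates need finite standard errors")
        stat += (za - zb) ** 2 / (va + vb)
    df = len(fits_a)
    return {"stat": float(stat), "df": df, "p": float(chi2.sf(stat, df))}
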