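"""Pairwise liability-threshold correlations via full-information ML.

Binary diagnoses are modelled as threshold exceedances of latent standard
normal liabilities.  Depending on the trait kinds, the latent correlation
between two family members is a tetrachoric (binary-binary), polyserial
(continuous-binary), or Pearson (continuous-continuous) correlation, each fit
by maximizing the full-information likelihood so that records with one
missing member still contribute their marginal likelihood.  Covariates
("definition variables", e.g. sex or birth year) enter the thresholds of
binary traits and the means of continuous traits with estimated slopes; the
correlation itself is covariate-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri
from scipy.stats import norm

from ._fitting import EstimationError, minimize_nll, numeric_hessian, se_from_hessian
from ._orthant import bvn_upper

__all__ = [
    "TraitSpec",
    "PairedObservations",
    "ThresholdModel",
    "CorrelationEstimate",
    "bivariate_upper_orthant",
    "estimate_tetrachoric",
    "estimate_polyserial",
    "estimate_pearson",
    "estimate_correlation",
    "correlation_matrix",
    "percent_reduction",
    "EstimationError",
]

_R_BOUNDARY = 0.999
_R_CLIP = 0.9999


@dataclass(frozen=True)
class TraitSpec:
    """A phenotype: a binary diagnosis with a prevalence, or a continuous score."""

    name: str
    kind: str = "binary"  # {"binary", "continuous"}
    prevalence: float | None = None
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError("binary trait needs prevalence strictly in (0, 1)")
        elif self.sd <= 0:
            raise ValueError("continuous trait needs sd > 0")

    @property
    def threshold(self) -> float:
        """Liability threshold tau with upper-tail mass equal to the prevalence."""
        if self.kind != "binary":
            raise ValueError("threshold defined only for binary traits")
        return float(norm.isf(self.prevalence))


@dataclass
class PairedObservations:
    """Phenotype pairs for one relationship, with optional per-member covariates.

    ``x`` and ``y`` are equal-length float vectors (binary coded 0/1); missing
    values are NaN.  Covariate matrices, when given, must have the same row
    count and enter the mean/threshold models of the corresponding member.
    """

    x: np.ndarray
    y: np.ndarray
    covariates_x: np.ndarray | None = None
    covariates_y: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, float).ravel()
        self.y = np.asarray(self.y, float).ravel()
        if self.x.size != self.y.size:
            raise ValueError("x and y must have the same length")
        for attr in ("covariates_x", "covariates_y"):
            c = getattr(self, attr)
            if c is not None:
                c = np.atleast_2d(np.asarray(c, float))
                if c.shape[0] != self.x.size:
                    c = c.T
                if c.shape[0] != self.x.size:
                    raise ValueError(f"{attr} row count does not match x/y")
                setattr(self, attr, c)
        for v, name in ((self.x, "x"), (self.y, "y")):
            vals = v[np.isfinite(v)]
            if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
                # only enforced later for binary estimators; no-op here
                pass

    def swapped(self) -> "PairedObservations":
        return PairedObservations(self.y, self.x, self.covariates_y, self.covariates_x)

    @property
    def n_pairs(self) -> int:
        return int(np.sum(np.isfinite(self.x) & np.isfinite(self.y)))


@dataclass
class ThresholdModel:
    """Threshold (binary) or mean (continuous) model with covariate slopes."""

    tau0: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mu0: float = 0.0
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class CorrelationEstimate:
    r: float
    se: float
    ci95: tuple[float, float]
    method: str
    n_pairs: int
    loglik: float
    converged: bool
    p: float = np.nan
    boundary: bool = False

    def __post_init__(self):
        if not -1.0 < self.r < 1.0:
            raise ValueError("correlation must lie strictly inside (-1, 1)")


def bivariate_upper_orthant(tau1: float, tau2: float, r: float) -> float:
    """P(Z1 > tau1, Z2 > tau2) for standard bivariate normal liabilities."""
    if not -1.0 < r < 1.0:
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    return float(bvn_upper(tau1, tau2, r))


def _covs(pairs: PairedObservations, adjust):
    """Resolve the covariate matrices according to the adjust selection."""
    if adjust is None or adjust is False:
        n = pairs.x.size
        return np.zeros((n, 0)), np.zeros((n, 0))
    cx = pairs.covariates_x
    cy = pairs.covariates_y
    n = pairs.x.size
    cx = np.zeros((n, 0)) if cx is None else cx
    cy = np.zeros((n, 0)) if cy is None else cy
    if adjust != "all":
        idx = list(adjust)
        cx = cx[:, idx] if cx.shape[1] else cx
        cy = cy[:, idx] if cy.shape[1] else cy
    return cx, cy


def _check_binary(v, name):
    vals = v[np.isfinite(v)]
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(f"{name} must be coded 0/1 (1 = affected) or NaN")


def _group(rows):
    """Unique rows with counts (rows: 2-D float array)."""
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def _wrap_estimate(res, nll, idx_z, method, n_pairs, n_free, compute_se=True):
    """Build a CorrelationEstimate from an optimizer result."""
    z_hat = res.x[idx_z]
    r = float(np.tanh(z_hat))
    boundary = abs(r) > _R_BOUNDARY
    se_z = np.nan
    ok = False
    if compute_se:
        se_all, ok = se_from_hessian(nll, res.x)
        se_z = se_all[idx_z]
    se_r = float((1.0 - r**2) * se_z) if np.isfinite(se_z) else np.nan
    lo, hi = np.tanh(z_hat - 1.96 * se_z), np.tanh(z_hat + 1.96 * se_z)
    p = float(2.0 * ndtr(-abs(z_hat) / se_z)) if (np.isfinite(se_z) and se_z > 0) else np.nan
    converged = bool(res.success) and not boundary and (ok or not compute_se)
    return CorrelationEstimate(
        r=float(np.clip(r, -_R_CLIP, _R_CLIP)),
        se=se_r,
        ci95=(float(lo), float(hi)),
        method=method,
        n_pairs=n_pairs,
        loglik=float(-res.fun),
        converged=converged,
        p=p,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# tetrachoric


def _tetra_nll_factory(pairs, cx, cy):
    x, y = pairs.x, pairs.y
    px, py = cx.shape[1], cy.shape[1]
    mb = np.isfinite(x) & np.isfinite(y)
    mx = np.isfinite(x) & ~np.isfinite(y)
    my = ~np.isfinite(x) & np.isfinite(y)

    gb, cb = _group(np.column_stack([cx[mb], cy[mb], x[mb], y[mb]])) if mb.any() else (np.zeros((0, px + py + 2)), np.zeros(0))
    gx, cxn = _group(np.column_stack([cx[mx], x[mx]])) if mx.any() else (np.zeros((0, px + 1)), np.zeros(0))
    gy, cyn = _group(np.column_stack([cy[my], y[my]])) if my.any() else (np.zeros((0, py + 1)), np.zeros(0))

    Gb_cx, Gb_cy = gb[:, :px], gb[:, px : px + py]
    sb_x = np.where(gb[:, -2] == 1.0, 1.0, -1.0)
    sb_y = np.where(gb[:, -1] == 1.0, 1.0, -1.0)
    Gx_c, sx = gx[:, :px], np.where(gx[:, -1] == 1.0, 1.0, -1.0)
    Gy_c, sy = gy[:, :py], np.where(gy[:, -1] == 1.0, 1.0, -1.0)

    def unpack(p):
        t0x = p[0]
        bx = p[1 : 1 + px]
        t0y = p[1 + px]
        by = p[2 + px : 2 + px + py]
        z = p[-1]
        return t0x, bx, t0y, by, z

    def nll(p):
        t0x, bx, t0y, by, z = unpack(p)
        r = np.tanh(z)
        total = 0.0
        if cb.size:
            taux = t0x + Gb_cx @ bx
            tauy = t0y + Gb_cy @ by
            # sign flips turn every cell into an upper-orthant probability
            pr = bvn_upper(sb_x * taux, sb_y * tauy, sb_x * sb_y * r)
            total -= np.dot(cb, np.log(np.clip(pr, 1e-300, 1.0)))
        if cxn.size:
            taux = t0x + Gx_c @ bx
            total -= np.dot(cxn, log_ndtr(-sx * taux))
        if cyn.size:
            tauy = t0y + Gy_c @ by
            total -= np.dot(cyn, log_ndtr(-sy * tauy))
        return float(total)

    n_params = 3 + px + py
    return nll, unpack, n_params


def _tetra_init(pairs, cx, cy, n_params):
    x, y = pairs.x, pairs.y
    p1 = np.nanmean(np.where(np.isfinite(x), x, np.nan))
    p2 = np.nanmean(np.where(np.isfinite(y), y, np.nan))
    p1 = min(max(p1, 1e-4), 1 - 1e-4)
    p2 = min(max(p2, 1e-4), 1 - 1e-4)
    x0 = np.zeros(n_params)
    x0[0] = -ndtri(p1)
    x0[cx.shape[1] + 1] = -ndtri(p2)
    mb = np.isfinite(x) & np.isfinite(y)
    a = np.sum((x[mb] == 1) & (y[mb] == 1)) + 0.5
    b = np.sum((x[mb] == 1) & (y[mb] == 0)) + 0.5
    c = np.sum((x[mb] == 0) & (y[mb] == 1)) + 0.5
    d = np.sum((x[mb] == 0) & (y[mb] == 0)) + 0.5
    r0 = np.sin(np.pi / 2 * (a * d - b * c) / (a * d + b * c))  # Yule init
    x0[-1] = np.arctanh(np.clip(r0, -0.9, 0.9))
    return x0


def estimate_tetrachoric(
    pairs: PairedObservations, adjust="all", mode: str = "joint", compute_se: bool = True
) -> CorrelationEstimate:
    """Tetrachoric correlation between two dichotomized liabilities (FIML).

    ``mode="joint"`` (default) maximizes the joint likelihood over both
    threshold models and atanh(r); ``mode="two_stage"`` fixes thresholds from
    the probit-inverted margins and profiles r in one dimension (faster, valid
    without covariates).
    """
    _check_binary(pairs.x, "x")
    _check_binary(pairs.y, "y")
    cx, cy = _covs(pairs, adjust)
    mb = np.isfinite(pairs.x) & np.isfinite(pairs.y)
    if not mb.any():
        raise EstimationError("degenerate table: no complete pairs")
    cells = {(int(a), int(b)) for a, b in zip(pairs.x[mb], pairs.y[mb])}
    if len(cells) < 2:
        raise EstimationError("degenerate table: all pairs in a single cell")

    nll, unpack, n_params = _tetra_nll_factory(pairs, cx, cy)
    x0 = _tetra_init(pairs, cx, cy, n_params)
    if mode == "two_stage":
        fixed = x0.copy()

        def nll1(zarr):
            p = fixed.copy()
            p[-1] = zarr[0]
            return nll(p)

        res = minimize_nll(nll1, [x0[-1]])
        res.x = np.concatenate([fixed[:-1], res.x])
        full_nll = nll
        est = _wrap_estimate(res, full_nll, -1, "tetrachoric", pairs.n_pairs, 1, compute_se)
        return est
    res = minimize_nll(nll, x0)
    return _wrap_estimate(res, nll, -1, "tetrachoric", pairs.n_pairs, n_params, compute_se)


# ---------------------------------------------------------------------------
# polyserial


def estimate_polyserial(
    pairs: PairedObservations, adjust="all", compute_se: bool = True
) -> CorrelationEstimate:
    """Polyserial correlation: continuous x, dichotomized-liability y (FIML)."""
    _check_binary(pairs.y, "y")
    cx, cy = _covs(pairs, adjust)
    x, y = pairs.x, pairs.y
    mb = np.isfinite(x) & np.isfinite(y)
    mx = np.isfinite(x) & ~np.isfinite(y)
    my = ~np.isfinite(x) & np.isfinite(y)
    if pairs.n_pairs < 3:
        raise EstimationError("fewer than 3 complete pairs")
    xs = x[np.isfinite(x)]
    if np.std(xs) == 0:
        raise EstimationError("continuous trait has zero variance")
    px, py = cx.shape[1], cy.shape[1]

    xb, cxb, cyb, yb = x[mb], cx[mb], cy[mb], y[mb]
    sb = np.where(yb == 1.0, 1.0, -1.0)
    xm, cxm = x[mx], cx[mx]
    ym, cym = y[my], cy[my]
    sm = np.where(ym == 1.0, 1.0, -1.0)

    def nll(p):
        mu0 = p[0]
        gx = p[1 : 1 + px]
        lsd = p[1 + px]
        t0 = p[2 + px]
        by = p[3 + px : 3 + px + py]
        z = p[-1]
        r = np.tanh(z)
        sd = np.exp(np.clip(lsd, -300, 300))
        s1 = np.sqrt(max(1.0 - r * r, 1e-12))
        total = 0.0
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            if xb.size:
                zx = (xb - mu0 - cxb @ gx) / sd
                tau = t0 + cyb @ by
                cond = (r * zx - tau) / s1
                total -= np.sum(norm.logpdf(zx) - lsd + log_ndtr(sb * cond))
            if xm.size:
                zx = (xm - mu0 - cxm @ gx) / sd
                total -= np.sum(norm.logpdf(zx) - lsd)
            if ym.size:
                tau = t0 + cym @ by
                total -= np.sum(log_ndtr(-sm * tau))
        if not np.isfinite(total):
            return 1e12
        return float(total)

    p1 = np.nanmean(np.where(np.isfinite(y), y, np.nan))
    p1 = min(max(p1, 1e-4), 1 - 1e-4)
    x0 = np.zeros(4 + px + py)
    x0[0] = np.mean(xs)
    x0[1 + px] = np.log(np.std(xs))
    x0[2 + px] = -ndtri(p1)
    if mb.any():
        pb = norm.pdf(-ndtri(p1))
        r0 = np.corrcoef(xb, yb)[0, 1] * np.sqrt(p1 * (1 - p1)) / pb if xb.size > 2 else 0.0
        x0[-1] = np.arctanh(np.clip(r0, -0.9, 0.9))
    res = minimize_nll(nll, x0)
    return _wrap_estimate(res, nll, -1, "polyserial", pairs.n_pairs, len(x0), compute_se)


# ---------------------------------------------------------------------------
# pearson


def _bvn_logpdf(zx, zy, r):
    q = (zx * zx - 2.0 * r * zx * zy + zy * zy) / (1.0 - r * r)
    return -np.log(2.0 * np.pi) - 0.5 * np.log(1.0 - r * r) - 0.5 * q


def estimate_pearson(
    pairs: PairedObservations, adjust="all", compute_se: bool = True
) -> CorrelationEstimate:
    """Pearson correlation of two continuous traits under a bivariate-normal FIML.

    With complete data the maximum-likelihood solution is available in closed
    form (per-variable least-squares residualization followed by the sample
    correlation of residuals) and is used directly; with missing members the
    likelihood is maximized numerically so that singletons contribute their
    marginal normal density.
    """
    cx, cy = _covs(pairs, adjust)
    x, y = pairs.x, pairs.y
    if pairs.n_pairs < 3:
        raise EstimationError("fewer than 3 complete pairs")
    complete = bool(np.all(np.isfinite(x) & np.isfinite(y)))
    px, py = cx.shape[1], cy.shape[1]

    if complete:
        rx = _ols_residuals(x, cx)
        ry = _ols_residuals(y, cy)
        sx, sy = rx.std(), ry.std()
        if sx == 0 or sy == 0:
            raise EstimationError("zero variance in a continuous trait")
        r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
        n = x.size
        boundary = abs(r) > _R_BOUNDARY
        if boundary:
            warnings.warn("correlation at the +/-1 boundary; estimate clipped")
        rr = float(np.clip(r, -_R_CLIP, _R_CLIP))
        zx, zy = rx / sx, ry / sy
        ll = float(np.sum(_bvn_logpdf(zx, zy, rr)) - n * (np.log(sx) + np.log(sy)))
        dof = max(n - 3 - px - py, 1)
        se_z = 1.0 / np.sqrt(dof)
        z = np.arctanh(rr)
        return CorrelationEstimate(
            r=rr,
            se=float((1 - rr**2) * se_z),
            ci95=(float(np.tanh(z - 1.96 * se_z)), float(np.tanh(z + 1.96 * se_z))),
            method="pearson",
            n_pairs=n,
            loglik=ll,
            converged=not boundary,
            p=float(2.0 * ndtr(-abs(z) / se_z)),
            boundary=boundary,
        )

    mb = np.isfinite(x) & np.isfinite(y)
    mx = np.isfinite(x) & ~np.isfinite(y)
    my = ~np.isfinite(x) & np.isfinite(y)
    xb, yb, cxb, cyb = x[mb], y[mb], cx[mb], cy[mb]
    xm, cxm = x[mx], cx[mx]
    ym, cym = y[my], cy[my]

    def nll(p):
        mux = p[0]
        gx = p[1 : 1 + px]
        lsx = p[1 + px]
        muy = p[2 + px]
        gy = p[3 + px : 3 + px + py]
        lsy = p[3 + px + py]
        z = p[-1]
        r = np.tanh(z)
        sdx, sdy = np.exp(lsx), np.exp(lsy)
        total = 0.0
        if xb.size:
            zx = (xb - mux - cxb @ gx) / sdx
            zy = (yb - muy - cyb @ gy) / sdy
            total -= np.sum(_bvn_logpdf(zx, zy, r) - lsx - lsy)
        if xm.size:
            total -= np.sum(norm.logpdf((xm - mux - cxm @ gx) / sdx) - lsx)
        if ym.size:
            total -= np.sum(norm.logpdf((ym - muy - cym @ gy) / sdy) - lsy)
        return float(total)

    xs, ys = x[np.isfinite(x)], y[np.isfinite(y)]
    if xs.std() == 0 or ys.std() == 0:
        raise EstimationError("zero variance in a continuous trait")
    x0 = np.zeros(5 + px + py)
    x0[0] = xs.mean()
    x0[1 + px] = np.log(xs.std())
    x0[2 + px] = ys.mean()
    x0[3 + px + py] = np.log(ys.std())
    r0 = np.corrcoef(x[mb], y[mb])[0, 1]
    x0[-1] = np.arctanh(np.clip(r0, -0.9, 0.9))
    res = minimize_nll(nll, x0)
    return _wrap_estimate(res, nll, -1, "pearson", pairs.n_pairs, len(x0), compute_se)


def _ols_residuals(v, covs):
    X = np.column_stack([np.ones(v.size), covs])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


# ---------------------------------------------------------------------------
# dispatch, matrices, summaries

_ROLE_PAIRS = {
    "partner": [("index", "partner")],
    "sibling": [("index", "sib_index"), ("partner", "sib_partner")],
    "inlaw": [("index", "sib_partner"), ("partner", "sib_index")],
    "within_person": [("index", "index"), ("partner", "partner")],
}


def estimate_correlation(
    pairs: PairedObservations, kind_x: str, kind_y: str, adjust="all", compute_se=True
) -> CorrelationEstimate:
    """Dispatch to the estimator matching the two trait kinds."""
    if kind_x == "binary" and kind_y == "binary":
        return estimate_tetrachoric(pairs, adjust, compute_se=compute_se)
    if kind_x == "continuous" and kind_y == "continuous":
        return estimate_pearson(pairs, adjust, compute_se=compute_se)
    if kind_x == "continuous":
        return estimate_polyserial(pairs, adjust, compute_se=compute_se)
    return estimate_polyserial(pairs.swapped(), adjust, compute_se=compute_se)


def _stack_pairs(pop: pd.DataFrame, trait_a, trait_b, role_pairs, adjust_cols, adjust_both=()):
    xs, ys, cxs, cys = [], [], [], []
    for ra, rb in role_pairs:
        xs.append(pop[f"{trait_a}_{ra}"].to_numpy(float))
        ys.append(pop[f"{trait_b}_{rb}"].to_numpy(float))
        if adjust_cols or adjust_both:
            own_x = [pop[f"{c}_{ra}"].to_numpy(float) for c in adjust_cols]
            own_y = [pop[f"{c}_{rb}"].to_numpy(float) for c in adjust_cols]
            # adjust_both covariates (e.g. both partners' education) enter the
            # mean/threshold model of each member of the pair
            shared = [pop[f"{c}_{r}"].to_numpy(float) for c in adjust_both for r in (ra, rb)]
            cxs.append(np.column_stack(own_x + shared))
            cys.append(np.column_stack(own_y + shared))
    cx = np.vstack(cxs) if cxs else None
    cy = np.vstack(cys) if cys else None
    return PairedObservations(np.concatenate(xs), np.concatenate(ys), cx, cy)


def _cross_partner_pairs(pop: pd.DataFrame, trait_a, trait_b, adjust_cols, adjust_both=()):
    """Trait A in the female partner against trait B in the male partner."""
    sex_i = pop["sex_index"].to_numpy(float)
    a_i = pop[f"{trait_a}_index"].to_numpy(float)
    a_p = pop[f"{trait_a}_partner"].to_numpy(float)
    b_i = pop[f"{trait_b}_index"].to_numpy(float)
    b_p = pop[f"{trait_b}_partner"].to_numpy(float)
    female_is_index = sex_i == 1.0
    x = np.where(female_is_index, a_i, a_p)
    y = np.where(female_is_index, b_p, b_i)
    cx = cy = None
    if adjust_cols or adjust_both:
        def stack(cols):
            return np.column_stack([pop[f"{c}_index"].to_numpy(float) for c in cols]), \
                np.column_stack([pop[f"{c}_partner"].to_numpy(float) for c in cols])
        parts_x, parts_y = [], []
        if adjust_cols:
            cols_i, cols_p = stack(adjust_cols)
            sel = female_is_index[:, None]
            parts_x.append(np.where(sel, cols_i, cols_p))
            parts_y.append(np.where(sel, cols_p, cols_i))
        if adjust_both:
            cols_i, cols_p = stack(adjust_both)
            shared = np.column_stack([cols_i, cols_p])
            parts_x.append(shared)
            parts_y.append(shared)
        cx = np.column_stack(parts_x)
        cy = np.column_stack(parts_y)
    return PairedObservations(x, y, cx, cy)


def correlation_matrix(
    pop: pd.DataFrame,
    traits: list[TraitSpec],
    relationship: str,
    adjust: list[str] | None = None,
    adjust_both: list[str] | None = None,
) -> pd.DataFrame:
    """Estimate the full trait-by-trait correlation matrix for a relationship.

    ``adjust`` covariates enter each member's own threshold/mean model;
    ``adjust_both`` covariates (e.g. an education trait) enter with the
    values of *both* members of the pair, which is how residual partner
    correlations after education adjustment are obtained.  Returns a tidy
    frame with columns trait_a, trait_b, relationship, r, se, ci_low,
    ci_high, p, p_bh, n_pairs, method, converged.  BH adjustment is applied
    across the whole matrix (self-correlations excluded).
    """
    from .family_quad_model import bh_adjust

    if relationship not in _ROLE_PAIRS and relationship != "cross_trait_partner":
        raise ValueError(f"unknown relationship {relationship!r}")
    by_name = {t.name: t for t in traits}
    for t in traits:
        if f"{t.name}_index" not in pop.columns:
            raise ValueError(f"trait {t.name!r} not present in the quad table")
    adjust_cols = list(adjust) if adjust else []
    both_cols = list(adjust_both) if adjust_both else []
    rows = []
    symmetric = relationship != "cross_trait_partner"
    names = [t.name for t in traits]
    for i, ta in enumerate(names):
        for j, tb in enumerate(names):
            if symmetric and j < i:
                continue
            if relationship == "cross_trait_partner":
                pairs = _cross_partner_pairs(pop, ta, tb, adjust_cols, both_cols)
            else:
                pairs = _stack_pairs(pop, ta, tb, _ROLE_PAIRS[relationship], adjust_cols, both_cols)
            if relationship == "within_person" and ta == tb:
                rows.append(
                    dict(trait_a=ta, trait_b=tb, relationship=relationship, r=1.0,
                         se=0.0, ci_low=1.0, ci_high=1.0, p=np.nan, n_pairs=pairs.n_pairs,
                         method="identity", converged=True)
                )
                continue
            try:
                est = estimate_correlation(
                    pairs,
                    by_name[ta].kind,
                    by_name[tb].kind,
                    adjust="all" if (adjust_cols or both_cols) else None,
                )
                rows.append(
                    dict(trait_a=ta, trait_b=tb, relationship=relationship, r=est.r,
                         se=est.se, ci_low=est.ci95[0], ci_high=est.ci95[1], p=est.p,
                         n_pairs=est.n_pairs, method=est.method, converged=est.converged)
                )
            except EstimationError as exc:
                rows.append(
                    dict(trait_a=ta, trait_b=tb, relationship=relationship, r=np.nan,
                         se=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                         n_pairs=pairs.n_pairs, method="error", converged=False)
                )
                warnings.warn(f"{ta} x {tb} ({relationship}): {exc}")
    out = pd.DataFrame(rows)
    mask = np.isfinite(out["p"].to_numpy(float))
    p_bh = np.full(len(out), np.nan)
    if mask.any():
        p_bh[mask] = bh_adjust(out.loc[mask, "p"].to_numpy(float))
    out["p_bh"] = p_bh
    return out


def percent_reduction(r_unadjusted: float, r_adjusted: float) -> float:
    """Percent attenuation of a correlation after covariate adjustment.

    100 * (1 - r_adjusted / r_unadjusted); NaN when the unadjusted
    correlation is zero.
    """
    if r_unadjusted == 0:
        return float("nan")
    return 100.0 * (1.0 - r_adjusted / r_unadjusted)
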