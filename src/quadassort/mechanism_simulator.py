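"""Synthetic family-quad populations under assortative-mating mechanisms.

Stands in for protected registry data.  Each quad (index person, partner, one
sibling per side) carries Gaussian liabilities drawn from the correlation
structure a mechanism implies:

* direct assortment — a copath ``m`` on the phenotype itself, sibling
  correlation ``r_s``;
* indirect assortment — the phenotype loads (``a``) on a latent mating factor
  M with copath ``mu`` between partners' factors, sibling correlation ``r_m``
  in M and residual sibling correlation ``r_e``;
* social stratification — all four members load ``q`` on a shared stratum;
* convergence — a post-formation overlay adding a couple-shared environment
  (variance ``n2``) and symmetric mutual influence (``x``).

All mechanisms are realized as a single joint multivariate-normal draw from
the path-implied correlation matrix (sequential conditional sampling and a
joint Cholesky draw are the same distribution), so the path-traced expected
correlations hold exactly in expectation.  Binary diagnoses are obtained by
dichotomizing liabilities at the upper-tail quantile of the trait prevalence.
Default design values emulate the registry sampling frame: ~83% of members
have an observed sibling, couples are opposite-sex, birth years span
1970-1990.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .family_quad_model import ROLES, expected_relative_correlations
from .liability_correlation import TraitSpec

__all__ = [
    "MechanismParams",
    "SimulationDesign",
    "SimulatedPopulation",
    "member_correlation_matrix",
    "multitrait_covariance",
    "simulate_quads",
    "simulate_multitrait",
    "overlay_convergence",
    "dichotomize",
    "skewed_liability",
]

def _check_open_unit(**kwargs):
    for name, v in kwargs.items():
        if v is None or not -1.0 < v < 1.0:
            raise ValueError(f"parameter {name} must lie strictly inside (-1, 1)")


_DEFAULT_TRAITS = (
    TraitSpec("diagnosis", "binary", prevalence=0.0909),  # depressive-disorder-like
)


@dataclass(frozen=True)
class MechanismParams:
    """Parameters of one partner-similarity mechanism (unit-variance scale)."""

    mechanism: str  # {direct, indirect, stratification, convergence_overlay}
    m: float | None = None
    r_s: float | None = None
    a: float | None = None
    mu: float | None = None
    r_m: float | None = None
    r_e: float = 0.0
    q: float | None = None
    n2: float = 0.0
    x: float = 0.0
    skew_gamma: float = 0.0

    def latent(self) -> tuple[float, float, float, float]:
        """Map onto the unified latent representation (a, mu, r_m, r_e).

        Direct assortment is a=1, mu=m, r_m=r_s; stratification is a=q,
        mu=1, r_m=1 (one shared stratum per family).  The chain construction
        is realizable for any parameters strictly inside (-1, 1), so range
        validation is the admissibility check.
        """
        if self.mechanism == "direct":
            _check_open_unit(m=self.m, r_s=self.r_s)
            return 1.0, float(self.m), float(self.r_s), 0.0
        if self.mechanism == "indirect":
            _check_open_unit(a=self.a, mu=self.mu, r_m=self.r_m, r_e=self.r_e)
            return float(self.a), float(self.mu), float(self.r_m), float(self.r_e)
        if self.mechanism == "stratification":
            _check_open_unit(q=self.q)
            return float(self.q), 1.0, 1.0, 0.0
        raise ValueError(f"no latent representation for mechanism {self.mechanism!r}")


@dataclass
class SimulationDesign:
    n_families: int = 200_000
    traits: tuple = _DEFAULT_TRAITS
    sibling_availability: float = 0.832  # registry-like sibling coverage
    missingness: dict = field(default_factory=dict)  # per-role rates
    seed: int = 0
    sex_effect: float = 0.0  # liability mean shift for females
    birth_years: tuple[int, int] = (1970, 1990)

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.sibling_availability <= 1.0:
            raise ValueError("sibling_availability must lie in [0, 1]")
        for role, rate in self.missingness.items():
            if role not in ROLES or not 0.0 <= rate <= 1.0:
                raise ValueError(f"bad missingness entry {role}={rate}")


@dataclass
class SimulatedPopulation:
    """Quad table plus the generating parameters as metadata."""

    data: pd.DataFrame
    params: MechanismParams
    design: SimulationDesign

    def to_csv(self, path) -> None:
        path = str(path)
        self.data.to_csv(path, index=False)
        meta = {
            "params": asdict(self.params),
            "design": {
                **asdict(self.design),
                "traits": [asdict(t) for t in self.design.traits],
            },
        }
        with open(path + ".meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_csv(cls, path) -> "SimulatedPopulation":
        path = str(path)
        data = pd.read_csv(path)
        with open(path + ".meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        traits = tuple(TraitSpec(**t) for t in meta["design"].pop("traits"))
        design = SimulationDesign(traits=traits, **meta["design"])
        params = MechanismParams(**meta["params"])
        return cls(data=data, params=params, design=design)


def _latent_member_matrix(mu: float, r_m: float) -> np.ndarray:
    """Correlation of the four members' latent factors, ROLES order.

    Realized by the chain index -- partner (copath mu) with each sibling
    attached by r_m, so the cross terms are the path products.
    """
    return np.array(
        [
            [1.0, mu, r_m, mu * r_m],
            [mu, 1.0, mu * r_m, r_m],
            [r_m, mu * r_m, 1.0, mu * r_m * r_m],
            [mu * r_m, r_m, mu * r_m * r_m, 1.0],
        ]
    )


def member_correlation_matrix(params: MechanismParams) -> np.ndarray:
    """Path-implied 4x4 phenotype correlation matrix for a single trait."""
    a, mu, r_m, r_e = params.latent()
    K = _latent_member_matrix(mu, r_m)
    res = np.eye(4)
    res[0, 2] = res[2, 0] = r_e  # index-sibling residual similarity
    res[1, 3] = res[3, 1] = r_e
    C = a * a * K + (1.0 - a * a) * res
    np.fill_diagonal(C, 1.0)
    w = np.linalg.eigvalsh(C)[0]
    if w < -1e-10:
        raise ValueError("parameters imply a non-positive-semidefinite structure")
    return C


def multitrait_covariance(loadings, mu, r_m, r_e, within_resid=None) -> np.ndarray:
    """Generating covariance over 4 members x T traits (member-major order).

    Entry ((j,t),(k,s)) is a_t a_s K_M[j,k] plus the residual term: the
    within-person residual correlation W[t,s] when j = k, or the sibling
    residual correlation r_e[t] when t = s and (j,k) are siblings.  Useful as
    the closed-form oracle for partial-correlation and adjustment analyses.
    """
    loadings = np.asarray(loadings, float)
    T = loadings.size
    if np.any(np.abs(loadings) >= 1.0):
        raise ValueError("loadings must lie strictly inside (-1, 1)")
    r_e = np.broadcast_to(np.asarray(r_e, float), (T,))
    W = np.eye(T) if within_resid is None else np.asarray(within_resid, float)
    K = _latent_member_matrix(mu, r_m)
    resid_sd = np.sqrt(1.0 - loadings**2)
    dim = 4 * T
    C = np.zeros((dim, dim))
    sib_pairs = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for j in range(4):
        for k_ in range(4):
            blk = np.outer(loadings, loadings) * K[j, k_]
            if j == k_:
                blk = blk + np.outer(resid_sd, resid_sd) * W
            elif (j, k_) in sib_pairs:
                blk = blk + np.diag(resid_sd**2 * r_e)
            C[j * T : (j + 1) * T, k_ * T : (k_ + 1) * T] = blk
    np.fill_diagonal(C, 1.0)
    w = np.linalg.eigvalsh(C)[0]
    if w < -1e-10:
        raise ValueError("loading structure implies a non-PSD covariance")
    return C


def dichotomize(liabilities: np.ndarray, prevalence: float) -> np.ndarray:
    """1 where liability exceeds the upper-tail quantile at ``prevalence``.

    The threshold is the empirical (1 - prevalence) quantile of the observed
    liabilities, so the construction also applies to skewed liabilities;
    missing values stay missing.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    liabilities = np.asarray(liabilities, float)
    thr = np.nanquantile(liabilities, 1.0 - prevalence)
    out = np.where(liabilities > thr, 1.0, 0.0)
    out[~np.isfinite(liabilities)] = np.nan
    return out


def _package(liab_by_trait, traits, design, params, rng) -> SimulatedPopulation:
    """Assemble the quad DataFrame: covariates, thinning, dichotomization."""
    n = design.n_families
    cols = {"family_id": np.arange(n)}
    sex_index = rng.integers(0, 2, n).astype(float)  # 1 = female
    sexes = {
        "index": sex_index,
        "partner": 1.0 - sex_index,
        "sib_index": rng.integers(0, 2, n).astype(float),
        "sib_partner": rng.integers(0, 2, n).astype(float),
    }
    lo, hi = design.birth_years
    for role in ROLES:
        cols[f"sex_{role}"] = sexes[role]
        cols[f"birth_year_{role}"] = rng.integers(lo, hi + 1, n).astype(float)

    # sibling availability and member-level missingness masks
    drop = {role: np.zeros(n, bool) for role in ROLES}
    for role in ("sib_index", "sib_partner"):
        drop[role] |= rng.random(n) >= design.sibling_availability
    for role, rate in design.missingness.items():
        if rate > 0:
            drop[role] |= rng.random(n) < rate

    for trait, L in zip(traits, liab_by_trait):
        L = L.copy()
        if design.sex_effect:
            for ri, role in enumerate(ROLES):
                L[:, ri] += design.sex_effect * sexes[role]
        for ri, role in enumerate(ROLES):
            L[drop[role], ri] = np.nan
            cols[f"{trait.name}_liab_{role}"] = L[:, ri]
        for ri, role in enumerate(ROLES):
            if trait.kind == "binary":
                cols[f"{trait.name}_{role}"] = dichotomize(L[:, ri], trait.prevalence)
            else:
                cols[f"{trait.name}_{role}"] = trait.mean + trait.sd * L[:, ri]
    return SimulatedPopulation(pd.DataFrame(cols), params, design)


def simulate_quads(params: MechanismParams, design: SimulationDesign) -> SimulatedPopulation:
    """Draw a quad population for each trait independently under one mechanism.

    Reproducible: identical (params, design) including the seed give
    byte-identical output.
    """
    if params.mechanism == "convergence_overlay":
        raise ValueError("use overlay_convergence() on a base population")
    rng = np.random.default_rng(design.seed)
    C = member_correlation_matrix(params)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(4))
    liabs = [
        rng.standard_normal((design.n_families, 4)) @ chol.T for _ in design.traits
    ]
    return _package(liabs, design.traits, design, params, rng)


def simulate_multitrait(
    loadings,
    params: MechanismParams,
    design: SimulationDesign,
    within_resid_corr: np.ndarray | None = None,
) -> SimulatedPopulation:
    """Multitrait population with one latent mating factor per person.

    ``loadings[t]`` is trait t's loading on the mating factor M; the copath
    ``params.mu`` acts on M, siblings correlate ``params.r_m`` in M and
    ``params.r_e`` in the trait residuals.  ``within_resid_corr`` optionally
    correlates the residuals of different traits within a person (e.g. to
    calibrate the within-person GPA-EA correlation).
    """
    loadings = np.asarray(loadings, float)
    if loadings.size != len(design.traits):
        raise ValueError("need one loading per trait")
    C = multitrait_covariance(
        loadings, params.mu, params.r_m, params.r_e, within_resid_corr
    )
    rng = np.random.default_rng(design.seed)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    Z = rng.standard_normal((design.n_families, C.shape[0])) @ chol.T
    T = loadings.size
    liabs = [Z[:, [j * T + t for j in range(4)]] for t in range(T)]
    return _package(liabs, design.traits, design, params, rng)


def overlay_convergence(
    pop: SimulatedPopulation, n2: float, x: float, seed: int | None = None
) -> SimulatedPopulation:
    """Add post-formation convergence to an existing population.

    A couple-shared Gaussian component of variance ``n2`` is added to both
    partners' liabilities, then symmetric mutual influence with coefficient
    ``x`` mixes the partners (simultaneous linear influence).  Columns are
    re-standardized and binary indicators re-dichotomized, so correlations
    stay on the unit-variance scale.  Partner correlations rise more than
    in-law correlations, pushing the IIF below its base value.
    """
    if n2 < 0:
        raise ValueError("n2 must be nonnegative")
    if not -1.0 < x < 1.0:
        raise ValueError("mixing coefficient x must lie strictly inside (-1, 1)")
    if n2 == 0 and x == 0:
        return pop
    rng = np.random.default_rng(pop.design.seed + 1 if seed is None else seed)
    df = pop.data.copy()
    n = len(df)
    for trait in pop.design.traits:
        li = df[f"{trait.name}_liab_index"].to_numpy(float)
        lp = df[f"{trait.name}_liab_partner"].to_numpy(float)
        c = rng.standard_normal(n) * np.sqrt(n2)
        li = li + c
        lp = lp + c
        ni = li + x * lp
        np_ = lp + x * li
        for role, v in (("index", ni), ("partner", np_)):
            v = (v - np.nanmean(v)) / np.nanstd(v)
            df[f"{trait.name}_liab_{role}"] = v
            if trait.kind == "binary":
                df[f"{trait.name}_{role}"] = dichotomize(v, trait.prevalence)
            else:
                df[f"{trait.name}_{role}"] = trait.mean + trait.sd * v
    new_params = MechanismParams(
        **{**asdict(pop.params), "n2": n2, "x": x}
    )
    return SimulatedPopulation(df, new_params, pop.design)


def _sinh_arcsinh_moments(eps: float) -> tuple[float, float]:
    """Mean and sd of sinh(asinh(Z) + eps) for Z ~ N(0,1), by quadrature."""
    from numpy.polynomial.hermite_e import hermegauss

    z, w = hermegauss(201)
    w = w / np.sqrt(2.0 * np.pi)
    v = np.sinh(np.arcsinh(z) + eps)
    m = np.dot(w, v)
    s2 = np.dot(w, (v - m) ** 2)
    return float(m), float(np.sqrt(s2))


def skewed_liability(params: MechanismParams, design: SimulationDesign) -> SimulatedPopulation:
    """Quads whose liabilities are skewed by a common monotone transform.

    Gaussian liabilities are drawn with the mechanism's correlation
    structure and each member's liability is passed through the same
    sinh-arcsinh transform z -> sinh(asinh(z) + skew_gamma) (negative
    ``skew_gamma`` gives left skew), then standardized.  The transform is
    monotone, so dichotomization at a prevalence quantile cuts the
    underlying Gaussian at the matching quantile: the chain product identity
    of the generating correlations carries over to the dichotomized
    tetrachorics even though each tetrachoric overstates the Pearson
    correlation of the skewed variables.  Used for the product-rule
    robustness experiment.
    """
    eps = float(params.skew_gamma)
    rng = np.random.default_rng(design.seed)
    C = member_correlation_matrix(params)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(4))
    mu_e, sd_e = _sinh_arcsinh_moments(eps)
    n = design.n_families
    liabs = []
    for _ in design.traits:
        Z = rng.standard_normal((n, 4)) @ chol.T
        liabs.append((np.sinh(np.arcsinh(Z) + eps) - mu_e) / sd_e)
    return _package(liabs, design.traits, design, params, rng)
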