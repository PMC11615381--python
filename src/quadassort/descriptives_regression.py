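"""Prevalence descriptives and the logistic-regression check of direct assortment.

Overall and conditional prevalences (among partners, siblings, and in-laws of
affected individuals) summarize how diagnoses cluster in couples and extended
families.  The logistic-regression check asks whether the sibling-in-law's
phenotype still predicts the index person's diagnosis once the partner's
phenotype is in the model: under direct (phenotype-based) assortment that
adjusted association is null, whereas indirect assortment leaves it positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .liability_correlation import TraitSpec, correlation_matrix

__all__ = [
    "AdjustedOddsRatio",
    "prevalence_table",
    "logistic_adjusted_or",
    "within_person_matrix",
]

# relative pairs pooled for conditional prevalences: (affected role, relative role)
_RELATIVE_PAIRS = {
    "partner": [("index", "partner"), ("partner", "index")],
    "sibling": [("index", "sib_index"), ("partner", "sib_partner")],
    "inlaw": [("index", "sib_partner"), ("partner", "sib_index")],
}


def prevalence_table(
    pop: pd.DataFrame,
    traits: list[TraitSpec],
    suppress_below: int = 10,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Per-trait prevalence and conditional prevalence among relatives of affected.

    Counts below ``suppress_below`` are masked (disclosure rule mirroring
    small-cell suppression in registry outputs).  With ``by_sex`` the overall
    prevalence is additionally split by the index member's sex.
    """
    rows = []
    for trait in traits:
        name = trait.name
        vals = np.concatenate(
            [pop[f"{name}_index"].to_numpy(float), pop[f"{name}_partner"].to_numpy(float)]
        )
        obs = vals[np.isfinite(vals)]
        n_aff = int(np.sum(obs == 1))
        row = {
            "trait": name,
            "n_affected": n_aff,
            "prevalence_pct": 100.0 * n_aff / obs.size if obs.size else np.nan,
        }
        lo, hi = proportion_confint(n_aff, obs.size, method="wilson") if obs.size else (np.nan, np.nan)
        row["prev_ci_low_pct"], row["prev_ci_high_pct"] = 100 * lo, 100 * hi
        if by_sex:
            sexes = np.concatenate(
                [pop["sex_index"].to_numpy(float), pop["sex_partner"].to_numpy(float)]
            )
            for label, code in (("female", 1.0), ("male", 0.0)):
                sel = (sexes == code) & np.isfinite(vals)
                row[f"prevalence_{label}_pct"] = (
                    100.0 * np.mean(vals[sel] == 1) if sel.any() else np.nan
                )
        for rel, pairs in _RELATIVE_PAIRS.items():
            num = den = 0
            for aff_role, rel_role in pairs:
                a = pop[f"{name}_{aff_role}"].to_numpy(float)
                b = pop[f"{name}_{rel_role}"].to_numpy(float)
                sel = (a == 1) & np.isfinite(b)
                den += int(sel.sum())
                num += int(np.sum(b[sel] == 1))
            if den == 0:
                row[f"n_{rel}_of_affected"] = np.nan
                row[f"prev_{rel}_of_affected_pct"] = np.nan
            elif num < suppress_below:
                row[f"n_{rel}_of_affected"] = np.nan  # suppressed small cell
                row[f"prev_{rel}_of_affected_pct"] = np.nan
            else:
                row[f"n_{rel}_of_affected"] = num
                row[f"prev_{rel}_of_affected_pct"] = 100.0 * num / den
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AdjustedOddsRatio:
    outcome: str
    predictor: str
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    separation: bool = False


def logistic_adjusted_or(
    pop: pd.DataFrame,
    outcome: str,
    predictors: tuple = ("partner", "sib_inlaw"),
    covariates: tuple = (),
) -> list[AdjustedOddsRatio]:
    """Odds ratios for the index person's diagnosis on relatives' phenotypes.

    ``predictors`` select the partner's phenotype and/or the sibling-in-law's
    (partner's sibling's) phenotype; both enter one multiple logistic
    regression so the in-law OR is adjusted for the partner association.
    Fitting is maximum likelihood via IRLS with Wald confidence intervals;
    complete separation is flagged, never silently diverged.
    """
    colmap = {"partner": f"{outcome}_partner", "sib_inlaw": f"{outcome}_sib_partner"}
    y = pop[f"{outcome}_index"].to_numpy(float)
    Xcols = []
    names = []
    for pr in predictors:
        if pr not in colmap:
            raise ValueError(f"unknown predictor {pr!r}")
        Xcols.append(pop[colmap[pr]].to_numpy(float))
        names.append(pr)
    for cov in covariates:
        Xcols.append(pop[f"{cov}_index"].to_numpy(float))
        names.append(cov)
    X = np.column_stack(Xcols)
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[mask], X[mask]
    Xd = sm.add_constant(X)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient")
    separation = False
    try:
        fit = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(maxiter=50, tol=1e-10)
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        if np.any(np.abs(params[1:]) > 15):
            separation = True
    except Exception:
        separation = True
        params = np.full(Xd.shape[1], np.nan)
        bse = pvals = params
    out = []
    for i, nm in enumerate(names, start=1):
        b, s = params[i], bse[i]
        out.append(
            AdjustedOddsRatio(
                outcome=outcome,
                predictor=nm,
                odds_ratio=float(np.exp(b)),
                ci95=(float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s))),
                p=float(pvals[i]),
                separation=separation,
            )
        )
    return out


def within_person_matrix(
    pop: pd.DataFrame, traits: list[TraitSpec], adjust=None
) -> pd.DataFrame:
    """Within-individual trait correlation matrix (delegates to the estimators)."""
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    return correlation_matrix(pop, traits, relationship="within_person", adjust=adjust)
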