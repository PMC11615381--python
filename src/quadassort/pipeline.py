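"""End-to-end orchestration: simulate or load quads, estimate, test, summarize.

A run is described by a :class:`RunConfig` (typically loaded from YAML): one
input source (a quad CSV or a simulation block), the traits and their kinds,
the relationships and adjustment arms to estimate, and the FDR level.  The
resulting :class:`AnalysisReport` holds the correlation matrices per arm, a
direct-assortment table (free and constrained quad fits, IIF, raw and
FDR-adjusted likelihood-ratio p-values), median correlations by trait
category, percent-reduction summaries across arms, and provenance (config
hash, seed, package version) so the report can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .family_quad_model import bh_adjust, fit_quad_model, lrt_direct_assortment
from .liability_correlation import TraitSpec, correlation_matrix, percent_reduction
from .mechanism_simulator import (
    MechanismParams,
    SimulatedPopulation,
    SimulationDesign,
    simulate_multitrait,
    simulate_quads,
)

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "median_by_category"]

log = logging.getLogger("quadassort")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    traits: list = field(default_factory=list)  # TraitSpec or dicts
    input_path: str | None = None
    simulation: dict | None = None  # {"params": {...}, "design": {...}, "loadings": [...]?}
    relationships: list = field(default_factory=lambda: ["partner", "sibling", "inlaw"])
    arms: dict = field(default_factory=lambda: {"unadjusted": {}})
    categories: dict = field(default_factory=dict)  # trait -> category
    fdr_alpha: float = 0.05
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path and simulation must be set")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        self.traits = [
            t if isinstance(t, TraitSpec) else TraitSpec(**t) for t in self.traits
        ]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = repr(
            (
                [repr(t) for t in self.traits],
                self.input_path,
                self.simulation,
                self.relationships,
                self.arms,
                sorted(self.categories.items()),
                self.fdr_alpha,
                self.seed,
            )
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    matrices: dict  # (arm, relationship) -> DataFrame
    direct_assortment: pd.DataFrame
    medians: pd.DataFrame | None
    reductions: pd.DataFrame | None
    provenance: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (arm, rel), df in self.matrices.items():
            df.to_csv(outdir / f"correlations_{arm}_{rel}.csv", index=False)
        self.direct_assortment.to_csv(outdir / "direct_assortment.csv", index=False)
        if self.medians is not None:
            self.medians.to_csv(outdir / "median_by_category.csv", index=False)
        if self.reductions is not None:
            self.reductions.to_csv(outdir / "percent_reduction.csv", index=False)
        with open(outdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(self.provenance, fh)


def _load_population(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return pd.read_csv(config.input_path)
    sim = dict(config.simulation)
    params = MechanismParams(**sim["params"])
    design_kw = dict(sim.get("design", {}))
    design_kw.setdefault("seed", config.seed)
    design = SimulationDesign(traits=tuple(config.traits), **design_kw)
    if "loadings" in sim:
        pop = simulate_multitrait(sim["loadings"], params, design)
    else:
        pop = simulate_quads(params, design)
    return pop.data


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run all stages; deterministic given the config (seed included)."""
    t0 = time.time()
    pop = _load_population(config)
    log.info("population ready: %d quads (%.1fs)", len(pop), time.time() - t0)

    matrices = {}
    for arm, spec in config.arms.items():
        adjust = spec.get("adjust") or None
        adjust_both = spec.get("adjust_both") or None
        arm_traits = [
            t for t in config.traits
            if t.name not in (adjust_both or []) and t.name not in (adjust or [])
        ]
        for rel in config.relationships:
            t1 = time.time()
            matrices[(arm, rel)] = correlation_matrix(
                pop, arm_traits, rel, adjust=adjust, adjust_both=adjust_both
            )
            log.info("arm %s / %s estimated (%.1fs)", arm, rel, time.time() - t1)

    rows = []
    for trait in config.traits:
        try:
            free = fit_quad_model(pop, trait, constrained=False)
            con = fit_quad_model(pop, trait, constrained=True, compute_se=False)
            test = lrt_direct_assortment(free, con)
            s = free.structure
            rows.append(
                dict(trait=trait.name, r_partner=s.r_partner, r_sibling=s.r_sibling,
                     r_inlaw=s.r_inlaw, r_cosib=s.r_cosib, iif=test.iif,
                     lrt_stat=test.lrt_stat, p_raw=test.p_raw,
                     converged=free.converged and con.converged)
            )
        except Exception as exc:  # one trait failing must not abort the run
            warnings.warn(f"quad fit failed for {trait.name}: {exc}")
            rows.append(dict(trait=trait.name, r_partner=np.nan, r_sibling=np.nan,
                             r_inlaw=np.nan, r_cosib=np.nan, iif=np.nan,
                             lrt_stat=np.nan, p_raw=np.nan, converged=False))
    direct = pd.DataFrame(rows)
    ok = np.isfinite(direct["p_raw"].to_numpy(float))
    p_bh = np.full(len(direct), np.nan)
    if ok.any():
        p_bh[ok] = bh_adjust(direct.loc[ok, "p_raw"].to_numpy(float))
    direct["p_bh"] = p_bh

    medians = None
    if config.categories:
        parts = []
        for (arm, rel), df in matrices.items():
            m = median_by_category(df, config.categories)
            m.insert(0, "arm", arm)
            m.insert(1, "relationship", rel)
            parts.append(m)
        medians = pd.concat(parts, ignore_index=True)

    reductions = None
    arms = list(config.arms)
    if len(arms) > 1:
        base = arms[0]
        red_rows = []
        for arm in arms[1:]:
            for rel in config.relationships:
                b = matrices[(base, rel)].set_index(["trait_a", "trait_b"])
                a = matrices[(arm, rel)].set_index(["trait_a", "trait_b"])
                for key in a.index.intersection(b.index):
                    red_rows.append(
                        dict(arm=arm, relationship=rel, trait_a=key[0], trait_b=key[1],
                             r_base=b.loc[key, "r"], r_adjusted=a.loc[key, "r"],
                             pct_reduction=percent_reduction(b.loc[key, "r"], a.loc[key, "r"]))
                    )
        reductions = pd.DataFrame(red_rows)
        if len(reductions):
            med = (
                reductions.groupby(["arm", "relationship"])["pct_reduction"]
                .median()
                .reset_index()
                .rename(columns={"pct_reduction": "median_pct_reduction"})
            )
            reductions = reductions.merge(med, on=["arm", "relationship"])

    report = AnalysisReport(
        matrices=matrices,
        direct_assortment=direct,
        medians=medians,
        reductions=reductions,
        provenance={
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    if config.outdir:
        report.save(config.outdir)
    return report


def median_by_category(matrix: pd.DataFrame, categories: dict) -> pd.DataFrame:
    """Median correlation and SE per category pair, within vs across traits."""
    missing = (set(matrix["trait_a"]) | set(matrix["trait_b"])) - set(categories)
    if missing:
        raise ValueError(f"uncategorized traits: {sorted(missing)}")
    df = matrix.copy()
    df = df[df["method"] != "identity"]
    df["cat_a"] = df["trait_a"].map(categories)
    df["cat_b"] = df["trait_b"].map(categories)
    df["within"] = np.where(df["trait_a"] == df["trait_b"], "within", "across")
    out = (
        df.groupby(["cat_a", "cat_b", "within"], sort=True)
        .agg(median_r=("r", "median"), median_se=("se", "median"), n_cells=("r", "size"))
        .reset_index()
    )
    return out
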