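"""Simulator contracts: determinism, prevalence calibration, path-traced moments."""

import numpy as np
import pandas as pd
import pytest

from quadassort import (
    MechanismParams,
    SimulatedPopulation,
    SimulationDesign,
    TraitSpec,
    dichotomize,
    expected_relative_correlations,
    member_correlation_matrix,
    multitrait_covariance,
    overlay_convergence,
    simulate_multitrait,
    simulate_quads,
    skewed_liability,
)

ROLE_COLS = ("index", "partner", "sib_index", "sib_partner")


def _pair_corr(df, trait, role_a, role_b):
    a = df[f"{trait}_{role_a}"].to_numpy(float)
    b = df[f"{trait}_{role_b}"].to_numpy(float)
    m = np.isfinite(a) & np.isfinite(b)
    return np.corrcoef(a[m], b[m])[0, 1]


def _relationship_corrs(df, trait):
    rp = _pair_corr(df, trait, "index", "partner")
    rs = 0.5 * (_pair_corr(df, trait, "index", "sib_index")
                + _pair_corr(df, trait, "partner", "sib_partner"))
    ri = 0.5 * (_pair_corr(df, trait, "index", "sib_partner")
                + _pair_corr(df, trait, "partner", "sib_index"))
    return rp, rs, ri


class TestSimulateQuads:
    def test_seed_determinism_is_byte_identical(self, continuous_trait):
        params = MechanismParams("direct", m=0.4, r_s=0.3)
        design = SimulationDesign(n_families=2_000, traits=(continuous_trait,), seed=5)
        a = simulate_quads(params, design).data
        b = simulate_quads(params, design).data
        pd.testing.assert_frame_equal(a, b)

    def test_zero_copath_gives_no_partner_or_inlaw_similarity(self, continuous_trait):
        pop = simulate_quads(
            MechanismParams("direct", m=0.0, r_s=0.4),
            SimulationDesign(n_families=50_000, traits=(continuous_trait,), seed=6),
        )
        rp, rs, ri = _relationship_corrs(pop.data, "score")
        assert abs(rp) < 0.02 and abs(ri) < 0.02
        assert rs == pytest.approx(0.4, abs=0.02)

    @pytest.mark.parametrize(
        "params",
        [
            MechanismParams("direct", m=0.5, r_s=0.4),
            MechanismParams("indirect", a=np.sqrt(0.5), mu=0.6, r_m=0.5, r_e=0.0),
            MechanismParams("indirect", a=np.sqrt(0.5), mu=0.6, r_m=0.4, r_e=0.4),
            MechanismParams("stratification", q=0.6),
        ],
        ids=["direct", "indirect", "indirect-residual", "stratification"],
    )
    def test_mechanism_moments_match_path_tracing(self, params, continuous_trait):
        design = SimulationDesign(
            n_families=150_000, traits=(continuous_trait,), seed=13, sibling_availability=1.0
        )
        pop = simulate_quads(params, design)
        rp, rs, ri = _relationship_corrs(pop.data, "score")
        e = expected_relative_correlations(params)
        mc = 3.0 / np.sqrt(design.n_families)
        assert rp == pytest.approx(e.r_partner, abs=3 * mc)
        assert rs == pytest.approx(e.r_sibling, abs=3 * mc)
        assert ri == pytest.approx(e.r_inlaw, abs=3 * mc)

    def test_prevalence_calibration(self, binary_trait):
        pop = simulate_quads(
            MechanismParams("direct", m=0.5, r_s=0.4),
            SimulationDesign(n_families=50_000, traits=(binary_trait,), seed=14),
        )
        for role in ROLE_COLS:
            v = pop.data[f"dx_{role}"].dropna()
            se = np.sqrt(0.0909 * (1 - 0.0909) / len(v))
            assert v.mean() == pytest.approx(0.0909, abs=3 * se + 1e-4)

    def test_sibling_availability_thinning(self, continuous_trait):
        design = SimulationDesign(
            n_families=20_000, traits=(continuous_trait,), seed=15, sibling_availability=0.832
        )
        pop = simulate_quads(MechanismParams("direct", m=0.5, r_s=0.4), design)
        frac = np.isfinite(pop.data["score_sib_index"]).mean()
        assert frac == pytest.approx(0.832, abs=0.01)

    def test_inadmissible_parameters_rejected(self):
        with pytest.raises(ValueError):
            member_correlation_matrix(MechanismParams("direct", m=1.2, r_s=0.4))
        with pytest.raises(ValueError):
            member_correlation_matrix(MechanismParams("indirect", a=0.7, mu=None, r_m=0.5))

    def test_csv_metadata_roundtrip(self, tmp_path, binary_trait):
        design = SimulationDesign(n_families=500, traits=(binary_trait,), seed=16)
        pop = simulate_quads(MechanismParams("direct", m=0.5, r_s=0.4), design)
        path = tmp_path / "quads.csv"
        pop.to_csv(path)
        back = SimulatedPopulation.from_csv(path)
        assert back.params == pop.params
        assert back.design.seed == 16
        assert back.design.traits[0].prevalence == pytest.approx(0.0909)
        pd.testing.assert_frame_equal(back.data, pop.data)


class TestDichotomize:
    def test_median_split_and_prevalence(self, rng):
        z = rng.standard_normal(20_000)
        half = dichotomize(z, 0.5)
        assert half.mean() == pytest.approx(0.5, abs=0.01)
        dep = dichotomize(z, 0.0909)
        assert dep.mean() == pytest.approx(0.0909, abs=0.005)

    def test_nan_passthrough_and_domain(self, rng):
        z = rng.standard_normal(100)
        z[0] = np.nan
        out = dichotomize(z, 0.2)
        assert np.isnan(out[0])
        with pytest.raises(ValueError):
            dichotomize(z, 0.0)


class TestConvergenceOverlay:
    def test_identity_when_disabled(self, direct_pop_continuous):
        assert overlay_convergence(direct_pop_continuous, 0.0, 0.0) is direct_pop_continuous

    def test_shared_environment_variance_bookkeeping(self, continuous_trait):
        # no assortment at all: r_partner = n2/(1+n2), in-laws stay unrelated
        pop = simulate_quads(
            MechanismParams("direct", m=0.0, r_s=0.0),
            SimulationDesign(n_families=80_000, traits=(continuous_trait,), seed=21),
        )
        ov = overlay_convergence(pop, n2=0.2, x=0.0)
        rp, _, ri = _relationship_corrs(ov.data, "score")
        assert rp == pytest.approx(0.2 / 1.2, abs=0.015)
        assert abs(ri) < 0.015

    def test_overlay_deflates_iif_below_one(self, direct_pop_continuous, continuous_trait):
        from quadassort import fit_quad_model

        ov = overlay_convergence(direct_pop_continuous, n2=0.2, x=0.0)
        fit = fit_quad_model(ov.data, continuous_trait, compute_se=False)
        e = expected_relative_correlations(
            MechanismParams("convergence_overlay", m=0.5, r_s=0.4, n2=0.2, x=0.0)
        )
        assert fit.structure.iif < 1.0
        assert fit.structure.iif == pytest.approx(e.iif, abs=0.05)

    def test_mutual_influence_also_deflates(self, direct_pop_continuous, continuous_trait):
        from quadassort import fit_quad_model

        ov = overlay_convergence(direct_pop_continuous, n2=0.0, x=0.3)
        fit = fit_quad_model(ov.data, continuous_trait, compute_se=False)
        e = expected_relative_correlations(
            MechanismParams("convergence_overlay", m=0.5, r_s=0.4, n2=0.0, x=0.3)
        )
        assert fit.structure.iif < 1.0
        assert fit.structure.r_partner == pytest.approx(e.r_partner, abs=0.02)


class TestSkewedLiability:
    def test_skew_sign_follows_parameter(self, binary_trait):
        design = SimulationDesign(n_families=30_000, traits=(binary_trait,), seed=31)
        left = skewed_liability(
            MechanismParams("direct", m=0.5, r_s=0.4, skew_gamma=-0.8), design
        )
        from scipy.stats import skew

        assert skew(left.data["dx_liab_index"].dropna()) < -0.3

    def test_gaussian_limit_preserves_pearson_structure(self, binary_trait):
        design = SimulationDesign(
            n_families=80_000, traits=(binary_trait,), seed=32, sibling_availability=1.0
        )
        pop = skewed_liability(MechanismParams("direct", m=0.6, r_s=0.5, skew_gamma=0.0), design)
        r_ip = _pair_corr(pop.data, "dx_liab", "index", "partner")
        r_ps = _pair_corr(pop.data, "dx_liab", "partner", "sib_partner")
        r_is = _pair_corr(pop.data, "dx_liab", "index", "sib_partner")
        assert r_ip == pytest.approx(0.6, abs=0.01)
        assert r_ip * r_ps == pytest.approx(r_is, abs=0.015)

    def test_product_identity_survives_skew_and_dichotomization(self, binary_trait):
        """Chain tetrachorics keep r_ab * r_bc = r_ac under left-skewed liabilities."""
        from quadassort import PairedObservations, estimate_tetrachoric

        design = SimulationDesign(
            n_families=150_000, traits=(binary_trait,), seed=33, sibling_availability=1.0
        )
        pop = skewed_liability(
            MechanismParams("direct", m=0.6, r_s=0.5, skew_gamma=-0.8), design
        )
        d = pop.data

        def tet(a, b):
            return estimate_tetrachoric(
                PairedObservations(d[a].to_numpy(), d[b].to_numpy())
            )

        r_ab = tet("dx_index", "dx_partner")
        r_bc = tet("dx_partner", "dx_sib_partner")
        r_ac = tet("dx_index", "dx_sib_partner")
        se = np.sqrt(
            (r_bc.r * r_ab.se) ** 2 + (r_ab.r * r_bc.se) ** 2 + r_ac.se**2
        )
        assert r_ab.r * r_bc.r == pytest.approx(r_ac.r, abs=3 * se)


class TestMultitrait:
    def test_zero_loadings_give_no_cross_trait_partner_correlation(self):
        traits = (TraitSpec("a", "continuous"), TraitSpec("b", "continuous"))
        design = SimulationDesign(n_families=40_000, traits=traits, seed=41)
        pop = simulate_multitrait(
            [0.0, 0.0], MechanismParams("indirect", mu=0.7, r_m=0.5), design
        )
        assert abs(_pair_corr(pop.data, "a", "index", "partner")) < 0.02
        x = pop.data["a_index"].to_numpy(float)
        y = pop.data["b_partner"].to_numpy(float)
        m = np.isfinite(x) & np.isfinite(y)
        assert abs(np.corrcoef(x[m], y[m])[0, 1]) < 0.02

    def test_cross_trait_equals_within_trait_for_equal_loadings(self):
        traits = (TraitSpec("h1", "continuous"), TraitSpec("h2", "continuous"))
        design = SimulationDesign(n_families=100_000, traits=traits, seed=42)
        pop = simulate_multitrait(
            [0.5, 0.5], MechanismParams("indirect", mu=0.6, r_m=0.5), design
        )
        within = _pair_corr(pop.data, "h1", "index", "partner")
        x = pop.data["h1_index"].to_numpy(float)
        y = pop.data["h2_partner"].to_numpy(float)
        m = np.isfinite(x) & np.isfinite(y)
        across = np.corrcoef(x[m], y[m])[0, 1]
        assert within == pytest.approx(0.25 * 0.6, abs=0.01)
        assert across == pytest.approx(within, abs=0.01)

    def test_generating_covariance_is_the_moment_oracle(self):
        traits = (TraitSpec("edu", "continuous"), TraitSpec("h", "continuous"))
        design = SimulationDesign(
            n_families=150_000, traits=traits, seed=43, sibling_availability=1.0
        )
        pop = simulate_multitrait(
            [0.8, 0.5], MechanismParams("indirect", mu=0.7, r_m=0.5, r_e=0.0), design
        )
        C = multitrait_covariance([0.8, 0.5], 0.7, 0.5, 0.0)
        # partner health correlation: a_h^2 * mu = 0.175 -> entry (h_index, h_partner)
        assert C[1, 3] == pytest.approx(0.5 * 0.5 * 0.7)
        obs = _pair_corr(pop.data, "h", "index", "partner")
        assert obs == pytest.approx(C[1, 3], abs=3.0 * 3 / np.sqrt(design.n_families))

    def test_non_psd_loadings_rejected(self):
        with pytest.raises(ValueError):
            multitrait_covariance([1.2, 0.5], 0.7, 0.5, 0.0)
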