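import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import exclosim as ex
from exclosim.lmm import CollinearityError, build_fixed_matrix, _response_vector
from conftest import ols_normal_equations

FULL = ex.ModelSpec(response="biomass_g")


class TestExactRecovery:
    def test_noise_free_main_only_recovered_exactly(self, design_10sites):
        vc = ex.VarianceComponents(0, 0, 0)
        sim = ex.simulate_experiment(
            design_10sites, ex.scenario_from_preset("main_only", 10.0), vc, 1
        )
        fit = ex.fit_lmm(sim, FULL, criterion="reml")
        expected = {"(Intercept)": 100.0, "i": 10.0, "f": 10.0, "m": 10.0,
                    "f:m": 0.0, "i:m": 0.0, "i:f": 0.0, "i:f:m": 0.0}
        for term, value in expected.items():
            assert fit.params[term] == pytest.approx(value, abs=1e-9)
        assert fit.vcomp["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_estimates_are_cell_mean_contrasts(self, noisy_data_10sites):
        fit = ex.fit_lmm(noisy_data_10sites, FULL)
        cells = noisy_data_10sites.groupby(list(ex.TREATMENT_COLUMNS))["biomass_g"].mean()
        assert fit.params["(Intercept)"] == pytest.approx(cells[(0, 0, 0)])
        assert fit.params["i"] == pytest.approx(cells[(1, 0, 0)] - cells[(0, 0, 0)])
        assert fit.params["f:m"] == pytest.approx(
            cells[(0, 1, 1)] - cells[(0, 1, 0)] - cells[(0, 0, 1)] + cells[(0, 0, 0)]
        )


class TestOLSOracle:
    def test_single_site_fixed_effects_match_normal_equations(self, design_1site):
        sim = ex.simulate_experiment(
            design_1site, ex.scenario_from_preset("superadditive", 10.0),
            ex.VarianceComponents(0, 7.82, 15.33), seed=5,
        )
        spec = ex.ModelSpec(
            response="biomass_g", fixed_terms=("block_id",) + ex.TERM_ORDER,
            random_intercepts=(),
        )
        fit = ex.fit_lmm(sim, spec)
        X, labels, _ = build_fixed_matrix(sim, spec.fixed_terms, spec.coding)
        beta = ols_normal_equations(X, sim["biomass_g"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_mixed_fixed_effects_match_ols_on_balanced_data(self, noisy_data_10sites):
        # under balance GLS == OLS, so the mixed fit must agree with the
        # independent normal-equations solve
        fit = ex.fit_lmm(noisy_data_10sites, FULL)
        X, labels, _ = build_fixed_matrix(noisy_data_10sites, FULL.fixed_terms, FULL.coding)
        beta = ols_normal_equations(X, noisy_data_10sites["biomass_g"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)


class TestVarianceComponents:
    def test_parameter_recovery_200_sites(self):
        design = ex.build_design(ex.DesignSpec(n_sites=200, rng_seed=2))
        sim = ex.simulate_experiment(
            design, ex.scenario_from_preset("main_only", 10.0), ex.PAPER_VC, seed=3
        )
        fit = ex.fit_lmm(sim, FULL, criterion="reml")
        assert np.sqrt(fit.vcomp["site"]) == pytest.approx(372.7, rel=0.10)
        assert np.sqrt(fit.vcomp["block"]) == pytest.approx(7.82, rel=0.35)
        assert np.sqrt(fit.vcomp["residual"]) == pytest.approx(15.33, rel=0.05)

    def test_boundary_block_variance_clamped_to_zero(self, design_10sites):
        vc = ex.VarianceComponents(50.0, 0.0, 15.0)  # no true block variation
        sim = ex.simulate_experiment(
            design_10sites, ex.scenario_from_preset("null", 0), vc, seed=12
        )
        fit = ex.fit_lmm(sim, FULL)
        assert fit.vcomp["block"] >= 0.0
        assert fit.converged


@pytest.fixture(scope="module")
def pair(noisy_data_10sites):
    """Fast-path and MixedLM fits of the same data, per criterion."""
    from exclosim.lmm import _fit_mixedlm

    fits = {}
    for crit in ("ml", "reml"):
        fast = ex.fit_lmm(noisy_data_10sites, FULL, criterion=crit)
        assert fast.method == "balanced-exact"
        y = _response_vector(noisy_data_10sites, FULL)
        X, labels, _ = build_fixed_matrix(noisy_data_10sites, FULL.fixed_terms, FULL.coding)
        slow = _fit_mixedlm(noisy_data_10sites, y, X, labels, FULL, crit)
        fits[crit] = (fast, slow)
    return fits


class TestAgainstMixedLM:
    """The exact balanced solver and statsmodels MixedLM are interchangeable."""

    def test_fixed_effects_agree(self, pair):
        for fast, slow in pair.values():
            np.testing.assert_allclose(fast.params, slow.params, atol=1e-6)

    def test_loglik_agrees(self, pair):
        for fast, slow in pair.values():
            assert fast.llf == pytest.approx(slow.llf, abs=1e-3)

    def test_variance_components_agree(self, pair):
        for fast, slow in pair.values():
            for key in ("site", "block", "residual"):
                assert fast.vcomp[key] == pytest.approx(slow.vcomp[key], rel=5e-3)

    def test_standard_errors_agree(self, pair):
        for fast, slow in pair.values():
            np.testing.assert_allclose(fast.bse, slow.bse, rtol=2e-3)


def test_against_lme4(noisy_data_10sites, tmp_path):
    """REML/ML log-likelihoods, estimates and variance components match lmer."""
    csv = tmp_path / "d.csv"
    noisy_data_10sites.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
suppressMessages(library(lme4))
d <- read.csv('%s')
d$site_block <- paste(d$site_id, d$block_id)
f <- biomass_g ~ insecticide*fungicide*molluscicide + (1|site_id) + (1|site_block)
m <- lmer(f, data=d, REML=TRUE); m2 <- lmer(f, data=d, REML=FALSE)
vc <- as.data.frame(VarCorr(m))
cat(as.numeric(logLik(m)), as.numeric(logLik(m2)),
    vc$vcov[vc$grp=='site_id'], vc$vcov[vc$grp=='site_block'],
    vc$vcov[vc$grp=='Residual'], fixef(m), sep='\\n')
""" % csv
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    vals = [float(v) for v in out.stdout.split()]
    reml_ll, ml_ll, v_site, v_block, v_res = vals[:5]
    fixef = np.array(vals[5:])
    fast_reml = ex.fit_lmm(noisy_data_10sites, FULL, criterion="reml")
    fast_ml = ex.fit_lmm(noisy_data_10sites, FULL, criterion="ml")
    assert fast_reml.llf == pytest.approx(reml_ll, abs=1e-3)
    assert fast_ml.llf == pytest.approx(ml_ll, abs=1e-3)
    assert fast_reml.vcomp["site"] == pytest.approx(v_site, rel=1e-3)
    assert fast_reml.vcomp["block"] == pytest.approx(v_block, rel=1e-2)
    assert fast_reml.vcomp["residual"] == pytest.approx(v_res, rel=1e-3)
    # lme4 orders the factorial terms differently; compare by magnitude set
    np.testing.assert_allclose(
        np.sort(np.abs(fast_reml.params.to_numpy())), np.sort(np.abs(fixef)), rtol=1e-5
    )


class TestLRT:
    def test_identical_models_give_zero_statistic(self, noisy_data_10sites):
        fit = ex.fit_lmm(noisy_data_10sites, FULL, criterion="ml")
        res = ex.lrt_test(fit, fit)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_chi2_quantile_identity(self):
        # a df-1 statistic of 3.841 sits exactly at p = 0.05
        assert stats.chi2.sf(3.841458820694124, 1) == pytest.approx(0.05, abs=1e-12)

    def test_pvalue_matches_independent_chi2_oracle(self, noisy_data_10sites):
        full = ex.fit_lmm(noisy_data_10sites, FULL, criterion="ml")
        red = ex.fit_lmm(noisy_data_10sites, FULL.drop_term("i:f:m"), criterion="ml")
        res = ex.lrt_test(full, red)
        assert res.df == 1

        # independent oracle: survival function by numerical integration of
        # the chi-squared density
        from scipy.integrate import quad

        oracle, _ = quad(lambda t: stats.chi2.pdf(t, 1), res.statistic, np.inf)
        assert res.pvalue == pytest.approx(oracle, abs=1e-10)

    def test_reml_fits_rejected(self, noisy_data_10sites):
        full = ex.fit_lmm(noisy_data_10sites, FULL, criterion="reml")
        red = ex.fit_lmm(noisy_data_10sites, FULL.drop_term("i"), criterion="reml")
        with pytest.raises(ValueError, match="unrestricted"):
            ex.lrt_test(full, red)

    def test_non_nested_rejected(self, noisy_data_10sites):
        a = ex.fit_lmm(noisy_data_10sites, FULL.drop_term("i"), criterion="ml")
        b = ex.fit_lmm(noisy_data_10sites, FULL.drop_term("f"), criterion="ml")
        with pytest.raises(ValueError, match="nested"):
            ex.lrt_test(a, b)


class TestWald:
    def test_normal_quantile_identity(self, noisy_data_10sites):
        fit = ex.fit_lmm(noisy_data_10sites, FULL)
        p = ex.wald_summary(fit)
        # independent normal survival-function oracle via the error function
        from math import erfc, sqrt

        for term in fit.terms:
            z = abs(fit.params[term] / fit.bse[term])
            assert p[term] == pytest.approx(erfc(z / sqrt(2.0)), abs=1e-10)

    def test_zero_estimate_gives_p_one(self, design_10sites):
        sim = ex.simulate_experiment(
            design_10sites, ex.scenario_from_preset("null", 0),
            ex.VarianceComponents(0, 0, 0), 1,
        )
        fit = ex.fit_lmm(sim, FULL)
        p = ex.wald_summary(fit)
        assert p["i"] == 1.0  # zero estimate, zero SE
        assert p["(Intercept)"] == 0.0  # nonzero estimate, zero SE


class TestInvariances:
    def test_row_shuffle_leaves_estimates_unchanged(self, noisy_data_10sites):
        fit = ex.fit_lmm(noisy_data_10sites, FULL)
        rng = np.random.default_rng(4)
        shuffled = noisy_data_10sites.sample(frac=1.0, random_state=7)
        fit2 = ex.fit_lmm(shuffled, FULL)
        np.testing.assert_allclose(fit.params, fit2.params, atol=1e-8)
        assert fit.llf == pytest.approx(fit2.llf, abs=1e-8)

    def test_log_transform_composes(self, noisy_data_10sites):
        data = noisy_data_10sites.copy()
        data["biomass_g"] = data["biomass_g"] + 2000.0  # ensure positivity
        log_spec = ex.ModelSpec(response="biomass_g", transform="log")
        fit_a = ex.fit_lmm(data, log_spec)
        pre = data.copy()
        pre["biomass_g"] = np.log(pre["biomass_g"])
        fit_b = ex.fit_lmm(pre, ex.ModelSpec(response="biomass_g"))
        np.testing.assert_allclose(fit_a.params, fit_b.params, atol=1e-12)
        assert fit_a.llf == pytest.approx(fit_b.llf, abs=1e-10)

    def test_log_of_nonpositive_raises(self, noisy_data_10sites):
        with pytest.raises(ValueError, match="positive"):
            ex.fit_lmm(noisy_data_10sites, ex.ModelSpec(response="biomass_g", transform="log"))

    def test_type_one_error_calibrated_under_null(self):
        """LRT on the insecticide term rejects ~5% of null simulations."""
        design = ex.build_design(ex.DesignSpec(n_sites=35, rng_seed=6))
        null = ex.scenario_from_preset("null", 0.0)
        spec = FULL
        red = spec.drop_term("i")
        n_sim, n_reject = 1000, 0
        for r in range(n_sim):
            sim = ex.simulate_experiment(design, null, ex.PAPER_VC, seed=[88, r])
            full_fit = ex.fit_lmm(sim, spec, criterion="ml")
            red_fit = ex.fit_lmm(sim, red, criterion="ml")
            if ex.lrt_test(full_fit, red_fit).pvalue < 0.05:
                n_reject += 1
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(n_reject / n_sim - 0.05) < 3.5 * se


def test_collinear_terms_raise_named_error(noisy_data_10sites):
    data = noisy_data_10sites.copy()
    data["dup"] = data["insecticide"].astype(float)  # alias of i
    spec = ex.ModelSpec(response="biomass_g", fixed_terms=("i", "f", "dup"))
    with pytest.raises(CollinearityError, match="dup"):
        ex.fit_lmm(data, spec)
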