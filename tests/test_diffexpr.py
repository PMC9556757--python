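import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexmap.datamodel import ExpressionMatrix, ExpressionStudy, subset_by
from coexmap.diffexpr import (
    DesignError,
    EmpiricalBayesParams,
    bh_fdr,
    call_degs,
    deg_table,
    estimate_prior,
    fit_gene_models,
    interaction_degs,
    moderate_statistics,
    pca_overview,
)
from coexmap.simulate import PlantedModule, SimulationConfig, simulate_study


def _study_with(values, design):
    expr = ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(len(values))],
            columns=design["sample_id"],
        )
    )
    traits = pd.DataFrame({"animal_id": design["animal_id"].unique()})
    return ExpressionStudy(expr, design.reset_index(drop=True), traits)


def _design_2x2():
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "animal_id": [f"a{i}" for i in range(8)],
            "sex": ["F"] * 4 + ["M"] * 4,
            "region": ["NAc"] * 8,
            "treatment": ["VEH", "VEH", "THC", "THC"] * 2,
        }
    )


class TestFitGeneModels:
    def test_noiseless_gene_recovers_exact_effect(self):
        design = _design_2x2()
        delta = 0.7
        thc = (design["treatment"] == "THC").to_numpy(float)
        values = [1.0 + delta * thc]
        fits = fit_gene_models(_study_with(values, design), "treatment")
        assert fits.coef["treatment"].iloc[0] == pytest.approx(delta)
        assert fits.sigma2[0] == pytest.approx(0.0, abs=1e-24)

    def test_pure_interaction_pattern_closed_form(self):
        # +1 only in THC males: with treatment-coded dummies the OLS solution
        # on the 4 cell means is interaction=1, all other coefficients 0
        design = _design_2x2()
        male = (design["sex"] == "M").to_numpy(float)
        thc = (design["treatment"] == "THC").to_numpy(float)
        values = [male * thc]
        fits = fit_gene_models(_study_with(values, design), "sex*treatment")
        assert fits.coef["sex:treatment"].iloc[0] == pytest.approx(1.0)
        assert fits.coef["sex"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert fits.coef["treatment"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert fits.coef["Intercept"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_sex_design_is_rank_deficient_for_interaction(self):
        design = _design_2x2()
        design["sex"] = "F"
        with pytest.raises(DesignError, match="aliased|rank"):
            fit_gene_models(_study_with([np.arange(8.0)], design),
                            "sex*treatment")


class TestModeration:
    def _fits(self, seed=0, n_genes=300):
        rng = np.random.default_rng(seed)
        design = _design_2x2()
        values = rng.normal(size=(n_genes, 8))
        return fit_gene_models(_study_with(values, design), "treatment")

    def test_infinite_prior_df_pins_posterior_at_prior_variance(self):
        fits = self._fits()
        prior = EmpiricalBayesParams(d0=np.inf, s0_sq=2.0)
        _, table = moderate_statistics(fits, "treatment", prior=prior)
        j = fits.design_columns.index("treatment")
        expected = fits.coef["treatment"].to_numpy() / (
            fits.se_unscaled[j] * np.sqrt(2.0)
        )
        np.testing.assert_allclose(table["t_mod"], expected, rtol=1e-12)

    def test_zero_prior_df_recovers_ordinary_t(self):
        fits = self._fits()
        prior = EmpiricalBayesParams(d0=0.0, s0_sq=5.0)
        _, table = moderate_statistics(fits, "treatment", prior=prior)
        j = fits.design_columns.index("treatment")
        ordinary = fits.coef["treatment"].to_numpy() / (
            fits.se_unscaled[j] * np.sqrt(fits.sigma2)
        )
        np.testing.assert_allclose(table["t_mod"], ordinary, rtol=1e-12)

    def test_all_zero_variances_rejected(self):
        design = _design_2x2()
        thc = (design["treatment"] == "THC").to_numpy(float)
        values = [i + thc for i in range(12)]
        fits = fit_gene_models(_study_with(values, design), "treatment")
        with pytest.raises(ValueError, match="zero"):
            estimate_prior(fits.sigma2, fits.df_resid)

    def test_null_p_values_are_uniform(self):
        # moderated p should be calibrated under the null
        ok = 0
        for seed in range(1, 11):
            config = SimulationConfig(
                seed=seed, n_genes=2000, regions=("A",), sexes=("F",),
                modules=[],
            )
            study, _ = simulate_study(config)
            table = deg_table(subset_by(study, "A", "F"))
            ok += stats.kstest(table["p"], "uniform").pvalue > 0.01
        assert ok >= 9


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=20,
        )
    )
    def test_matches_hand_step_up_oracle(self, p):
        # independent oracle: literal step-up definition
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 20))
            np.testing.assert_allclose(
                bh_fdr(p),
                multipletests(p, method="fdr_bh")[1],
                atol=1e-12,
            )


class TestCallDegs:
    @pytest.mark.parametrize(
        "fdr,logfc,expected",
        [
            (0.04, 0.5, True),
            (0.04, 0.39, False),
            (0.05, 1.0, False),  # strict FDR < 0.05
            (0.04, 0.4, True),  # |logFC| >= 0.4 inclusive
            (0.04, -0.5, True),
        ],
    )
    def test_dual_threshold_rule(self, fdr, logfc, expected):
        table = pd.DataFrame(
            {"gene_id": ["g"], "logFC": [logfc], "p": [fdr], "fdr": [fdr]}
        )
        assert call_degs(table)["is_deg"].iloc[0] == expected

    def test_calls_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(200)],
                "logFC": rng.normal(scale=1.0, size=200),
                "p": rng.uniform(size=200) ** 3,
            }
        )
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        n = lambda a, l: call_degs(table, alpha=a, lfc_min=l)["is_deg"].sum()
        assert n(0.01, 0.4) <= n(0.05, 0.4) <= n(0.1, 0.4)
        assert n(0.05, 0.8) <= n(0.05, 0.4) <= n(0.05, 0.1)


class TestInteractionDegs:
    def _study(self, seed, delta_int=0.0, delta_main=0.0, sigma=0.1):
        rng = np.random.default_rng(seed)
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(24)],
                "animal_id": [f"a{i}" for i in range(24)],
                "sex": ["F"] * 12 + ["M"] * 12,
                "region": ["Amy"] * 24,
                "treatment": (["VEH"] * 6 + ["THC"] * 6) * 2,
            }
        )
        male = (design["sex"] == "M").to_numpy(float)
        thc = (design["treatment"] == "THC").to_numpy(float)
        signal = delta_int * male * thc + delta_main * thc
        values = np.vstack(
            [signal + rng.normal(0, sigma, 24) for _ in range(60)]
        )
        return _study_with(values, design)

    def test_planted_interaction_detected(self):
        hits = 0
        for seed in range(30):
            table = interaction_degs(self._study(seed, delta_int=1.0))
            hits += bool(table["is_deg"].all())
        assert hits >= 27  # strong signal, sigma=0.1

    def test_main_effect_not_called_as_interaction(self):
        false_hits = 0
        for seed in range(30):
            table = interaction_degs(self._study(seed, delta_main=1.0))
            false_hits += bool(table["is_deg"].any())
        assert false_hits <= 4

    def test_single_treatment_is_rank_error(self):
        study = self._study(0)
        study.design["treatment"] = "VEH"
        with pytest.raises(DesignError):
            interaction_degs(study)


class TestPcaOverview:
    def test_region_shift_dominates_first_component(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(300, 20))
        values[:100, 10:] += 3.0  # 100 genes shifted in half the samples
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(300)],
                         columns=[f"s{i}" for i in range(20)])
        )
        coords, loadings, top = pca_overview(expr, top_k=100)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:10].mean() > 0) != (pc1[10:].mean() > 0)
        shifted = {f"g{i}" for i in range(100)}
        assert len(shifted & set(top["PC1"])) >= 90

    def test_constant_expression_reports_no_components(self):
        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((5, 4)), index=list("abcde"),
                         columns=[f"s{i}" for i in range(4)])
        )
        coords, loadings, top = pca_overview(expr, top_k=5)
        assert coords.shape[1] == 0 and top == {}

    def test_top_k_larger_than_genes_rejected(self):
        expr = ExpressionMatrix(
            pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                         index=list("abcde"),
                         columns=[f"s{i}" for i in range(4)])
        )
        with pytest.raises(ValueError, match="top_k"):
            pca_overview(expr, top_k=50)
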