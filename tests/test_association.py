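"""Regression-layer checks: OLS against a normal-equation oracle, model
nesting, genetic-model selection, interaction and synergy contracts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from statin_pgx import association as assoc
from statin_pgx.genetics import GeneticModel
from statin_pgx.pipeline import build_analysis_table, replicate_estimates
from statin_pgx.synthetic_ehr import SimConfig, VariantSimSpec, simulate_analysis_table


def _random_design(n=200, p=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p + 1)
    y = beta[0] + X @ beta[1:] + rng.normal(size=n)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["y"] = y
    return df


class TestOLS:
    @pytest.mark.parametrize("p,seed", [(1, 0), (4, 1), (10, 2)])
    def test_matches_normal_equation_oracle(self, p, seed):
        df = _random_design(p=p, seed=seed)
        covs = tuple(f"x{i}" for i in range(p))
        res = assoc.fit_linear_model(df, assoc.ModelSpec("y", covariates=covs))
        X = np.column_stack([np.ones(len(df))] + [df[c] for c in covs])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        fitted = np.array([res.terms["const"].estimate]
                          + [res.terms[c].estimate for c in covs])
        np.testing.assert_allclose(fitted, beta_oracle, atol=1e-10)

    def test_noiseless_line_recovered_exactly(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 3.0 + 2.0 * df["x"]
        res = assoc.fit_linear_model(df, assoc.ModelSpec("y", covariates=("x",)))
        assert res.terms["const"].estimate == pytest.approx(3.0)
        assert res.terms["x"].estimate == pytest.approx(2.0)
        assert res.terms["x"].se == pytest.approx(0.0, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        df = _random_design(p=3, seed=5)
        spec = assoc.ModelSpec("y", covariates=("x0", "x1", "x2"))
        a = assoc.fit_linear_model(df, spec)
        b = assoc.fit_linear_model(df.sample(frac=1, random_state=7), spec)
        for term in a.terms:
            assert a.terms[term].estimate == pytest.approx(b.terms[term].estimate, rel=1e-12)

    def test_complete_case_drops_only_rows_with_missing_terms(self):
        df = _random_design(p=2, seed=3)
        df.loc[:9, "x0"] = np.nan
        res = assoc.fit_linear_model(df, assoc.ModelSpec("y", covariates=("x0", "x1")))
        assert res.n == len(df) - 10

    def test_singular_design_names_collinear_terms(self):
        df = _random_design(p=2, seed=4)
        df["x_dup"] = df["x0"]
        with pytest.raises(assoc.SingularDesignError, match="x"):
            assoc.fit_linear_model(df, assoc.ModelSpec("y", covariates=("x0", "x1", "x_dup")))

    def test_ci_uses_t_quantile(self):
        from scipy import stats

        df = _random_design(p=2, seed=6)
        res = assoc.fit_linear_model(df, assoc.ModelSpec("y", covariates=("x0", "x1")))
        t = res.terms["x0"]
        half = stats.t.ppf(0.975, res.df_resid) * t.se
        assert t.ci_low == pytest.approx(t.estimate - half)
        assert t.ci_high == pytest.approx(t.estimate + half)


class TestCovariateNesting:
    def test_model3_never_increases_rss(self, default_cohort, default_phenotypes):
        from statin_pgx.io import load_variant_metadata

        table = build_analysis_table(default_phenotypes, default_cohort.genotypes,
                                     load_variant_metadata())
        data, col = assoc.add_encoding_column(table, "rs1045642", "recessive")
        rss = {}
        for m in (1, 2, 3):
            spec = assoc.ModelSpec.for_model(m, genetic_term=col)
            res = assoc.fit_linear_model(data, spec)
            rss[m] = res.resid_sd ** 2 * res.df_resid
        assert rss[2] <= rss[1] + 1e-9
        assert rss[3] <= rss[2] + 1e-9

    def test_covariate_sets_are_nested(self):
        m1 = set(assoc.ModelSpec.for_model(1).covariates)
        m2 = set(assoc.ModelSpec.for_model(2).covariates)
        m3 = set(assoc.ModelSpec.for_model(3).covariates)
        assert m1 < m2 < m3


class TestGeneticModelSelection:
    def test_injected_recessive_effect_is_usually_selected(self):
        cfg = SimConfig(n_patients=5000, seed=0, adherence_effect=0.0,
                        variant_specs=[VariantSimSpec("rs1045642", 0.48, "recessive", 0.09)],
                        interaction_effect_mmol_per_l=0.0)
        wins = 0
        n_reps = 30
        for seed in range(n_reps):
            tbl, _ = simulate_analysis_table(
                replace(cfg, seed=seed + 1000))
            sel = assoc.select_genetic_model(tbl, "rs1045642")
            wins += sel.chosen is GeneticModel.RECESSIVE
        assert wins / n_reps >= 0.7

    def test_literature_prior_overrides_data(self):
        tbl, _ = simulate_analysis_table(SimConfig(n_patients=500, seed=3))
        sel = assoc.select_genetic_model(tbl, "rs1045642", prior="dominant")
        assert sel.chosen is GeneticModel.DOMINANT
        assert sel.overridden
        assert set(sel.results) == set(GeneticModel)


class TestInteraction:
    def test_monomorphic_variant_gives_singularity_error(self):
        tbl, _ = simulate_analysis_table(SimConfig(n_patients=300, seed=1))
        data, col_a = assoc.add_encoding_column(tbl, "rs1045642", "recessive")
        data["mono"] = 1.0
        with pytest.raises(assoc.SingularDesignError):
            assoc.interaction_test(data, col_a, "mono")

    def test_injected_interaction_is_detected(self):
        # strong two-locus bonus: the product term should reject far above 5%
        cfg = SimConfig(
            n_patients=8000, seed=0, adherence_effect=0.0,
            variant_specs=[VariantSimSpec("rs1045642", 0.48, "recessive", 0.09),
                           VariantSimSpec("rs12975366", 0.40, "dominant", 0.04)],
            interaction_effect_mmol_per_l=0.10)
        rejections = 0
        n_reps = 20
        for seed in range(n_reps):
            tbl, _ = simulate_analysis_table(
                replace(cfg, seed=2000 + seed))
            data, col_a = assoc.add_encoding_column(tbl, "rs1045642", "recessive")
            data, col_b = assoc.add_encoding_column(data, "rs12975366", "dominant")
            term, _ = assoc.interaction_test(data, col_a, col_b)
            rejections += term.p_value < 0.05
        # analytic power at this design is ~0.4, an order of magnitude
        # above the 5% null rate
        assert rejections / n_reps > 0.2


class TestSynergy:
    def test_expected_additive_is_the_sum(self):
        assert assoc.expected_additive(0.45, 0.5) == pytest.approx(0.95)
        assert assoc.expected_additive(0.44, 0.79) == pytest.approx(1.23)

    def test_zero_excess_for_an_algebraically_additive_fixture(self):
        # balanced orthogonal two-locus design, noiseless additive outcome:
        # the score contrast must equal the sum of the single-variant effects
        cells = [(a, b) for a in (0, 1) for b in (0, 1)]
        rows = []
        for a, b in cells:
            for _ in range(10):
                rows.append({"rs1045642_count": 2 * a, "rs12975366_count": b,
                             "y": 0.09 * a + 0.04 * b})
        df = pd.DataFrame(rows)
        data, col_a = assoc.add_encoding_column(df, "rs1045642", "recessive")
        data, col_b = assoc.add_encoding_column(data, "rs12975366", "dominant")
        data, score = assoc.add_risk_score_column(data)
        res = assoc.synergy(data, col_a, col_b, score, outcome="y")
        assert res.expected_additive == pytest.approx(0.13)
        assert res.synergy_excess == pytest.approx(0.0, abs=1e-10)
        assert res.combined - res.expected_additive == res.synergy_excess


class TestThresholdAndSubsets:
    def test_bonferroni_over_21_tests(self):
        exact, reported = assoc.multiple_testing_threshold(7, 3)
        assert exact == pytest.approx(0.05 / 21)
        assert reported == 0.002

    def test_single_test_threshold_is_alpha(self):
        assert assoc.multiple_testing_threshold(1, 1) == (0.05, 0.05)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            assoc.multiple_testing_threshold(0, 3)

    def test_statin_subset_fraction_matches_generator_mix(self):
        tbl, _ = simulate_analysis_table(SimConfig(n_patients=20000, seed=5))
        sub = assoc.statin_subset(tbl, ["simvastatin", "atorvastatin"])
        frac = len(sub) / len(tbl)
        se = np.sqrt(0.941 * 0.059 / 20000)
        assert frac == pytest.approx(0.941, abs=3 * se)

    def test_subset_edge_cases(self):
        tbl, _ = simulate_analysis_table(SimConfig(n_patients=100, seed=6))
        assert assoc.statin_subset(tbl, []).empty
        assert len(assoc.statin_subset(tbl, set(tbl["first_statin_type"]))) == len(tbl)
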