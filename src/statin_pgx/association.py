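"""Regression models for genotype effects on statin response.

Three nested covariate sets mirror the staged adjustment strategy:

* Model 1 — univariate: outcome on the genetic term alone.
* Model 2 — adds the statin-intolerance features: PDC adherence
  surrogate, statin switching, dose reduction.
* Model 3 — adds mean simvastatin-equivalent dose, therapy duration in
  28-day periods, type-2 diabetes, prior MACE, and baseline non-HDL-C.

Fits are ordinary least squares (statsmodels) with complete-case
handling per model and t-based 95% confidence intervals. On top of the
single-variant fits sit the genetic-model selection (additive vs
dominant vs recessive by smallest p, overridable by a literature
prior), the two-locus interaction test, and the synergy contrast of the
combined two-SNP risk-score effect against the sum of the single-variant
effects (the expected additive effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genetics import GeneticModel, encode_counts, protective_indicator, risk_score_levels

MODEL2_COVARIATES = ("pdc", "switched", "dose_reduced")
MODEL3_COVARIATES = MODEL2_COVARIATES + (
    "mean_dose", "duration_periods", "t2d", "prior_mace", "baseline_nonhdl")

OUTCOMES = ("absolute_reduction", "percent_reduction")


class SingularDesignError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class ModelSpec:
    """One regression to fit: outcome, optional genetic term, covariates,
    optional product interaction terms (pairs of column names)."""

    outcome: str = "absolute_reduction"
    genetic_term: str | None = None
    covariates: tuple[str, ...] = ()
    interaction_terms: tuple[tuple[str, str], ...] = ()

    @classmethod
    def for_model(cls, model: int, outcome: str = "absolute_reduction",
                  genetic_term: str | None = None,
                  include_dose_increase: bool = False) -> "ModelSpec":
        """Build the spec for adjustment stage 1, 2 or 3."""
        if model == 1:
            cov: tuple[str, ...] = ()
        elif model == 2:
            cov = MODEL2_COVARIATES
        elif model == 3:
            cov = MODEL3_COVARIATES
        else:
            raise ValueError(f"model must be 1, 2 or 3, got {model}")
        if include_dose_increase and model >= 2:
            cov = cov + ("dose_increased",)
        return cls(outcome=outcome, genetic_term=genetic_term, covariates=cov)


@dataclass(frozen=True)
class TermEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class ModelResult:
    """Fitted OLS output: per-term estimates with t-based 95% CIs."""

    terms: Mapping[str, TermEstimate]
    n: int
    df_resid: float
    r_squared: float
    resid_sd: float
    outcome: str

    def __getitem__(self, term: str) -> TermEstimate:
        return self.terms[term]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": name, "estimate": t.estimate, "se": t.se,
                 "ci_low": t.ci_low, "ci_high": t.ci_high, "p_value": t.p_value}
                for name, t in self.terms.items()]
        frame = pd.DataFrame(rows)
        frame.attrs["n"] = self.n
        return frame


@dataclass(frozen=True)
class SynergyResult:
    """Observed combined two-variant effect against the expected additive one."""

    effect_a: float
    effect_b: float
    combined: float
    expected_additive: float
    synergy_excess: float
    scale: str
    model_a: ModelResult
    model_b: ModelResult
    model_combined: ModelResult


def _design_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    terms: list[str] = []
    if spec.genetic_term:
        terms.append(spec.genetic_term)
    terms.extend(spec.covariates)
    work = df.copy()
    for a, b in spec.interaction_terms:
        name = f"{a}:{b}"
        work[name] = work[a] * work[b]
        if a not in terms:
            terms.append(a)
        if b not in terms:
            terms.append(b)
        terms.append(name)
    missing = [c for c in [spec.outcome] + terms if c not in work.columns]
    if missing:
        raise KeyError(f"model terms absent from the table: {missing}")
    data = work[[spec.outcome] + terms].apply(pd.to_numeric).dropna()
    y = data[spec.outcome]
    X = sm.add_constant(data[terms].astype(float), has_constant="add")
    return y, X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR puts the redundant columns last
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(arr, mode="economic", pivoting=True)
        dropped = [str(X.columns[piv[i]]) for i in range(rank, arr.shape[1])]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear terms: {dropped}")


def fit_linear_model(df: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the specified OLS model on complete cases.

    Rows with any missing outcome/term are dropped for this model only
    (pairwise across models). Raises SingularDesignError for
    rank-deficient designs, naming the collinear terms. Requires more
    rows than parameters.
    """
    y, X = _design_matrix(df, spec)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} parameters")
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    conf = fit.conf_int(alpha=0.05)
    terms = {
        name: TermEstimate(
            estimate=float(fit.params[name]), se=float(fit.bse[name]),
            ci_low=float(conf.loc[name, 0]), ci_high=float(conf.loc[name, 1]),
            p_value=float(fit.pvalues[name]))
        for name in X.columns
    }
    return ModelResult(terms=terms, n=int(fit.nobs), df_resid=float(fit.df_resid),
                       r_squared=float(fit.rsquared),
                       resid_sd=float(np.sqrt(fit.mse_resid)), outcome=spec.outcome)


def add_encoding_column(df: pd.DataFrame, rsid: str,
                        model: GeneticModel | str) -> tuple[pd.DataFrame, str]:
    """Derive `<rsid>_<model>` from the protective-allele count column."""
    model = GeneticModel(model)
    col = f"{rsid}_{model.value}"
    out = df.copy()
    out[col] = encode_counts(out[f"{rsid}_count"], model)
    return out, col


@dataclass(frozen=True)
class ModelSelection:
    rsid: str
    chosen: GeneticModel
    overridden: bool
    results: Mapping[GeneticModel, ModelResult]


def select_genetic_model(df: pd.DataFrame, rsid: str,
                         outcome: str = "absolute_reduction",
                         covariates: Sequence[str] = (),
                         prior: GeneticModel | str | None = None) -> ModelSelection:
    """Fit the variant under all three encodings and pick one.

    Default choice is the encoding with the smallest genotype p-value;
    a literature `prior` (the packaged metadata pins ABCB1 recessive and
    LILRB5 dominant) overrides the data-driven pick while the per-model
    results remain reported.
    """
    results: dict[GeneticModel, ModelResult] = {}
    for model in GeneticModel:
        data, col = add_encoding_column(df, rsid, model)
        spec = ModelSpec(outcome=outcome, genetic_term=col, covariates=tuple(covariates))
        try:
            results[model] = fit_linear_model(data, spec)
        except SingularDesignError:
            continue  # e.g. no homozygous carriers for a rare recessive coding
    if prior is not None:
        prior = GeneticModel(prior)
        if prior not in results:
            raise SingularDesignError(
                f"{rsid}: pinned {prior.value} encoding is degenerate in this cohort")
        return ModelSelection(rsid, prior, True, results)
    if not results:
        raise SingularDesignError(f"{rsid}: no genetic encoding is estimable")
    chosen = min(results, key=lambda m: results[m].terms[f"{rsid}_{m.value}"].p_value)
    return ModelSelection(rsid, chosen, False, results)


def interaction_test(df: pd.DataFrame, term_a: str, term_b: str,
                     covariates: Sequence[str] = (),
                     outcome: str = "absolute_reduction") -> tuple[TermEstimate, ModelResult]:
    """Product-term test of two encoded variants, adjusted for both main
    effects (and any further covariates). Returns the product-term
    estimate plus the full model."""
    spec = ModelSpec(outcome=outcome, covariates=tuple(covariates),
                     interaction_terms=((term_a, term_b),))
    result = fit_linear_model(df, spec)
    return result.terms[f"{term_a}:{term_b}"], result


def expected_additive(effect_a: float, effect_b: float) -> float:
    """The purely additive prediction for the joint effect of two variants."""
    return effect_a + effect_b


def synergy(df: pd.DataFrame, variant_a_term: str, variant_b_term: str,
            score_term: str, outcome: str = "percent_reduction",
            covariates: Sequence[str] = ()) -> SynergyResult:
    """Observed-vs-expected-additive synergy of the two-variant score.

    Fits three models under identical outcome and covariates: one per
    single variant and one for the combined risk-score contrast. The
    expected additive effect is the sum of the single-variant estimates;
    the synergy excess is the combined estimate minus that sum.
    """
    res_a = fit_linear_model(df, ModelSpec(outcome, variant_a_term, tuple(covariates)))
    res_b = fit_linear_model(df, ModelSpec(outcome, variant_b_term, tuple(covariates)))
    res_c = fit_linear_model(df, ModelSpec(outcome, score_term, tuple(covariates)))
    ea = res_a.terms[variant_a_term].estimate
    eb = res_b.terms[variant_b_term].estimate
    combined = res_c.terms[score_term].estimate
    expected = expected_additive(ea, eb)
    return SynergyResult(effect_a=ea, effect_b=eb, combined=combined,
                         expected_additive=expected,
                         synergy_excess=combined - expected,
                         scale="%" if outcome == "percent_reduction" else "mmol/L",
                         model_a=res_a, model_b=res_b, model_combined=res_c)


def add_risk_score_column(df: pd.DataFrame, abcb1_rsid: str = "rs1045642",
                          lilrb5_rsid: str = "rs12975366",
                          mode: str = "strict") -> tuple[pd.DataFrame, str]:
    """Attach the two-SNP score's protected-group indicator (1 = level 0,
    0 = level 1, NaN = intermediate/missing) as `risk_score_protected`."""
    levels = risk_score_levels(df[f"{abcb1_rsid}_count"], df[f"{lilrb5_rsid}_count"], mode=mode)
    out = df.copy()
    out["risk_score_level"] = levels
    out["risk_score_protected"] = protective_indicator(levels)
    return out, "risk_score_protected"


def multiple_testing_threshold(n_snps: int, n_models: int,
                               alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni threshold over n_snps x n_models tests.

    Returns (exact, reported) where `reported` is rounded to three
    decimals — the convention under which 0.05/21 is declared as 0.002.
    """
    if n_snps <= 0 or n_models <= 0:
        raise ValueError("n_snps and n_models must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    exact = alpha / (n_snps * n_models)
    return exact, round(exact, 3)


def statin_subset(pheno: pd.DataFrame, allowed: Iterable[str]) -> pd.DataFrame:
    """Rows whose first prescribed statin is in `allowed` (e.g. the
    simvastatin+atorvastatin restriction)."""
    allowed = set(allowed)
    return pheno[pheno["first_statin_type"].isin(allowed)].copy()
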