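"""End-to-end orchestration: simulate/load -> phenotype -> genotype QC ->
association models -> synergy -> power, with an attrition report, a run
log, and a replicate mode for parameter-recovery studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, genetics, phenotyping, power
from .io import (load_equivalence_table, load_variant_metadata, read_demographics,
                 read_genotypes_csv, read_labs, read_prescriptions, write_cohort_csvs)
from .synthetic_ehr import SimConfig, SyntheticCohort, simulate_analysis_table, simulate_cohort


@dataclass(frozen=True)
class RunConfig:
    """One reproducible analysis run.

    Provide either the four input table paths or a SimConfig for
    self-generation (not neither). `risk_score_mode` picks how
    discordant two-locus genotypes enter the score ("strict" drops
    them; "complement" counts them as non-protected).
    """

    out_dir: str | Path
    sim: SimConfig | None = None
    prescriptions_path: str | Path | None = None
    labs_path: str | Path | None = None
    demographics_path: str | Path | None = None
    genotypes_path: str | Path | None = None
    variants_path: str | Path | None = None
    equivalence_path: str | Path | None = None
    models: tuple[int, ...] = (1, 2, 3)
    outcomes: tuple[str, ...] = ("absolute_reduction", "percent_reduction")
    subsets: tuple[tuple[str, ...], ...] = (("simvastatin", "atorvastatin"),)
    risk_score_mode: str = "strict"
    use_literature_prior: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        paths = (self.prescriptions_path, self.labs_path,
                 self.demographics_path, self.genotypes_path)
        if self.sim is None and any(p is None for p in paths):
            raise ValueError("provide either a SimConfig or all four input table paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "sim" in raw:
            sim_raw = dict(raw.pop("sim"))
            specs = sim_raw.pop("variant_specs", None)
            if specs is not None:
                from .synthetic_ehr import VariantSimSpec

                sim_raw["variant_specs"] = [VariantSimSpec(**s) for s in specs]
            sim = SimConfig(**sim_raw)
        for key in ("models", "outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "subsets" in raw:
            raw["subsets"] = tuple(tuple(s) for s in raw["subsets"])
        return cls(sim=sim, **raw)


@dataclass
class AttritionReport:
    """Cohort attrition counts through the exclusion cascade."""

    n_prescribed: int
    n_with_baseline: int
    n_with_followup: int
    n_analysis: int
    n_genotyped: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        seq = [self.n_prescribed, self.n_with_baseline, self.n_with_followup, self.n_analysis]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"attrition counts must be non-increasing, got {seq}")

    def to_dict(self) -> dict:
        return {"n_prescribed": self.n_prescribed,
                "n_with_baseline": self.n_with_baseline,
                "n_with_followup": self.n_with_followup,
                "n_analysis": self.n_analysis,
                "n_genotyped": dict(self.n_genotyped)}


@dataclass
class RunResult:
    phenotypes: pd.DataFrame
    analysis_table: pd.DataFrame
    qc: pd.DataFrame
    model_results: pd.DataFrame
    synergy_reports: list[dict]
    attrition: AttritionReport
    log: list[str]
    out_dir: Path


def compute_attrition(prescriptions: pd.DataFrame, labs: pd.DataFrame,
                      pheno: pd.DataFrame, genotypes: pd.DataFrame,
                      window: tuple[int, int] = phenotyping.FOLLOWUP_WINDOW) -> AttritionReport:
    """Count patients surviving each exclusion step."""
    rx = prescriptions.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    init = rx.groupby("patient_id")["dispense_date"].min().rename("initiation_date")
    labs_p = phenotyping._prepare_labs(labs).merge(init, on="patient_id")
    offset = (labs_p["date"] - labs_p["initiation_date"]).dt.days
    has_pre = set(labs_p.loc[offset <= 0, "patient_id"])
    has_fup = set(labs_p.loc[(offset >= window[0]) & (offset <= window[1]), "patient_id"])
    report = AttritionReport(
        n_prescribed=int(rx["patient_id"].nunique()),
        n_with_baseline=len(has_pre),
        n_with_followup=len(has_pre & has_fup),
        n_analysis=int(len(pheno)),
    )
    called = genotypes.dropna(subset=["allele1", "allele2"])
    in_pheno = called[called["patient_id"].isin(pheno["patient_id"])]
    report.n_genotyped = in_pheno.groupby("rsid")["patient_id"].nunique().to_dict()
    report.validate()
    return report


def build_analysis_table(pheno: pd.DataFrame, genotypes: pd.DataFrame,
                         variants: Sequence[genetics.VariantInfo]) -> pd.DataFrame:
    """Phenotype rows joined with per-variant protective-allele counts."""
    counts = genetics.genotypes_to_counts(genotypes, variants)
    return pheno.merge(counts, on="patient_id", how="left")


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write results under `config.out_dir`."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    variants = load_variant_metadata(config.variants_path)
    equivalence = load_equivalence_table(config.equivalence_path)

    if config.sim is not None:
        cohort = simulate_cohort(config.sim)
        write_cohort_csvs(cohort, out / "inputs")
        prescriptions, labs = cohort.prescriptions, cohort.labs
        demographics, genotypes = cohort.demographics, cohort.genotypes
        log.append(f"simulated cohort: n={config.sim.n_patients} seed={config.sim.seed}")
    else:
        prescriptions = read_prescriptions(config.prescriptions_path)
        labs = read_labs(config.labs_path)
        demographics = read_demographics(config.demographics_path)
        genotypes = read_genotypes_csv(config.genotypes_path)
        log.append("loaded input tables from disk")

    pheno = phenotyping.derive_phenotypes(prescriptions, labs, demographics,
                                          equivalence_table=equivalence)
    if pheno.empty:
        raise ValueError("no patients survive the baseline/follow-up filters")
    attrition = compute_attrition(prescriptions, labs, pheno, genotypes)
    log.append(f"analysis cohort: {len(pheno)} patients")

    qc = genetics.genotype_qc_table(genotypes, variants)
    table = build_analysis_table(pheno, genotypes, variants)

    rows = []
    encodings: dict[str, genetics.GeneticModel] = {}
    for v in variants:
        prior = v.genetic_model if config.use_literature_prior else None
        try:
            selection = association.select_genetic_model(table, v.rsid, prior=prior)
        except association.SingularDesignError:
            log.append(f"{v.rsid}: skipped (degenerate genotype distribution)")
            continue
        encodings[v.rsid] = selection.chosen
        log.append(f"{v.rsid}: encoding={selection.chosen.value}"
                   f" ({'literature prior' if selection.overridden else 'min p'})")
        data, col = association.add_encoding_column(table, v.rsid, selection.chosen)
        for outcome in config.outcomes:
            for m in config.models:
                spec = association.ModelSpec.for_model(m, outcome=outcome, genetic_term=col)
                try:
                    res = association.fit_linear_model(data, spec)
                except association.SingularDesignError:
                    log.append(f"{v.rsid}: model {m} ({outcome}) skipped (singular design)")
                    continue
                for term, est in res.terms.items():
                    rows.append({"analysis": f"{v.rsid}", "subset": "all",
                                 "outcome": outcome, "model": m, "term": term,
                                 "estimate": est.estimate, "se": est.se,
                                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                                 "p_value": est.p_value, "n": res.n})

    n_tests = len(variants) * len(genetics.GeneticModel)
    threshold_exact, threshold_reported = association.multiple_testing_threshold(
        len(variants), len(genetics.GeneticModel))
    log.append(f"multiple-testing threshold over {n_tests} tests:"
               f" {threshold_exact:.5f} (reported {threshold_reported})")

    table, score_col = association.add_risk_score_column(table, mode=config.risk_score_mode)
    log.append(f"risk-score mode: {config.risk_score_mode}"
               f" ({int(table[score_col].notna().sum())} patients assigned a level)")

    subset_tables = {"all": table}
    for allowed in config.subsets:
        subset_tables["+".join(allowed)] = association.statin_subset(table, allowed)

    synergy_reports = []
    for name, sub in subset_tables.items():
        for outcome in config.outcomes:
            for m in config.models:
                spec = association.ModelSpec.for_model(m, outcome=outcome,
                                                       genetic_term=score_col)
                res = association.fit_linear_model(sub, spec)
                for term, est in res.terms.items():
                    rows.append({"analysis": "two_snp_score", "subset": name,
                                 "outcome": outcome, "model": m, "term": term,
                                 "estimate": est.estimate, "se": est.se,
                                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                                 "p_value": est.p_value, "n": res.n})
        # synergy on both scales under the fully adjusted covariates
        data_a, col_a = association.add_encoding_column(sub, "rs1045642", encodings["rs1045642"])
        data_ab, col_b = association.add_encoding_column(data_a, "rs12975366",
                                                         encodings["rs12975366"])
        for outcome in config.outcomes:
            syn = association.synergy(data_ab, col_a, col_b, score_col, outcome=outcome,
                                      covariates=association.MODEL3_COVARIATES)
            synergy_reports.append({
                "subset": name, "outcome": outcome, "scale": syn.scale,
                "effect_abcb1": syn.effect_a, "effect_lilrb5": syn.effect_b,
                "combined": syn.combined, "expected_additive": syn.expected_additive,
                "synergy_excess": syn.synergy_excess,
                "n_combined": syn.model_combined.n,
            })

    inter_data, col_a = association.add_encoding_column(table, "rs1045642", encodings["rs1045642"])
    inter_data, col_b = association.add_encoding_column(inter_data, "rs12975366",
                                                       encodings["rs12975366"])
    inter_term, inter_model = association.interaction_test(inter_data, col_a, col_b)
    log.append(f"ABCB1 x LILRB5 interaction: beta={inter_term.estimate:.4f}"
               f" p={inter_term.p_value:.4g} (n={inter_model.n})")

    sd = float(pheno["absolute_reduction"].std())
    power_rows = []
    for v in variants:
        if v.rsid not in encodings:
            continue
        model = encodings[v.rsid].value
        if model == "additive":
            model = "dominant"  # MDD needs a two-group contrast
        q = power.PowerQuery(total_n=len(pheno), maf=v.maf or 0.5,
                             genetic_model=model, outcome_sd=sd)
        try:
            mdd = power.minimum_detectable_difference(q)
        except power.InfeasibleGroupError:
            mdd = float("nan")
        power_rows.append({"rsid": v.rsid, "maf": v.maf, "genetic_model": model,
                           "outcome_sd": sd, "mdd_mmol_per_l": mdd})

    model_results = pd.DataFrame(rows)
    results_dir = out
    pheno_out = pheno.copy()
    pheno_out["initiation_date"] = pd.to_datetime(pheno_out["initiation_date"]).dt.strftime("%Y-%m-%d")
    pheno_out.to_csv(results_dir / "phenotypes.csv", index=False)
    qc.to_csv(results_dir / "genotype_qc.csv", index=False)
    model_results.to_csv(results_dir / "model_results.csv", index=False)
    pd.DataFrame(power_rows).to_csv(results_dir / "power.csv", index=False)
    (results_dir / "synergy.json").write_text(json.dumps(synergy_reports, indent=2))
    (results_dir / "attrition.json").write_text(json.dumps(attrition.to_dict(), indent=2))

    manifest = {
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "seed": config.seed,
        "versions": _versions(),
        "threshold_exact": threshold_exact,
        "threshold_reported": threshold_reported,
    }
    (results_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (results_dir / "run.log").write_text("\n".join(log) + "\n")

    return RunResult(phenotypes=pheno, analysis_table=table, qc=qc,
                     model_results=model_results, synergy_reports=synergy_reports,
                     attrition=attrition, log=log, out_dir=results_dir)


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {"statin_pgx": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}


def replicate_seeds(base_seed: int, n_replicates: int) -> np.ndarray:
    """Independent child seeds (< 2**31) derived from one base seed."""
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2 ** 31 - 1, size=n_replicates)


def replicate_estimates(config: SimConfig, n_replicates: int, base_seed: int,
                        estimator: Callable[[pd.DataFrame], float],
                        events: bool = False) -> np.ndarray:
    """Replicate mode: regenerate the cohort `n_replicates` times under
    fresh seeds and apply `estimator` to each analysis table.

    With ``events=False`` (default) the outcome model is sampled
    directly (`simulate_analysis_table`); with ``events=True`` the full
    event streams are generated and pushed through the phenotyping
    stage before estimation.
    """
    out = np.empty(n_replicates)
    for i, s in enumerate(replicate_seeds(base_seed, n_replicates)):
        cfg = replace(config, seed=int(s))
        if events:
            cohort = simulate_cohort(cfg)
            pheno = phenotyping.derive_phenotypes(cohort.prescriptions, cohort.labs,
                                                  cohort.demographics)
            variants = [v for v in load_variant_metadata()
                        if v.rsid in {s_.rsid for s_ in cfg.variant_specs}]
            table = build_analysis_table(pheno, cohort.genotypes, variants)
        else:
            table, _ = simulate_analysis_table(cfg)
        out[i] = estimator(table)
    return out


def univariate_effect_estimator(rsid: str, model: genetics.GeneticModel | str,
                                outcome: str = "absolute_reduction") -> Callable[[pd.DataFrame], float]:
    """Estimator factory: the univariate OLS genotype coefficient for one
    variant under a fixed encoding."""

    def estimate(table: pd.DataFrame) -> float:
        data, col = association.add_encoding_column(table, rsid, model)
        res = association.fit_linear_model(
            data, association.ModelSpec(outcome=outcome, genetic_term=col))
        return res.terms[col].estimate

    return estimate


def score_contrast_estimator(outcome: str = "absolute_reduction",
                             mode: str = "strict") -> Callable[[pd.DataFrame], float]:
    """Estimator factory: the univariate protected-vs-risk two-SNP score
    contrast."""

    def estimate(table: pd.DataFrame) -> float:
        data, col = association.add_risk_score_column(table, mode=mode)
        res = association.fit_linear_model(
            data, association.ModelSpec(outcome=outcome, genetic_term=col))
        return res.terms[col].estimate

    return estimate
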