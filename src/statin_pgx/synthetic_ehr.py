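"""Synthetic statin-cohort generator.

Emulates the statistical structure of a longitudinal prescribing +
laboratory + genotype extract for statin initiators, so the phenotyping,
genetics, association and power stages can be exercised and validated
without access to any real records:

* genotypes in Hardy-Weinberg proportions at configurable allele
  frequencies for the seven-variant ADR panel;
* baseline non-HDL-C ~ N(4.43, 1.19^2) mmol/L and an absolute on-treatment
  reduction with SD 1.04 mmol/L around a configurable mean (1.45);
* genotype effects of configurable size injected on the absolute
  reduction scale under a chosen genetic model, plus an optional
  two-locus interaction bonus when both named variants carry their
  protective encoding;
* adherence (latent PDC, truncated-normal mean 1.54 / SD 0.79), statin
  switching, dose changes, and 28-day dispensing cadence arranged so the
  PDC recomputed from the emitted prescriptions tracks the latent value;
* lab dates compatible with the 28-180-day follow-up window (median
  follow-up ~75 days; median baseline ~12 days before initiation).

A `truth` table of latent values is kept alongside the four analysis
tables strictly for test assertions; the analysis modules never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import GeneticModel, encode_counts
from .io import load_equivalence_table, load_variant_metadata

_EPOCH_START = pd.Timestamp("2005-01-01")
_EPOCH_DAYS = 4017  # initiations drawn uniformly over 2005-2015

#: starting-strength menus (mg) and probabilities per statin
_STRENGTH_MENU: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "simvastatin": ((10, 20, 40, 80), (0.15, 0.52, 0.28, 0.05)),
    "atorvastatin": ((10, 20, 40, 80), (0.30, 0.40, 0.20, 0.10)),
    "rosuvastatin": ((5, 10, 20, 40), (0.30, 0.40, 0.20, 0.10)),
    "pravastatin": ((10, 20, 40), (0.20, 0.40, 0.40)),
    "fluvastatin": ((20, 40, 80), (0.30, 0.40, 0.30)),
}

_MINOR_FLOOR = 0.05  # follow-up labs are floored here to keep lipids physical


@dataclass(frozen=True)
class VariantSimSpec:
    """One simulated variant: frequency, genetic model, and the injected
    effect (mmol/L extra absolute reduction per unit of the protective
    encoding)."""

    rsid: str
    maf: float
    genetic_model: GeneticModel | str = GeneticModel.ADDITIVE
    effect_mmol_per_l: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError(f"{self.rsid}: maf must lie in (0, 1), got {self.maf}")
        object.__setattr__(self, "genetic_model", GeneticModel(self.genetic_model))


def default_variant_specs() -> list[VariantSimSpec]:
    """The packaged seven-variant panel at its reference frequencies, with
    the two study-positive effects injected (ABCB1 rs1045642 recessive
    0.09 mmol/L; LILRB5 rs12975366 dominant 0.04 mmol/L) and the five
    null variants at zero."""
    effects = {"rs1045642": 0.09, "rs12975366": 0.04}
    return [VariantSimSpec(v.rsid, v.maf, v.genetic_model, effects.get(v.rsid, 0.0))
            for v in load_variant_metadata()]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    Distributional defaults follow the study population: baseline
    non-HDL-C 4.43 (SD 1.19) mmol/L, absolute reduction 1.45 (SD 1.04)
    mmol/L, adherence 1.54 (SD 0.79), statin mix 74.7% simvastatin /
    19.4% atorvastatin / 5.9% other, 3% switchers, 71.4% type-2
    diabetes, 18.6% prior MACE. The interaction bonus applies when both
    `interaction_variants` carry their protective encoding; its default
    0.01 mmol/L makes the joint protected-vs-risk contrast 0.14 mmol/L
    on top of the 0.09 + 0.04 single-variant effects.
    """

    n_patients: int
    seed: int = 0
    variant_specs: Sequence[VariantSimSpec] = field(default_factory=default_variant_specs)
    interaction_variants: tuple[str, str] = ("rs1045642", "rs12975366")
    interaction_effect_mmol_per_l: float = 0.01
    baseline_mean: float = 4.43
    baseline_sd: float = 1.19
    reduction_mean: float = 1.45
    reduction_sd: float = 1.04
    adherence_mean: float = 1.54
    adherence_sd: float = 0.79
    adherence_effect: float = 0.26
    switch_prob: float = 0.03
    dose_reduction_prob: float = 0.49
    dose_increase_prob: float = 0.62
    statin_mix: Mapping[str, float] = field(default_factory=lambda: {
        "simvastatin": 0.747, "atorvastatin": 0.194, "other": 0.059})
    t2d_prev: float = 0.714
    mace_prev: float = 0.186
    t2d_effect: float = -0.13
    mace_effect: float = -0.04
    baseline_effect: float = 0.0
    female_prev: float = 0.453
    age_mean: float = 63.06
    age_sd: float = 10.97
    followup_day_range: tuple[int, int] = (28, 180)
    followup_median_days: float = 75.0
    followup_log_sd: float = 0.60
    baseline_median_days: float = 12.0
    baseline_log_sd: float = 1.587
    genotype_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name in ("baseline_sd", "reduction_sd", "adherence_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        probs = {"switch_prob": self.switch_prob,
                 "dose_reduction_prob": self.dose_reduction_prob,
                 "dose_increase_prob": self.dose_increase_prob,
                 "t2d_prev": self.t2d_prev, "mace_prev": self.mace_prev,
                 "female_prev": self.female_prev,
                 "genotype_missing_rate": self.genotype_missing_rate}
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        mix_total = sum(self.statin_mix.values())
        if not np.isclose(mix_total, 1.0):
            raise ValueError(f"statin_mix probabilities must sum to 1, got {mix_total}")
        lo, hi = self.followup_day_range
        if not 0 < lo < hi:
            raise ValueError("followup_day_range must be an increasing positive pair")
        rsids = [v.rsid for v in self.variant_specs]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsid in variant_specs")


@dataclass
class SyntheticCohort:
    """The four analysis input tables plus the latent truth.

    `truth` exists only so tests can compare recovered quantities with
    what was injected; analysis code must never consume it.
    """

    demographics: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    genotypes: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def genotype_frequencies_hwe(maf: float, n: int, seed: int) -> tuple[int, int, int]:
    """Multinomial genotype counts (hom-major, het, hom-minor) under
    Hardy-Weinberg proportions ((1-maf)^2, 2 maf (1-maf), maf^2)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < maf < 1:
        raise ValueError(f"maf must lie strictly in (0, 1), got {maf}")
    rng = np.random.default_rng(seed)
    p, q = 1.0 - maf, maf
    counts = rng.multinomial(n, [p * p, 2 * p * q, q * q])
    return int(counts[0]), int(counts[1]), int(counts[2])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_days(rng: np.random.Generator, median: float, log_sd: float,
                    size: int, lo: int | None = None, hi: int | None = None) -> np.ndarray:
    draws = rng.lognormal(np.log(median), log_sd, size)
    if lo is not None or hi is not None:
        lo_f = lo if lo is not None else 0.0
        hi_f = hi if hi is not None else np.inf
        bad = (draws < lo_f) | (draws > hi_f)
        while bad.any():  # rejection sampling keeps the in-window shape
            draws[bad] = rng.lognormal(np.log(median), log_sd, int(bad.sum()))
            bad = (draws < lo_f) | (draws > hi_f)
    return np.maximum(np.round(draws), 1).astype(int)


def _draw_latents(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    lat = pd.DataFrame({"patient_id": [f"P{i:07d}" for i in range(1, n + 1)]})
    lat["sex"] = np.where(rng.random(n) < config.female_prev, "F", "M")
    lat["age"] = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 25, 95)
    lat["t2d"] = (rng.random(n) < config.t2d_prev).astype(int)
    lat["prior_mace"] = (rng.random(n) < config.mace_prev).astype(int)

    genotype_effect = np.zeros(n)
    for v in config.variant_specs:
        counts = rng.binomial(2, v.maf, n).astype(float)
        lat[f"{v.rsid}_count"] = counts
        enc = encode_counts(counts, v.genetic_model).to_numpy()
        lat[f"{v.rsid}_enc"] = enc
        genotype_effect += v.effect_mmol_per_l * enc
    rs_a, rs_b = config.interaction_variants
    specs = {v.rsid for v in config.variant_specs}
    if config.interaction_effect_mmol_per_l != 0.0 and {rs_a, rs_b} <= specs:
        joint = (lat[f"{rs_a}_enc"].to_numpy() > 0) & (lat[f"{rs_b}_enc"].to_numpy() > 0)
        genotype_effect += config.interaction_effect_mmol_per_l * joint
        lat["joint_protective"] = joint.astype(int)
    lat["genotype_effect"] = genotype_effect

    lat["adherence"] = _truncated_normal(rng, config.adherence_mean, config.adherence_sd, 0.0, n)
    lat["baseline_nonhdl"] = _truncated_normal(rng, config.baseline_mean, config.baseline_sd, 0.5, n)

    noise = rng.normal(0.0, 1.0, n) * config.reduction_sd
    lat["reduction"] = (
        config.reduction_mean
        + genotype_effect
        + config.adherence_effect * (lat["adherence"] - config.adherence_mean)
        + config.t2d_effect * (lat["t2d"] - config.t2d_prev)
        + config.mace_effect * (lat["prior_mace"] - config.mace_prev)
        + config.baseline_effect * (lat["baseline_nonhdl"] - config.baseline_mean)
        + noise
    )
    lat["followup_nonhdl"] = lat["baseline_nonhdl"] - lat["reduction"]

    mix = config.statin_mix
    cat = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
    other = rng.choice(["rosuvastatin", "pravastatin", "fluvastatin"], size=n)
    lat["statin_type"] = np.where(cat == "other", other, cat)
    lat["directions"] = np.where(rng.random(n) < 0.9, 1, 2)
    strength = np.empty(n)
    for statin, (menu, probs) in _STRENGTH_MENU.items():
        mask = lat["statin_type"].to_numpy() == statin
        strength[mask] = rng.choice(menu, size=int(mask.sum()), p=probs)
    lat["strength_mg"] = strength

    lo, hi = config.followup_day_range
    lat["followup_offset"] = _lognormal_days(rng, config.followup_median_days,
                                             config.followup_log_sd, n, lo, hi)
    lat["baseline_offset"] = _lognormal_days(rng, config.baseline_median_days,
                                             config.baseline_log_sd, n)
    lat["initiation_day"] = rng.integers(0, _EPOCH_DAYS, n)

    lat["switch"] = rng.random(n) < config.switch_prob
    lat["dose_reduce"] = rng.random(n) < config.dose_reduction_prob
    lat["dose_increase"] = rng.random(n) < config.dose_increase_prob
    return lat


_TRUTH_BASE = ["patient_id", "adherence", "genotype_effect", "reduction",
               "followup_nonhdl", "switch", "dose_reduce", "dose_increase"]


def _truth_table(lat: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    cols = list(_TRUTH_BASE)
    cols += [c for c in lat.columns if c.endswith("_enc") or c == "joint_protective"]
    return lat[cols].rename(columns={"reduction": "true_reduction",
                                     "followup_nonhdl": "true_followup_nonhdl"}).copy()


def simulate_analysis_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-mode fast path: sample the outcome model directly.

    Returns (analysis table, truth table). The analysis table carries
    the same columns the phenotyping stage would derive (outcome,
    usage covariates, demographics) plus per-variant protective-allele
    counts, without materialising event streams. Used for the
    many-replicate recovery and calibration studies.
    """
    rng = np.random.default_rng(config.seed)
    lat = _draw_latents(config, rng)
    tbl = pd.DataFrame({
        "patient_id": lat["patient_id"],
        "first_statin_type": lat["statin_type"],
        "baseline_nonhdl": lat["baseline_nonhdl"],
        "followup_nonhdl": lat["followup_nonhdl"],
        "absolute_reduction": lat["reduction"],
        "percent_reduction": 100.0 * lat["reduction"] / lat["baseline_nonhdl"],
        "duration_periods": lat["followup_offset"] / 28.0,
        "switched": lat["switch"],
        "dose_reduced": lat["dose_reduce"],
        "dose_increased": lat["dose_increase"],
        "mean_dose": lat["strength_mg"] * lat["directions"],
        "pdc": lat["adherence"],
        "sex": lat["sex"],
        "t2d": lat["t2d"],
        "prior_mace": lat["prior_mace"],
    })
    for v in config.variant_specs:
        counts = lat[f"{v.rsid}_count"]
        if config.genotype_missing_rate > 0:
            counts = counts.mask(rng.random(len(counts)) < config.genotype_missing_rate)
        tbl[f"{v.rsid}_count"] = counts
    return tbl, _truth_table(lat, config)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the four analysis input tables plus the truth table.

    Deterministic for a given config (identical seeds give bit-identical
    tables). Every patient receives one pre-initiation lipid panel, one
    panel inside the follow-up window, and 28-day dispensing from
    initiation past the follow-up lab with quantities realising the
    latent adherence. Switchers change statin type before the follow-up
    lab at potency-equivalent strength.
    """
    rng = np.random.default_rng(config.seed)
    lat = _draw_latents(config, rng)
    n = config.n_patients
    initiation = _EPOCH_START + pd.to_timedelta(lat["initiation_day"], unit="D")

    demographics = pd.DataFrame({
        "patient_id": lat["patient_id"],
        "sex": lat["sex"],
        "birth_year": (initiation.dt.year - lat["age"]).astype(int),
        "t2d": lat["t2d"],
        "prior_mace": lat["prior_mace"],
    })

    # --- prescriptions: scripts every 28 days, 8 per patient ---------------
    n_scripts = 8
    offsets = np.arange(n_scripts) * 28
    followup = lat["followup_offset"].to_numpy()
    m_before = (followup - 1) // 28 + 1  # scripts strictly before the follow-up lab

    equivalence = load_equivalence_table()
    ratios = lat["statin_type"].map(equivalence).to_numpy()

    types = np.tile(lat["statin_type"].to_numpy()[:, None], (1, n_scripts)).astype(object)
    strength = np.tile(lat["strength_mg"].to_numpy()[:, None], (1, n_scripts)).astype(float)
    col_ix = np.tile(np.arange(n_scripts), (n, 1))

    def _change_index(active: np.ndarray) -> np.ndarray:
        # a script index in [1, m-1], so the change lands before the follow-up lab
        u = rng.random(n)
        idx = 1 + np.floor(u * np.maximum(m_before - 1, 1)).astype(int)
        return np.where(active & (m_before >= 2), idx, n_scripts + 1)

    inc_idx = _change_index(lat["dose_increase"].to_numpy())
    red_idx = _change_index(lat["dose_reduce"].to_numpy())
    strength[col_ix >= inc_idx[:, None]] *= 2.0
    mask_red = col_ix >= red_idx[:, None]
    strength[mask_red] *= 0.5

    switch = lat["switch"].to_numpy()
    switch_idx = _change_index(switch)
    target = np.where(lat["statin_type"] == "simvastatin", "atorvastatin", "simvastatin")
    target_ratio = pd.Series(target).map(equivalence).to_numpy()
    switched_cell = col_ix >= switch_idx[:, None]
    types[switched_cell] = np.tile(target[:, None], (1, n_scripts))[switched_cell]
    # potency-equivalent strength after the switch, so switching alone is not a dose change
    conv = np.tile((ratios / target_ratio)[:, None], (1, n_scripts))
    strength[switched_cell] *= conv[switched_cell]
    # switchers whose follow-up lab falls inside the first pack period get an
    # extra mid-period dispense of the new statin, so every drawn switcher
    # really changes type before the measurement
    early_switch = switch & (m_before < 2)

    directions = np.tile(lat["directions"].to_numpy()[:, None], (1, n_scripts)).astype(float)
    jitter_sd = 0.15
    jitter = rng.lognormal(-0.5 * jitter_sd ** 2, jitter_sd, (n, n_scripts))
    adherence = lat["adherence"].to_numpy()[:, None]
    quantity = np.maximum(np.round(28.0 * directions * adherence * jitter), 1).astype(int)

    dispense = (initiation.to_numpy()[:, None]
                + offsets[None, :].astype("timedelta64[D]"))
    prescriptions = pd.DataFrame({
        "patient_id": np.repeat(lat["patient_id"].to_numpy(), n_scripts),
        "dispense_date": dispense.ravel(),
        "statin_type": types.ravel(),
        "strength_mg": strength.ravel(),
        "quantity": quantity.ravel(),
        "directions": directions.ravel(),
    })
    extra_jitter = rng.lognormal(-0.5 * jitter_sd ** 2, jitter_sd, n)
    if early_switch.any():
        ix = np.flatnonzero(early_switch)
        extra = pd.DataFrame({
            "patient_id": lat["patient_id"].to_numpy()[ix],
            "dispense_date": initiation.to_numpy()[ix] + np.timedelta64(14, "D"),
            "statin_type": target[ix],
            "strength_mg": lat["strength_mg"].to_numpy()[ix] * (ratios / target_ratio)[ix],
            "quantity": np.maximum(np.round(
                28.0 * lat["directions"].to_numpy()[ix]
                * adherence[ix, 0] * extra_jitter[ix]), 1).astype(int),
            "directions": lat["directions"].to_numpy()[ix].astype(float),
        })
        prescriptions = pd.concat([prescriptions, extra], ignore_index=True)
    prescriptions = prescriptions.sort_values(
        ["patient_id", "dispense_date"], kind="stable").reset_index(drop=True)

    # --- labs: one baseline panel, one in-window follow-up panel -----------
    followup_obs = np.maximum(lat["followup_nonhdl"].to_numpy(), _MINOR_FLOOR)
    hdl = np.clip(rng.normal(1.35, 0.25, 2 * n), 0.4, None)
    lab_nonhdl = np.concatenate([lat["baseline_nonhdl"].to_numpy(), followup_obs])
    lab_dates = np.concatenate([
        (initiation - pd.to_timedelta(lat["baseline_offset"], unit="D")).to_numpy(),
        (initiation + pd.to_timedelta(lat["followup_offset"], unit="D")).to_numpy(),
    ])
    labs = pd.DataFrame({
        "patient_id": np.concatenate([lat["patient_id"].to_numpy()] * 2),
        "date": lab_dates,
        "total_cholesterol": lab_nonhdl + hdl,
        "hdl_cholesterol": hdl,
    }).sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)

    # --- genotypes: long table of allele pairs ------------------------------
    metadata = {v.rsid: v for v in load_variant_metadata()}
    geno_frames = []
    for v in config.variant_specs:
        info = metadata.get(v.rsid)
        prot = info.protective_allele if info else "B"
        other = info.other_allele if info else "A"
        counts = lat[f"{v.rsid}_count"].to_numpy().astype(int)
        pair = np.empty((n, 2), dtype=object)
        pair[counts == 0] = [other, other]
        pair[counts == 2] = [prot, prot]
        het = sorted([other, prot])
        pair[counts == 1] = het
        frame = pd.DataFrame({"patient_id": lat["patient_id"], "rsid": v.rsid,
                              "allele1": pair[:, 0], "allele2": pair[:, 1]})
        if config.genotype_missing_rate > 0:
            miss = rng.random(n) < config.genotype_missing_rate
            frame.loc[miss, ["allele1", "allele2"]] = pd.NA
        geno_frames.append(frame)
    genotypes = pd.concat(geno_frames, ignore_index=True)

    truth = _truth_table(lat, config)
    truth["followup_clipped"] = lat["followup_nonhdl"].to_numpy() < _MINOR_FLOOR

    return SyntheticCohort(demographics=demographics, prescriptions=prescriptions,
                           labs=labs, genotypes=genotypes, truth=truth, config=config)
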