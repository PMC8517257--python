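"""Statin-response phenotyping from prescribing and laboratory tables.

Turns raw longitudinal records into one analysis row per patient:

* baseline non-HDL-C = the nearest measurement on or before the first
  statin prescription (any look-back by default);
* follow-up non-HDL-C = the earliest measurement 28-180 days (inclusive)
  after initiation;
* response = baseline - follow-up, in mmol/L and as a percentage of
  baseline (positive = improvement);
* statin-usage covariates over the scripts dispensed before the
  follow-up measurement: switching, simvastatin-equivalent mean daily
  dose, dose reduction/increase flags, therapy duration in 28-day pack
  periods, and the proportion-of-days-covered (PDC) adherence surrogate.

PDC is deliberately uncapped: the numerator is the days of supply
dispensed in [first script, last script) and the denominator the span in
days between the first and last script, so stockpiling pushes PDC above
1 (the study cohort averages ~1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

STATIN_TYPES = ("simvastatin", "atorvastatin", "rosuvastatin", "pravastatin", "fluvastatin")

#: follow-up window after statin initiation, days, closed interval
FOLLOWUP_WINDOW = (28, 180)

#: days per dispensing period (standard pack size)
PACK_DAYS = 28


class UnknownStatinError(KeyError):
    """A prescription names a statin absent from the equivalence table."""


class InvalidRecordError(ValueError):
    """A lipid record violates its domain (e.g. non-positive baseline)."""


@dataclass(frozen=True)
class PhenotypeConfig:
    """Switches for the phenotype derivation.

    max_lookback_days  -- limit on how old the baseline lab may be
                          (None = any value before initiation qualifies).
    pdc_before_followup -- restrict PDC to scripts before the follow-up
                          lab (True, default) or use all scripts (False).
    window             -- follow-up window in days, closed interval.
    """

    max_lookback_days: int | None = None
    pdc_before_followup: bool = True
    window: tuple[int, int] = FOLLOWUP_WINDOW


def nonhdl(total_cholesterol, hdl_cholesterol):
    """Non-HDL cholesterol: total minus HDL, mmol/L."""
    return total_cholesterol - hdl_cholesterol


def _prepare_labs(labs: pd.DataFrame) -> pd.DataFrame:
    labs = labs.copy()
    labs["date"] = pd.to_datetime(labs["date"])
    if "non_hdl" not in labs.columns:
        labs["non_hdl"] = nonhdl(labs["total_cholesterol"], labs["hdl_cholesterol"])
    # same-day duplicate assays: average (order-independent tie rule)
    return labs.groupby(["patient_id", "date"], as_index=False)["non_hdl"].mean()


def derive_baseline(labs: pd.DataFrame, initiation_date,
                    max_lookback_days: int | None = None) -> tuple[float, int] | None:
    """Nearest non-HDL-C value on or before statin initiation.

    Returns (value mmol/L, offset days <= 0), or None when no
    pre-initiation measurement exists. Same-day duplicates are averaged.
    """
    initiation_date = pd.Timestamp(initiation_date)
    labs = _prepare_labs(labs)
    offset = (labs["date"] - initiation_date).dt.days
    elig = offset <= 0
    if max_lookback_days is not None:
        elig &= offset >= -max_lookback_days
    if not elig.any():
        return None
    picked = labs[elig].sort_values("date").iloc[-1]
    return float(picked["non_hdl"]), int((picked["date"] - initiation_date).days)


def derive_followup(labs: pd.DataFrame, initiation_date,
                    window: tuple[int, int] = FOLLOWUP_WINDOW) -> tuple[float, int] | None:
    """Earliest non-HDL-C value in the closed follow-up window after
    initiation (default 28-180 days); None if the window is empty."""
    initiation_date = pd.Timestamp(initiation_date)
    labs = _prepare_labs(labs)
    offset = (labs["date"] - initiation_date).dt.days
    elig = (offset >= window[0]) & (offset <= window[1])
    if not elig.any():
        return None
    picked = labs[elig].sort_values("date").iloc[0]
    return float(picked["non_hdl"]), int((picked["date"] - initiation_date).days)


def compute_response(baseline: float, followup: float) -> tuple[float, float]:
    """Absolute (mmol/L) and percent reduction from baseline to follow-up.

    Positive values mean the cholesterol fell. Raises for non-positive
    baseline, where a percentage is undefined.
    """
    if baseline <= 0:
        raise InvalidRecordError(f"baseline non-HDL-C must be positive, got {baseline}")
    absolute = baseline - followup
    return absolute, 100.0 * absolute / baseline


def detect_switching(prescriptions: pd.DataFrame, followup_date) -> bool:
    """True when more than one distinct statin type was dispensed strictly
    before the follow-up measurement."""
    followup_date = pd.Timestamp(followup_date)
    before = prescriptions[pd.to_datetime(prescriptions["dispense_date"]) < followup_date]
    return int(before["statin_type"].nunique()) > 1


def duration_periods(initiation_date, followup_date) -> float:
    """Therapy duration from initiation to the follow-up lab, in 28-day
    pack periods."""
    days = (pd.Timestamp(followup_date) - pd.Timestamp(initiation_date)).days
    return days / PACK_DAYS


def sim_equiv_dose(statin_type: str, daily_dose_mg: float,
                   equivalence_table: Mapping[str, float]) -> float:
    """Convert a daily dose to its simvastatin-equivalent via the potency
    ratio table (identity for simvastatin)."""
    try:
        ratio = equivalence_table[statin_type]
    except KeyError:
        raise UnknownStatinError(
            f"statin type {statin_type!r} missing from the equivalence table"
        ) from None
    return daily_dose_mg * ratio


def _equiv_daily_doses(prescriptions: pd.DataFrame,
                       equivalence_table: Mapping[str, float]) -> pd.Series:
    unknown = set(prescriptions["statin_type"]) - set(equivalence_table)
    if unknown:
        raise UnknownStatinError(f"statin types {sorted(unknown)} missing from the equivalence table")
    ratios = prescriptions["statin_type"].map(equivalence_table)
    return prescriptions["strength_mg"] * prescriptions["directions"] * ratios


def mean_dose(prescriptions: pd.DataFrame, followup_date,
              equivalence_table: Mapping[str, float]) -> float:
    """Mean simvastatin-equivalent daily dose over scripts before follow-up."""
    followup_date = pd.Timestamp(followup_date)
    before = prescriptions[pd.to_datetime(prescriptions["dispense_date"]) < followup_date]
    if before.empty:
        raise InvalidRecordError("no prescriptions before the follow-up date")
    return float(_equiv_daily_doses(before, equivalence_table).mean())


def detect_dose_changes(prescriptions: pd.DataFrame, followup_date,
                        equivalence_table: Mapping[str, float]) -> tuple[bool, bool]:
    """(dose_reduced, dose_increased) from consecutive simvastatin-equivalent
    daily doses before follow-up; both can be true. Equivalence-scale
    comparison means a statin switch at constant potency is not a change."""
    followup_date = pd.Timestamp(followup_date)
    before = prescriptions[pd.to_datetime(prescriptions["dispense_date"]) < followup_date]
    before = before.sort_values("dispense_date", kind="stable")
    doses = _equiv_daily_doses(before, equivalence_table).to_numpy()
    if len(doses) < 2:
        return False, False
    diffs = np.diff(doses)
    return bool((diffs < 0).any()), bool((diffs > 0).any())


def compute_pdc(prescriptions: pd.DataFrame, followup_date) -> tuple[float, bool]:
    """Proportion-of-days-covered adherence surrogate, uncapped.

    Over scripts dispensed strictly before `followup_date`:
    supply dispensed in [first, last) divided by the day span first->last.
    The final script's supply is excluded (it covers days beyond the
    span). A patient with a single qualifying script gets supply divided
    by days from dispensing to follow-up instead, flagged imputed.
    """
    followup_date = pd.Timestamp(followup_date)
    rx = prescriptions.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    before = rx[rx["dispense_date"] < followup_date]
    if before.empty:
        raise InvalidRecordError("no prescriptions before the follow-up date")
    supply = before["quantity"] / before["directions"]
    first = before["dispense_date"].min()
    last = before["dispense_date"].max()
    span = (last - first).days
    if span == 0:
        denom = (followup_date - first).days
        if denom <= 0:
            raise InvalidRecordError("follow-up date does not postdate the only prescription")
        return float(supply.sum() / denom), True
    covered = supply[before["dispense_date"] < last].sum()
    return float(covered / span), False


def derive_phenotypes(prescriptions: pd.DataFrame, labs: pd.DataFrame,
                      demographics: pd.DataFrame | None = None,
                      equivalence_table: Mapping[str, float] | None = None,
                      config: PhenotypeConfig = PhenotypeConfig()) -> pd.DataFrame:
    """Vectorised phenotype derivation for a whole cohort.

    Produces one row per patient with a valid positive baseline and an
    in-window follow-up; patients failing either filter are absent (the
    pipeline's attrition report counts them). Output is sorted by
    patient id and independent of input row order.
    """
    if equivalence_table is None:
        from .io import load_equivalence_table

        equivalence_table = load_equivalence_table()

    rx = prescriptions.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    rx = rx.sort_values(["patient_id", "dispense_date"], kind="stable")
    init = rx.groupby("patient_id", as_index=False).first()[
        ["patient_id", "dispense_date", "statin_type"]
    ].rename(columns={"dispense_date": "initiation_date", "statin_type": "first_statin_type"})

    labs_clean = _prepare_labs(labs).merge(init[["patient_id", "initiation_date"]], on="patient_id")
    offset = (labs_clean["date"] - labs_clean["initiation_date"]).dt.days
    labs_clean["offset_days"] = offset

    pre = labs_clean[offset <= 0]
    if config.max_lookback_days is not None:
        pre = pre[pre["offset_days"] >= -config.max_lookback_days]
    base = (pre.sort_values(["patient_id", "date"], kind="stable")
            .groupby("patient_id", as_index=False).last()
            .rename(columns={"non_hdl": "baseline_nonhdl", "offset_days": "baseline_offset_days"}))

    lo, hi = config.window
    post = labs_clean[(offset >= lo) & (offset <= hi)]
    fup = (post.sort_values(["patient_id", "date"], kind="stable")
           .groupby("patient_id", as_index=False).first()
           .rename(columns={"non_hdl": "followup_nonhdl", "offset_days": "followup_offset_days",
                            "date": "followup_date"}))

    pheno = init.merge(base[["patient_id", "baseline_nonhdl", "baseline_offset_days"]],
                       on="patient_id")
    pheno = pheno.merge(fup[["patient_id", "followup_nonhdl", "followup_offset_days",
                             "followup_date"]], on="patient_id")
    pheno = pheno[pheno["baseline_nonhdl"] > 0].copy()

    pheno["absolute_reduction"] = pheno["baseline_nonhdl"] - pheno["followup_nonhdl"]
    pheno["percent_reduction"] = 100.0 * pheno["absolute_reduction"] / pheno["baseline_nonhdl"]
    pheno["duration_periods"] = (
        (pheno["followup_date"] - pheno["initiation_date"]).dt.days / PACK_DAYS
    )

    # statin-usage covariates from scripts before the follow-up lab
    rx_f = rx.merge(pheno[["patient_id", "followup_date"]], on="patient_id")
    before = rx_f[rx_f["dispense_date"] < rx_f["followup_date"]].copy()
    before["equiv_dose"] = _equiv_daily_doses(before, equivalence_table)
    before["supply_days"] = before["quantity"] / before["directions"]

    g = before.groupby("patient_id")
    usage = pd.DataFrame({
        "switched": g["statin_type"].nunique() > 1,
        "mean_dose": g["equiv_dose"].mean(),
        "first_rx": g["dispense_date"].min(),
        "last_rx": g["dispense_date"].max(),
        "supply_total": g["supply_days"].sum(),
        "n_scripts": g.size(),
    })
    deltas = before.sort_values(["patient_id", "dispense_date"], kind="stable")
    diff = deltas.groupby("patient_id")["equiv_dose"].diff()
    usage["dose_reduced"] = (diff < 0).groupby(deltas["patient_id"]).any()
    usage["dose_increased"] = (diff > 0).groupby(deltas["patient_id"]).any()

    last_supply = (before[before["dispense_date"].eq(
        before["patient_id"].map(usage["last_rx"]))]
        .groupby("patient_id")["supply_days"].sum())
    usage["supply_before_last"] = usage["supply_total"] - last_supply.reindex(usage.index).fillna(0.0)
    span = (usage["last_rx"] - usage["first_rx"]).dt.days
    usage["pdc"] = usage["supply_before_last"] / span.where(span > 0)
    usage["pdc_imputed"] = span == 0

    pheno = pheno.merge(usage.reset_index(), on="patient_id", how="left")
    single = pheno["pdc_imputed"].fillna(False).astype(bool)
    denom = (pheno.loc[single, "followup_date"] - pheno.loc[single, "first_rx"]).dt.days
    pheno.loc[single, "pdc"] = pheno.loc[single, "supply_total"] / denom

    if not config.pdc_before_followup:
        # recompute PDC over the full prescription history
        rx_all = rx.copy()
        rx_all["supply_days"] = rx_all["quantity"] / rx_all["directions"]
        ga = rx_all.groupby("patient_id")
        first_a, last_a = ga["dispense_date"].min(), ga["dispense_date"].max()
        last_supply_a = (rx_all[rx_all["dispense_date"].eq(
            rx_all["patient_id"].map(last_a))].groupby("patient_id")["supply_days"].sum())
        span_a = (last_a - first_a).dt.days
        pdc_all = (ga["supply_days"].sum() - last_supply_a) / span_a.where(span_a > 0)
        pheno["pdc"] = pheno["patient_id"].map(pdc_all).fillna(pheno["pdc"])

    if demographics is not None:
        pheno = pheno.merge(demographics, on="patient_id", how="left")

    cols = ["patient_id", "initiation_date", "first_statin_type",
            "baseline_nonhdl", "baseline_offset_days",
            "followup_nonhdl", "followup_offset_days",
            "absolute_reduction", "percent_reduction", "duration_periods",
            "switched", "dose_reduced", "dose_increased",
            "mean_dose", "pdc", "pdc_imputed"]
    extra = [c for c in pheno.columns if c not in cols
             and c not in ("followup_date", "first_rx", "last_rx",
                           "supply_total", "supply_before_last", "n_scripts")]
    out = pheno[cols + extra].sort_values("patient_id", kind="stable").reset_index(drop=True)
    for flag in ("switched", "dose_reduced", "dose_increased", "pdc_imputed"):
        out[flag] = out[flag].fillna(False).astype(bool)
    return out
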