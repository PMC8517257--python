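"""Phenotype-derivation rules: lab selection windows, response
arithmetic, statin-usage covariates, and the uncapped PDC convention."""

import numpy as np
import pandas as pd
import pytest

from statin_pgx import phenotyping as ph
from conftest import make_labs, make_rx

EQ = {"simvastatin": 1.0, "atorvastatin": 2.0, "rosuvastatin": 4.0,
      "pravastatin": 0.5, "fluvastatin": 0.5}
BASE = pd.Timestamp("2010-06-01")


def day(off):
    return BASE + pd.Timedelta(days=off)


class TestLabSelection:
    def test_baseline_takes_nearest_value_before_initiation(self):
        labs = make_labs("p1", [(-40, 5.0), (-12, 4.5), (30, 3.0)])
        assert ph.derive_baseline(labs, BASE) == (4.5, -12)

    def test_baseline_absent_without_pre_initiation_lab(self):
        labs = make_labs("p1", [(30, 3.0)])
        assert ph.derive_baseline(labs, BASE) is None

    def test_same_day_duplicate_assays_are_averaged(self):
        labs = make_labs("p1", [(-12, 4.0), (-12, 5.0)])
        assert ph.derive_baseline(labs, BASE) == (4.5, -12)

    def test_lookback_limit_excludes_old_values(self):
        labs = make_labs("p1", [(-400, 5.0)])
        assert ph.derive_baseline(labs, BASE) == (5.0, -400)
        assert ph.derive_baseline(labs, BASE, max_lookback_days=365) is None

    @pytest.mark.parametrize("offsets,expected_offset", [
        ([(10, 5.0), (30, 4.0), (90, 3.5)], 30),   # earliest in window
        ([(28, 4.2), (180, 3.0)], 28),             # closed lower endpoint
        ([(180, 3.0)], 180),                       # closed upper endpoint
    ])
    def test_followup_takes_earliest_in_window(self, offsets, expected_offset):
        labs = make_labs("p1", offsets)
        value, offset = ph.derive_followup(labs, BASE)
        assert offset == expected_offset

    @pytest.mark.parametrize("offset", [27, 181, -5])
    def test_followup_absent_outside_window(self, offset):
        labs = make_labs("p1", [(offset, 4.0)])
        assert ph.derive_followup(labs, BASE) is None


class TestResponse:
    def test_study_mean_values(self):
        absolute, percent = ph.compute_response(4.43, 2.98)
        assert absolute == pytest.approx(1.45)
        assert percent == pytest.approx(32.7, abs=0.05)

    @pytest.mark.parametrize("baseline,followup,expected", [
        (4.0, 4.0, (0.0, 0.0)),
        (3.0, 4.5, (-1.5, -50.0)),
    ])
    def test_sign_convention(self, baseline, followup, expected):
        assert ph.compute_response(baseline, followup) == pytest.approx(expected)

    def test_non_positive_baseline_is_invalid(self):
        with pytest.raises(ph.InvalidRecordError):
            ph.compute_response(0.0, 1.0)


class TestUsageCovariates:
    def test_switcher_needs_distinct_types_before_followup(self):
        rx = make_rx("p1", [(0, "simvastatin", 20, 28, 1),
                            (28, "simvastatin", 20, 28, 1),
                            (56, "atorvastatin", 10, 28, 1)])
        assert ph.detect_switching(rx, day(90)) is True
        assert ph.detect_switching(rx, day(40)) is False  # switch after cutoff

    @pytest.mark.parametrize("days,expected", [(84, 3.0), (28, 1.0), (75, 75 / 28)])
    def test_duration_in_pack_periods(self, days, expected):
        assert ph.duration_periods(BASE, day(days)) == pytest.approx(expected)

    @pytest.mark.parametrize("statin,dose,expected", [
        ("simvastatin", 20, 20.0),
        ("atorvastatin", 10, 20.0),
        ("rosuvastatin", 5, 20.0),
        ("pravastatin", 40, 20.0),
    ])
    def test_simvastatin_equivalent_dose(self, statin, dose, expected):
        assert ph.sim_equiv_dose(statin, dose, EQ) == expected

    def test_unknown_statin_raises(self):
        with pytest.raises(ph.UnknownStatinError):
            ph.sim_equiv_dose("cerivastatin", 10, EQ)

    def test_mean_dose_on_equivalence_scale(self):
        rx = make_rx("p1", [(0, "simvastatin", 20, 28, 1),
                            (28, "atorvastatin", 20, 28, 1)])
        assert ph.mean_dose(rx, day(90), EQ) == pytest.approx(30.0)  # mean(20, 40)

    @pytest.mark.parametrize("doses,expected", [
        ((20, 40, 20), (True, True)),
        ((20, 20, 20), (False, False)),
        ((40, 20), (True, False)),
        ((20, 40), (False, True)),
    ])
    def test_dose_change_flags(self, doses, expected):
        rx = make_rx("p1", [(28 * i, "simvastatin", d, 28, 1) for i, d in enumerate(doses)])
        assert ph.detect_dose_changes(rx, day(200), EQ) == expected

    def test_potency_constant_switch_is_not_a_dose_change(self):
        rx = make_rx("p1", [(0, "simvastatin", 40, 28, 1),
                            (28, "atorvastatin", 20, 28, 1)])
        assert ph.detect_dose_changes(rx, day(90), EQ) == (False, False)


class TestPDC:
    def test_perfect_coverage(self):
        rx = make_rx("p1", [(0, "simvastatin", 20, 28, 1), (28, "simvastatin", 20, 28, 1)])
        assert ph.compute_pdc(rx, day(60)) == (1.0, False)

    def test_double_directions_halve_coverage(self):
        rx = make_rx("p1", [(0, "simvastatin", 20, 28, 2), (28, "simvastatin", 20, 28, 2)])
        assert ph.compute_pdc(rx, day(60)) == (0.5, False)

    def test_stockpiling_gives_pdc_above_one(self):
        rx = make_rx("p1", [(0, "simvastatin", 20, 28, 1),
                            (14, "simvastatin", 20, 28, 1),
                            (28, "simvastatin", 20, 28, 1)])
        assert ph.compute_pdc(rx, day(60)) == (2.0, False)

    def test_single_prescription_is_imputed_against_followup(self):
        rx = make_rx("p1", [(0, "simvastatin", 20, 28, 1)])
        pdc, imputed = ph.compute_pdc(rx, day(56))
        assert pdc == pytest.approx(0.5)
        assert imputed is True

    def test_no_prescriptions_before_followup_raises(self):
        rx = make_rx("p1", [(10, "simvastatin", 20, 28, 1)])
        with pytest.raises(ph.InvalidRecordError):
            ph.compute_pdc(rx, day(5))


class TestTableDerivation:
    def test_row_order_invariance(self, default_cohort):
        c = default_cohort
        shuffled_rx = c.prescriptions.sample(frac=1, random_state=1).reset_index(drop=True)
        shuffled_labs = c.labs.sample(frac=1, random_state=2).reset_index(drop=True)
        a = ph.derive_phenotypes(c.prescriptions, c.labs, c.demographics)
        b = ph.derive_phenotypes(shuffled_rx, shuffled_labs, c.demographics)
        pd.testing.assert_frame_equal(a, b)

    def test_emitted_records_satisfy_window_and_identity(self, default_phenotypes):
        p = default_phenotypes
        assert p["followup_offset_days"].between(28, 180).all()
        assert (p["baseline_offset_days"] <= 0).all()
        np.testing.assert_allclose(
            p["absolute_reduction"] + p["followup_nonhdl"], p["baseline_nonhdl"], atol=1e-12)
        assert (p["pdc"] >= 0).all()

    def test_switcher_fraction_matches_generator_probability(self, default_cohort,
                                                             default_phenotypes):
        prob = default_cohort.config.switch_prob
        frac = default_phenotypes["switched"].mean()
        se = np.sqrt(prob * (1 - prob) / len(default_phenotypes))
        assert abs(frac - prob) <= 3 * se

    def test_recomputed_pdc_tracks_latent_adherence(self, default_cohort, default_phenotypes):
        merged = default_phenotypes.merge(default_cohort.truth, on="patient_id")
        assert np.corrcoef(merged["pdc"], merged["adherence"])[0, 1] > 0.9
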