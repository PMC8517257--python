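"""Genotype QC and encoding checks: MAF, HWE test calibration, the three
genetic-model encodings, and the two-SNP risk-score enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from statin_pgx import genetics as gx
from statin_pgx.synthetic_ehr import genotype_frequencies_hwe

ABCB1 = gx.VariantInfo(rsid="rs1045642", gene="ABCB1", major_allele="T", minor_allele="C",
                       genetic_model=gx.GeneticModel.RECESSIVE, protective_allele="C")


def calls_from_counts(n_hom_major, n_het, n_hom_minor, major="T", minor="C"):
    pairs = ([(major, major)] * n_hom_major + [(major, minor)] * n_het
             + [(minor, minor)] * n_hom_minor)
    return pd.DataFrame(pairs, columns=["allele1", "allele2"])


class TestMAF:
    @pytest.mark.parametrize("counts,expected", [
        ((25, 50, 25), 0.5),
        ((100, 0, 0), 0.0),
        ((81, 18, 1), 0.10),
    ])
    def test_allele_counting(self, counts, expected):
        calls = calls_from_counts(*counts)
        assert gx.minor_allele_frequency(calls, "C") == pytest.approx(expected)

    def test_missing_calls_are_excluded_pairwise(self):
        calls = calls_from_counts(1, 1, 1)
        calls.loc[len(calls)] = [None, None]
        assert gx.minor_allele_frequency(calls, "C") == pytest.approx(3 / 6)

    def test_all_missing_raises(self):
        calls = pd.DataFrame({"allele1": [None], "allele2": [None]})
        with pytest.raises(ValueError):
            gx.minor_allele_frequency(calls, "C")


class TestHWE:
    def test_exact_hwe_proportions_give_zero_statistic(self):
        chi2, p = gx.hwe_chi_square(25, 50, 25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        # observed (50, 0, 50) vs expected (25, 50, 25) at q = 0.5, n = 100
        chi2, p = gx.hwe_chi_square(50, 0, 50)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            gx.hwe_chi_square(0, 0, 0)

    def test_monomorphic_variant_warns_and_returns_null(self):
        with pytest.warns(gx.MonomorphicVariantWarning):
            chi2, p = gx.hwe_chi_square(100, 0, 0)
        assert (chi2, p) == (0.0, 1.0)

    def test_exact_test_agrees_with_chisquare_at_large_n(self):
        counts = (3600, 4800, 1600)
        _, p_chi = gx.hwe_chi_square(*counts)
        p_exact = gx.hwe_exact(*counts)
        assert p_chi > 0.5 and p_exact > 0.5

    def test_null_rejection_rate_is_nominal(self):
        """Genotypes drawn under HWE should be rejected at ~ the 5% rate."""
        n_reps, rejections = 2000, 0
        for seed in range(n_reps):
            counts = genotype_frequencies_hwe(maf=0.3, n=1000, seed=seed)
            _, p = gx.hwe_chi_square(*counts)
            rejections += p < 0.05
        assert 0.035 <= rejections / n_reps <= 0.065


class TestEncoding:
    @pytest.mark.parametrize("pair,model,expected", [
        (("T", "C"), "dominant", 1.0),
        (("T", "C"), "recessive", 0.0),
        (("C", "C"), "additive", 2.0),
        (("T", "T"), "dominant", 0.0),
        (("C", "C"), "recessive", 1.0),
    ])
    def test_encoding_examples(self, pair, model, expected):
        assert gx.encode(pair, ABCB1, model) == expected

    def test_missing_call_encodes_as_nan(self):
        assert np.isnan(gx.encode((None, None), ABCB1, "additive"))

    def test_foreign_allele_rejected(self):
        with pytest.raises(ValueError):
            gx.encode(("A", "C"), ABCB1, "additive")

    def test_dominant_bounds_recessive_and_additive_is_their_sum(self):
        counts = pd.Series([0.0, 1.0, 2.0, np.nan])
        dom = gx.encode_counts(counts, "dominant")
        rec = gx.encode_counts(counts, "recessive")
        add = gx.encode_counts(counts, "additive")
        valid = counts.notna()
        assert (dom[valid] >= rec[valid]).all()
        pd.testing.assert_series_equal(add, dom + rec)


class TestRiskScore:
    @pytest.mark.parametrize("abcb1,lilrb5,expected", [
        (("C", "C"), ("T", "C"), 0),   # protected
        (("C", "T"), ("T", "T"), 1),   # at risk
        (("C", "T"), ("T", "C"), None),  # discordant -> intermediate
        ((None, None), ("T", "T"), None),  # missing -> unassigned
    ])
    def test_level_examples(self, abcb1, lilrb5, expected):
        assert gx.two_snp_risk_score(abcb1, lilrb5).level == expected

    def test_complement_mode_counts_discordant_as_risk(self):
        assert gx.two_snp_risk_score(("C", "T"), ("T", "C"), mode="complement").level == 1
        assert gx.two_snp_risk_score((None, None), ("T", "T"), mode="complement").level is None

    def test_partition_over_all_nine_genotype_pairs(self):
        genotypes = [("C", "C"), ("C", "T"), ("T", "T")]
        levels = {(a, b): gx.two_snp_risk_score(a, b).level
                  for a, b in itertools.product(genotypes, genotypes)}
        assert sum(v == 0 for v in levels.values()) == 2
        assert sum(v == 1 for v in levels.values()) == 2
        assert sum(v is None for v in levels.values()) == 5
        assert levels[(("C", "C"), ("C", "C"))] == 0
        assert levels[(("T", "T"), ("T", "T"))] == 1

    def test_vectorised_levels_agree_with_scalar(self):
        pairs = list(itertools.product([0, 1, 2], [0, 1, 2]))
        a = pd.Series([p[0] for p in pairs], dtype=float)
        b = pd.Series([p[1] for p in pairs], dtype=float)
        for mode in ("strict", "complement"):
            vec = gx.risk_score_levels(a, b, mode=mode)
            for i, (ca, cb) in enumerate(pairs):
                pair_a = [("T", "T"), ("C", "T"), ("C", "C")][ca]
                pair_b = [("T", "T"), ("C", "T"), ("C", "C")][cb]
                scalar = gx.two_snp_risk_score(pair_a, pair_b, mode=mode).level
                if scalar is None:
                    assert np.isnan(vec.iloc[i])
                else:
                    assert vec.iloc[i] == scalar

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            gx.two_snp_risk_score(("C", "C"), ("C", "C"), mode="lenient")


class TestQCTable:
    def test_qc_on_synthetic_genotypes(self, default_cohort):
        from statin_pgx.io import load_variant_metadata

        variants = load_variant_metadata()
        qc = gx.genotype_qc_table(default_cohort.genotypes, variants)
        assert set(qc["rsid"]) == {v.rsid for v in variants}
        by_rsid = qc.set_index("rsid")
        for v in variants:
            se = np.sqrt(v.maf * (1 - v.maf) / (2 * 4000))
            assert by_rsid.loc[v.rsid, "maf"] == pytest.approx(v.maf, abs=4 * se)
        assert (by_rsid["hwe_p"] > 1e-4).all()  # generated under HWE
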