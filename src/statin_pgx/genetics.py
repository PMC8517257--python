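"""Genotype QC and encodings.

Minor-allele frequencies, Hardy-Weinberg testing, the three standard
genetic-model encodings (additive / dominant / recessive), and the
two-variant ABCB1/LILRB5 unweighted risk score used to contrast
"protected" against "at-risk" statin users.

Genotypes are handled as unordered allele pairs per patient per rsid.
Encodings count a designated *effect allele* — for the packaged variants
this is the protective allele from the study orientation, which need not
be the population minor allele (ABCB1 rs1045642 C is protective and sits
near 50% frequency in Europeans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


class GeneticModel(str, Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class MonomorphicVariantWarning(UserWarning):
    """Raised when a QC statistic is degenerate because only one allele is present."""


@dataclass(frozen=True)
class VariantInfo:
    """Per-variant metadata: alleles, assigned genetic model, protective orientation."""

    rsid: str
    gene: str
    major_allele: str
    minor_allele: str
    genetic_model: GeneticModel
    protective_allele: str
    maf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.rsid}: major and minor allele must differ")
        if self.protective_allele not in (self.major_allele, self.minor_allele):
            raise ValueError(f"{self.rsid}: protective allele not among the variant's alleles")

    @property
    def protective_genotypes(self) -> frozenset[str]:
        """Genotype classes (sorted allele strings) scoring 1 under the assigned model."""
        p, q = self.protective_allele, self.other_allele
        het = "".join(sorted([p, q]))
        hom = p + p
        model = GeneticModel(self.genetic_model)
        if model is GeneticModel.RECESSIVE:
            return frozenset({hom})
        if model is GeneticModel.DOMINANT:
            return frozenset({hom, het})
        return frozenset({hom, het})  # additive: any carrier scores > 0

    @property
    def other_allele(self) -> str:
        return self.minor_allele if self.protective_allele == self.major_allele else self.major_allele


@dataclass(frozen=True)
class RiskScoreAssignment:
    """Two-SNP risk-score level for one patient.

    level 0 = protected (ABCB1 rs1045642 CC and LILRB5 rs12975366 CC/TC),
    level 1 = at risk  (ABCB1 CT/TT and LILRB5 TT),
    None    = intermediate (discordant loci) or unassignable (missing call).
    """

    patient_id: object
    level: int | None
    abcb1_genotype: str | None
    lilrb5_genotype: str | None


def allele_counts(calls: pd.DataFrame, counted_allele: str) -> pd.Series:
    """Count `counted_allele` copies (0/1/2, NaN for missing) per row of an
    (allele1, allele2) frame."""
    a1 = calls["allele1"]
    a2 = calls["allele2"]
    missing = a1.isna() | a2.isna()
    counts = (a1 == counted_allele).astype(float) + (a2 == counted_allele).astype(float)
    counts[missing] = np.nan
    return counts


def minor_allele_frequency(calls: pd.DataFrame, minor_allele: str) -> float:
    """Sample frequency of `minor_allele` among non-missing calls for one rsid.

    Missing calls are excluded pairwise (the denominator is two alleles per
    genotyped patient, not per cohort member).
    """
    counts = allele_counts(calls, minor_allele).dropna()
    if len(counts) == 0:
        raise ValueError("no non-missing genotype calls")
    return float(counts.sum() / (2 * len(counts)))


def hwe_chi_square(n_hom_major: int, n_het: int, n_hom_minor: int) -> tuple[float, float]:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions.

    Expected counts use the sample allele frequency; no continuity
    correction. A monomorphic variant gives (0.0, 1.0) with a warning —
    there is nothing to test.
    """
    obs = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    q = (2 * n_hom_minor + n_het) / (2 * n)
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        warnings.warn("monomorphic variant: HWE test is degenerate", MonomorphicVariantWarning)
        return 0.0, 1.0
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p-value (sum of heterozygote-count probabilities no larger
    than the observed one, conditioning on allele counts)."""
    n = n_hom_major + n_het + n_hom_minor
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        warnings.warn("monomorphic variant: HWE test is degenerate", MonomorphicVariantWarning)
        return 1.0
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log P(het = h | allele counts) up to a constant, via log-factorials
    from scipy.special import gammaln

    def logprob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return h * np.log(2) - gammaln(h + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)

    lp = logprob(hets)
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(probs[probs <= observed + 1e-12].sum())


def encode_counts(counts: pd.Series | np.ndarray, model: GeneticModel | str) -> pd.Series:
    """Map effect-allele counts (0/1/2) to the numeric genotype code.

    additive -> the count itself; dominant -> carrier indicator;
    recessive -> homozygote indicator. NaN propagates.
    """
    counts = pd.Series(counts, dtype=float)
    model = GeneticModel(model)
    if model is GeneticModel.ADDITIVE:
        coded = counts.copy()
    elif model is GeneticModel.DOMINANT:
        coded = (counts >= 1).astype(float)
    else:
        coded = (counts == 2).astype(float)
    coded[counts.isna()] = np.nan
    return coded


def encode(allele_pair: tuple[str | None, str | None], variant: VariantInfo,
           model: GeneticModel | str | None = None) -> float:
    """Encode a single unordered allele pair under a genetic model
    (default: the variant's assigned model). Missing alleles give NaN."""
    a1, a2 = allele_pair
    if a1 is None or a2 is None or (isinstance(a1, float) and np.isnan(a1)):
        return float("nan")
    valid = {variant.major_allele, variant.minor_allele}
    if not {a1, a2} <= valid:
        raise ValueError(f"{variant.rsid}: alleles {a1}/{a2} not in {sorted(valid)}")
    count = (a1 == variant.protective_allele) + (a2 == variant.protective_allele)
    model = GeneticModel(model) if model is not None else GeneticModel(variant.genetic_model)
    return float(encode_counts(pd.Series([count]), model).iloc[0])


def genotype_class(allele_pair: tuple[str | None, str | None]) -> str | None:
    """Canonical genotype string (alleles sorted alphabetically), None if missing."""
    a1, a2 = allele_pair
    if a1 is None or a2 is None:
        return None
    if isinstance(a1, float) and np.isnan(a1):
        return None
    return "".join(sorted([str(a1), str(a2)]))


# Two-SNP risk score: the protective classes at each locus.
_ABCB1_PROTECTED = {"CC"}
_ABCB1_RISK = {"CT", "TT"}
_LILRB5_PROTECTED = {"CC", "CT"}  # C-allele carriers; 'TC' normalises to 'CT'
_LILRB5_RISK = {"TT"}


def two_snp_risk_score(abcb1_pair: tuple[str | None, str | None],
                       lilrb5_pair: tuple[str | None, str | None],
                       patient_id: object = None,
                       mode: str = "strict") -> RiskScoreAssignment:
    """Assign the unweighted two-variant ABCB1/LILRB5 risk-score level.

    Level 0 (protected): ABCB1 rs1045642 CC together with LILRB5
    rs12975366 CC or TC. Level 1 (at risk): ABCB1 CT or TT together with
    LILRB5 TT. Under ``mode="strict"`` the five discordant genotype pairs
    are intermediate (level None) and drop out of the binary contrast;
    under ``mode="complement"`` every non-protected pair is level 1.
    Missing calls are unassigned in either mode.
    """
    if mode not in ("strict", "complement"):
        raise ValueError(f"unknown risk-score mode: {mode!r}")
    g_abcb1 = genotype_class(abcb1_pair)
    g_lilrb5 = genotype_class(lilrb5_pair)
    if g_abcb1 is None or g_lilrb5 is None:
        return RiskScoreAssignment(patient_id, None, g_abcb1, g_lilrb5)
    if g_abcb1 in _ABCB1_PROTECTED and g_lilrb5 in _LILRB5_PROTECTED:
        level: int | None = 0
    elif g_abcb1 in _ABCB1_RISK and g_lilrb5 in _LILRB5_RISK:
        level = 1
    else:
        level = None if mode == "strict" else 1
    return RiskScoreAssignment(patient_id, level, g_abcb1, g_lilrb5)


def risk_score_levels(abcb1_counts: pd.Series, lilrb5_counts: pd.Series,
                      mode: str = "strict") -> pd.Series:
    """Vectorised risk-score levels from protective-allele counts.

    `abcb1_counts` counts the C allele at rs1045642 (protected iff 2);
    `lilrb5_counts` counts the C allele at rs12975366 (protected iff >= 1).
    Returns 0.0 / 1.0 / NaN aligned to the inputs.
    """
    if mode not in ("strict", "complement"):
        raise ValueError(f"unknown risk-score mode: {mode!r}")
    a = pd.Series(abcb1_counts, dtype=float)
    b = pd.Series(lilrb5_counts, dtype=float)
    protected = (a == 2) & (b >= 1)
    at_risk = (a <= 1) & (b == 0)
    level = pd.Series(np.nan, index=a.index)
    if mode == "complement":
        level[a.notna() & b.notna()] = 1.0
    else:
        level[at_risk] = 1.0
    level[protected] = 0.0
    return level


def protective_indicator(levels: pd.Series) -> pd.Series:
    """Recode levels for regression: 1 = protected (level 0), 0 = at risk.

    With this coding a positive coefficient means the protected group
    achieves a greater cholesterol reduction.
    """
    out = pd.Series(np.nan, index=levels.index)
    out[levels == 0] = 1.0
    out[levels == 1] = 0.0
    return out


def genotype_qc_table(genotypes: pd.DataFrame, variants: Iterable[VariantInfo]) -> pd.DataFrame:
    """Per-variant QC summary: call rate, MAF, HWE chi-square and p-value."""
    rows = []
    for v in variants:
        calls = genotypes.loc[genotypes["rsid"] == v.rsid, ["allele1", "allele2"]]
        n_total = len(calls)
        counts = allele_counts(calls, v.minor_allele).dropna()
        n_called = len(counts)
        if n_called == 0:
            rows.append({"rsid": v.rsid, "gene": v.gene, "n_called": 0, "call_rate": 0.0,
                         "maf": np.nan, "hwe_chi2": np.nan, "hwe_p": np.nan})
            continue
        triple = (int((counts == 0).sum()), int((counts == 1).sum()), int((counts == 2).sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MonomorphicVariantWarning)
            chi2, pval = hwe_chi_square(*triple)
        rows.append({
            "rsid": v.rsid,
            "gene": v.gene,
            "n_called": n_called,
            "call_rate": n_called / n_total if n_total else 0.0,
            "maf": counts.sum() / (2 * n_called),
            "hwe_chi2": chi2,
            "hwe_p": pval,
        })
    return pd.DataFrame(rows)


def genotypes_to_counts(genotypes: pd.DataFrame, variants: Iterable[VariantInfo]) -> pd.DataFrame:
    """Pivot the long genotype table to one row per patient with a
    `<rsid>_count` column of protective-allele counts per variant."""
    wide = pd.DataFrame({"patient_id": genotypes["patient_id"].unique()})
    for v in variants:
        calls = genotypes[genotypes["rsid"] == v.rsid]
        counts = allele_counts(calls[["allele1", "allele2"]], v.protective_allele)
        col = pd.DataFrame({"patient_id": calls["patient_id"].values,
                            f"{v.rsid}_count": counts.values})
        wide = wide.merge(col, on="patient_id", how="left")
    return wide
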