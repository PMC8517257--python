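"""Derive the statin-response phenotype table.

Reads the simulated prescribing/laboratory/demographic tables, applies
the baseline (nearest before initiation) and follow-up (earliest within
28-180 days) selection rules, computes absolute and percent non-HDL-C
reduction and the statin-usage covariates, and prints the cohort
description alongside the attrition cascade.
"""

from pathlib import Path

from statin_pgx.io import read_demographics, read_genotypes_csv, read_labs, read_prescriptions
from statin_pgx.phenotyping import derive_phenotypes
from statin_pgx.pipeline import compute_attrition

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    rx = read_prescriptions(IN / "prescriptions.csv")
    labs = read_labs(IN / "labs.csv")
    demo = read_demographics(IN / "demographics.csv")
    geno = read_genotypes_csv(IN / "genotypes.csv")

    pheno = derive_phenotypes(rx, labs, demo)
    pheno.to_csv(OUT / "phenotypes.csv", index=False)

    att = compute_attrition(rx, labs, pheno, geno)
    print("attrition:", att.to_dict())

    p = pheno
    print(f"\nanalysis cohort: n={len(p)}")
    print(f"  baseline non-HDL-C     {p['baseline_nonhdl'].mean():.2f} "
          f"({p['baseline_nonhdl'].std():.2f}) mmol/L")
    print(f"  post-statin non-HDL-C  {p['followup_nonhdl'].mean():.2f} "
          f"({p['followup_nonhdl'].std():.2f}) mmol/L")
    print(f"  absolute reduction     {p['absolute_reduction'].mean():.2f} "
          f"({p['absolute_reduction'].std():.2f}) mmol/L")
    q = p["percent_reduction"].quantile([0.25, 0.5, 0.75])
    print(f"  percent reduction      median {q[0.5]:.1f}% (IQR {q[0.25]:.1f}-{q[0.75]:.1f})")
    print(f"  duration               {p['duration_periods'].mean():.2f} "
          f"({p['duration_periods'].std():.2f}) 28-day periods")
    print(f"  adherence (PDC)        {p['pdc'].mean():.2f} ({p['pdc'].std():.2f})")
    print(f"  switchers              {p['switched'].mean():.1%}")
    print(f"  first statin simva     {(p['first_statin_type'] == 'simvastatin').mean():.1%}"
          f" / atorva {(p['first_statin_type'] == 'atorvastatin').mean():.1%}")
    print(f"\nphenotypes -> {OUT / 'phenotypes.csv'}")


if __name__ == "__main__":
    main()
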