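"""Genotype QC for the seven-variant ADR panel.

Computes per-variant call rate, minor-allele frequency, and the 1-df
Pearson Hardy-Weinberg chi-square; all variants should sit near their
configured frequencies and show no HWE departure (the generator draws
genotypes under HWE, which is exactly what a clean genotyping batch
should look like).
"""

from pathlib import Path

from statin_pgx.genetics import genotype_qc_table
from statin_pgx.io import load_variant_metadata, read_genotypes_csv

IN = Path("results/analysis/inputs")
OUT = Path("results/analysis")


def main() -> None:
    geno = read_genotypes_csv(IN / "genotypes.csv")
    qc = genotype_qc_table(geno, load_variant_metadata())
    qc.to_csv(OUT / "genotype_qc.csv", index=False)
    print(qc.round({"call_rate": 3, "maf": 3, "hwe_chi2": 2, "hwe_p": 3}).to_string(index=False))
    flagged = qc[qc["hwe_p"] < 0.05 / len(qc)]
    print(f"\nvariants failing Bonferroni HWE check: {len(flagged)}")
    print(f"qc table -> {OUT / 'genotype_qc.csv'}")


if __name__ == "__main__":
    main()
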