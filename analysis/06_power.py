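"""Post hoc minimum-detectable-difference bounds.

Closed-form MDD for genotype contrasts on the absolute non-HDL-C
reduction (SD 1.04 mmol/L) at two-sided alpha 0.05 and 80% power,
across the panel's allele frequencies — including the low-frequency
recessive case (MAF 0.16) where detectability degrades to ~0.2 mmol/L.
"""

from pathlib import Path

import pandas as pd

from statin_pgx.power import PowerQuery, minimum_detectable_difference

OUT = Path("results/analysis")
N = 9401
SD = 1.04


def main() -> None:
    rows = []
    for maf in (0.48, 0.42, 0.40, 0.16, 0.07, 0.05):
        for model in ("dominant", "recessive"):
            q = PowerQuery(total_n=N, maf=maf, genetic_model=model, outcome_sd=SD)
            try:
                mdd = minimum_detectable_difference(q)
            except ValueError:
                mdd = float("nan")
            rows.append({"maf": maf, "model": model,
                         "exposed_fraction": round(q.exposed_fraction, 4),
                         "mdd_mmol_per_l": round(mdd, 4)})
    grid = pd.DataFrame(rows)
    grid.to_csv(OUT / "power_grid.csv", index=False)
    print(f"assumptions: N={N}, outcome SD={SD} mmol/L, two-sided alpha=0.05, power=0.80")
    print(grid.to_string(index=False))
    rec16 = grid.query("maf == 0.16 and model == 'recessive'")["mdd_mmol_per_l"].iloc[0]
    print(f"\nrecessive contrast at MAF 0.16: MDD = {rec16:.2f} mmol/L "
          f"(~0.2 to one decimal) — effects of that size or larger are detectable;")
    print("common variants (MAF > 0.42) support detection down to ~0.06-0.07 mmol/L.")
    print(f"grid -> {OUT / 'power_grid.csv'}")


if __name__ == "__main__":
    main()
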