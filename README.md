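# statin-pgx

Statin pharmacogenetics from longitudinal electronic health records:
does carrying statin-intolerance risk variants change how much a
patient's cholesterol actually falls on therapy?

The package implements the full analysis chain for that question —
phenotype derivation from raw prescribing and laboratory tables,
genotype QC and model encoding, staged regression adjustment, a
two-variant risk score with a synergy contrast, and post hoc
detectability bounds — together with a synthetic-EHR generator so every
stage runs, and is validated, without access to any real patient data.

## The science in brief

**Outcome.** Statin response is the reduction in non-HDL cholesterol
(non-HDL-C = total cholesterol − HDL-C, mmol/L): baseline is the
nearest measurement before the first statin dispense, follow-up the
earliest measurement 28–180 days after it, and the response is
Δ = baseline − follow-up (also expressed as 100·Δ/baseline %).

**Exposure.** Seven candidate variants with prior statin-ADR evidence
(*ABCB1* rs1128503, rs1045642; *SLCO1B1* rs4149056, rs2306283;
*LILRB5* rs12975366; *CYP3A4* rs2740574; *CYP3A5* rs776746), each
tested under additive, dominant and recessive codings of its
protective allele, with Hardy–Weinberg QC.

**Models.** OLS regression of Δ on the genotype coding, staged:

* Model 1 — univariate;
* Model 2 — + statin-intolerance features: adherence (PDC), statin
  switching, dose reduction;
* Model 3 — + mean simvastatin-equivalent daily dose, therapy duration
  in 28-day pack periods, type-2 diabetes, prior MACE, baseline
  non-HDL-C.

PDC (proportion of days covered) is dispensed supply over the
first-to-last-script day span, deliberately uncapped so stockpiling is
visible (cohort mean ≈ 1.5).

**Risk score and synergy.** The two positive loci combine into an
unweighted score: *protected* = rs1045642 CC **and** rs12975366 CC/TC;
*at risk* = rs1045642 CT/TT **and** rs12975366 TT; discordant pairs are
intermediate. Synergy is measured as the combined protected-vs-risk
contrast minus the sum of the two single-variant effects (the
*expected additive* effect); a positive excess means the loci reinforce
each other.

**Power.** For a genotype contrast with exposed fraction *f* from HWE
(maf² recessive, 1−(1−maf)² dominant), the minimum detectable
difference is MDD = (z₁₋α/₂ + z_power)·σ·√(1/n₁ + 1/n₂).

## Worked example

The numbered drivers under `analysis/` run the whole study on a
simulated 9,401-patient cohort:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_derive_phenotypes.py
python analysis/03_genotype_qc.py
python analysis/04_association_models.py
python analysis/05_synergy.py
python analysis/06_power.py
python analysis/07_parameter_recovery.py
```

Step 02 prints the derived cohort description (seed 1):

```
analysis cohort: n=9401
  baseline non-HDL-C     4.45 (1.18) mmol/L
  post-statin non-HDL-C  2.95 (1.55) mmol/L
  absolute reduction     1.50 (1.04) mmol/L
  percent reduction      median 34.2% (IQR 17.8-52.7)
  duration               2.89 (1.30) 28-day periods
  adherence (PDC)        1.58 (0.77)
  switchers              2.7%
  first statin simva     75.5% / atorva 19.3%
```

i.e. the phenotyping stage recovers the distributions the generator
injected (baseline 4.43 ± 1.19, reduction SD 1.04, adherence
1.54 ± 0.79, 3% switchers). Step 04 finds the injected *ABCB1*
recessive effect (fitted 0.08, 95% CI 0.03–0.13 mmol/L under the
fully adjusted model) while the five null variants stay null, and
step 06 prints the detectability grid — a recessive contrast at MAF
0.16 has MDD ≈ 0.19 mmol/L (≈ 0.2), versus ≈ 0.06–0.07 mmol/L for
common variants (MAF > 0.42).

The same machinery is scriptable (`statin-pgx simulate|phenotype|
associate|power|run`) and usable as a library:

```python
from statin_pgx import SimConfig, simulate_cohort, derive_phenotypes

cohort = simulate_cohort(SimConfig(n_patients=2000, seed=7))
pheno = derive_phenotypes(cohort.prescriptions, cohort.labs, cohort.demographics)
```

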