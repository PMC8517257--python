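# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the design choices where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Phenotype model

Statin response is the change in non-HDL cholesterol
(total − HDL, mmol/L) between a pre-treatment baseline and an early
on-treatment follow-up:

* **Baseline** — the measurement with the latest date on or before the
  first statin dispense ("nearest before"). No look-back limit by
  default; `PhenotypeConfig.max_lookback_days` can impose one.
  Same-day duplicate assays are averaged — no ordering rule is
  defensible for ties, and averaging is order-independent.
* **Follow-up** — the earliest measurement in the *closed* window
  28–180 days after initiation. "Between 28 and 180 days" is read
  inclusively at both ends.
* **Response** — Δ = baseline − follow-up, positive = improvement;
  percent response = 100·Δ/baseline, defined only for positive
  baselines (non-positive baselines are invalid records and are
  excluded, counted in the attrition report).

Statin-usage covariates are computed over scripts dispensed strictly
before the follow-up measurement:

* **Switching** — more than one distinct statin type.
* **Simvastatin-equivalent dose** — daily dose × a per-statin potency
  ratio from a packaged, editable YAML (defaults: atorvastatin ×2,
  rosuvastatin ×4, pravastatin ×0.5, fluvastatin ×0.5; simvastatin
  identity). Published equivalence tables differ, so the ratios are
  configuration, never constants in code.
* **Dose change flags** — any strict decrease (resp. increase) between
  consecutive equivalent daily doses; both can be true. Comparing on
  the equivalence scale means a switch at constant potency is not a
  dose change — dose reduction is meant to proxy intolerance, which is
  potency-relative. Dose increase is computed but is not a default
  model covariate (only dose reduction enters Models 2–3; a toggle
  adds the increase flag).
* **Duration** — days from initiation to the follow-up lab ÷ 28
  (the standard pack period). The follow-up lab, not the last script,
  is the endpoint.
* **PDC** — Σ(quantity/directions) over scripts in [first, last)
  divided by the first→last day span, with the final script's supply
  excluded (it covers days beyond the span) and **no cap at 1**:
  early refills push PDC above 1, and the cohort-mean adherence of
  ~1.5 requires that to be representable. A patient with a single
  qualifying script gets supply ÷ (follow-up − dispense) days, flagged
  `pdc_imputed`. By default PDC uses only scripts before the follow-up
  lab (`pdc_before_followup=False` switches to the full history).

Phenotyping is pure: identical input tables give identical outputs
regardless of row order.

## Genetics

Encodings count a designated **protective allele** per variant —
recorded independently of which allele is the population minor allele
(the *ABCB1* rs1045642 protective C allele sits near 0.5 frequency).
Additive = allele count (0/1/2), dominant = carrier indicator,
recessive = homozygote indicator; missing calls propagate as NaN and
are deleted pairwise per model (each variant's models use all patients
with that call).

HWE is tested with the plain 1-df Pearson chi-square at the sample
allele frequency, no continuity correction; a conditional exact test
is available as an option. Monomorphic variants return (0, 1) with a
warning rather than an error.

The two-SNP risk score assigns level 0 (protected: rs1045642 CC and
rs12975366 CC/TC) and level 1 (at risk: rs1045642 CT/TT and
rs12975366 TT). Only 4 of the 9 two-locus genotype classes are covered
by those definitions; how the remaining 5 (discordant) classes were
handled in the original analysis is ambiguous — the reported score n
is close to the full genotyped cohort, suggesting they were *not*
dropped, yet the level definitions exclude them. Both readings are
implemented: `strict` (discordant → intermediate, excluded from the
binary contrast) and `complement` (level 0 vs everything else). The
default is `strict`, and the run log records the mode and the number
of patients assigned a level so the choice is auditable.

## Regression layer

All fits are OLS (statsmodels) with complete cases per model, t-based
95% CIs on residual degrees of freedom, and an explicit
rank-deficiency check: singular designs raise an error naming the
collinear columns (identified by pivoted QR) instead of silently
dropping terms. Covariate sets are nested (Model 1 ⊂ 2 ⊂ 3). The
percent-reduction outcome is summarised descriptively by median/IQR
but modelled by ordinary linear regression, so both pathways exist.

Genetic-model selection fits all three encodings univariately and
picks the smallest genotype p-value; a literature prior (packaged
metadata pins *ABCB1* → recessive, *LILRB5* → dominant, etc.)
overrides the data-driven pick while all per-encoding results remain
reported. Encodings that are degenerate in a given cohort (e.g. no
minor-allele homozygotes for a rare recessive coding) are skipped and
logged.

The interaction test adds the product of the two encoded variants to a
model containing both main effects. The synergy contrast fits the two
single-variant models and the score-contrast model under identical
outcome and covariates; expected-additive = sum of the single
estimates, synergy excess = combined − expected (an exact arithmetic
identity on the fitted coefficients).

The Bonferroni threshold is α/(n_snps·n_models); with 7 SNPs × 3
models and α = 0.05 the exact value 0.00238 is conventionally reported
to three decimals as 0.002.

## Power

The minimum detectable difference uses the two-sample normal
approximation with HWE group fractions (recessive f = maf², dominant
f = 1−(1−maf)²):

MDD = (z₁₋α/₂ + z_power)·σ·√(1/(fN) + 1/((1−f)N))

Defaults are two-sided α = 0.05 and 80% power — the assumptions are
explicit `PowerQuery` parameters and are printed by the CLI because
the choice of power level and genetic model materially changes the
bound. Reproduction of the ~0.2 mmol/L bound for a MAF-0.16 recessive
contrast at N = 9,401/σ = 1.04 is asserted to one decimal only, as no
finer precision is defensible. An expected group below 2 patients
raises an infeasible-group error. A Monte-Carlo cross-check
(`empirical_power`) verifies the closed form by simulation.

## Synthetic-EHR generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions:

| parameter | default | meaning |
|---|---|---|
| baseline_mean / sd | 4.43 / 1.19 mmol/L | pre-treatment non-HDL-C |
| reduction_mean / sd | 1.45 / 1.04 mmol/L | absolute reduction and its noise SD |
| adherence_mean / sd | 1.54 / 0.79 | latent PDC, normal truncated at 0 |
| adherence_effect | 0.26 mmol/L per PDC unit | adherence→response slope |
| statin_mix | 0.747 / 0.194 / 0.059 | simvastatin / atorvastatin / other |
| switch_prob | 0.03 | statin switchers |
| dose_reduction / increase_prob | 0.49 / 0.62 | dose-change rates |
| t2d_prev, mace_prev | 0.714, 0.186 | comorbidity flags |
| t2d_effect, mace_effect | −0.13, −0.04 mmol/L | comorbidity effects on response (centred) |
| follow-up window | 28–180 d, median ≈ 75 | lognormal(log 75, 0.6), rejection-truncated |
| baseline lab offset | median ≈ 12 d before | lognormal(log 12, 1.587) |

The outcome model is linear on the absolute-reduction scale:

Δ = μ + Σ_v β_v·enc_v + γ·1[both interaction variants protective]
  + λ·(PDC − PDC̄) + centred comorbidity terms + ε,  ε ~ N(0, σ²)

Genotypes are binomial(2, maf) per variant (exactly HWE), and the
default seven-variant panel injects the two study-positive effects
(recessive 0.09, dominant 0.04 mmol/L) with a two-locus bonus of
γ = 0.01 mmol/L, making the protected-vs-risk score contrast
0.09 + 0.04 + 0.01 = 0.14 mmol/L; the other five variants are null.
Percent-scale effects arise implicitly from the absolute-scale
injection. Adherence, switching and dose changes are generated
independently of each other and of genotype — no correlation structure
among them is assumed, because none is documented; this is a stated
simplification, not a claim about real behaviour.

Event streams: dispensing every 28 days (eight scripts from
initiation), quantities ≈ 28·directions·adherence with mean-one
lognormal jitter (σ = 0.15), so the PDC recomputed by the phenotyping
stage tracks the latent adherence (r > 0.9 at defaults, verified).
Switchers change statin type, at potency-equivalent strength, at a
script strictly before the follow-up lab; when the follow-up falls
inside the first pack period an extra mid-period dispense carries the
switch, so the realised switcher fraction equals `switch_prob`. Dose
changes double or halve the strength from a random pre-follow-up
script onward; when a doubling and a halving collide on the same
script they cancel, so realised dose-change rates sit somewhat below
their probabilities (acceptable: no analysis property depends on those
rates). Lipid panels draw HDL ~ N(1.35, 0.25²) (floored at 0.4) and
set total = non-HDL + HDL.

Two numerical guards in the event path: baseline draws are truncated
at 0.5 mmol/L, and follow-up lab values are floored at 0.05 mmol/L so
emitted lipid panels always satisfy total ≥ HDL ≥ 0. The floor touches
the few per cent of patients whose latent follow-up would go
non-positive and attenuates genotype effects recovered *through the
event path* by a comparable relative amount. Many-replicate studies
(parameter recovery, calibration suites) therefore use the
generator's direct outcome-model path (`simulate_analysis_table`),
which shares the identical latent model without the lab-materialisation
floor — this is also orders of magnitude faster, which is what makes
hundreds of replicates routine. The two paths are verified against
each other in the test suite. A consequence of the same design: the
marginal SD of the realised reduction slightly exceeds `reduction_sd`
whenever covariate effects are switched on (they add variance), so
moment-convergence checks are run under a null configuration where
the equality is exact.

The `truth` table (latent adherence, encodings, injected effects) is
retained for test assertions only; analysis modules never read it.

What passing tests on this generator do **not** show: robustness to
irregular dispensing cadences, informative lab timing, genotype–
adherence correlation, measurement error in lipid assays, or
population stratification. None of these are modelled.

## Replicate studies and problem sizes

Parameter recovery regenerates 200 cohorts per study at the study's
cohort sizes (n = 8,843 single-variant; n = 8,070 two-variant) and
compares the mean univariate estimate with the injected effect within
two Monte-Carlo SEs. Calibration suites use 2,000 replicates
(interaction type-I error at n = 1,000; HWE rejection at n = 1,000)
and 100 replicates for the null synergy centring at n = 4,000 — sizes
chosen to keep Monte-Carlo error well inside the asserted bands while
the whole suite stays fast.

## Known limitations

* Cohort assembly from raw hospital/ICD streams is out of scope;
  comorbidities are taken as given binary flags.
* No haplotype or imputation work; the *ABCB1* rs2032582 haplotype is
  deliberately not modelled.
* The attrition emulation reproduces the *structure* of the exclusion
  cascade, not the original counts (the generator gives every patient
  qualifying labs by construction; attrition becomes informative on
  degraded inputs).
* Reported percent-scale synergy depends on the strict-vs-complement
  score choice; the strict default discards more than half the cohort
  as intermediate, which is visible in the run log.
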