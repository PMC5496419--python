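# Methods

This note documents the models and procedures implemented in
`traumascore`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish.

## Scores and coding conventions

The code-value tables bin integer readings (e.g. SBP "76–89" → 3). For
real-valued inputs every band is closed at its printed lower endpoint and
open at the next one: RTS SBP code 3 is [76, 90), NTS SBP code 4 is
[110, 150). This closes the real-number gaps the integer tables leave
open (89.5, 149.5, …) while agreeing with the printed table on every
integer. The ">89 → 4" and ">29 → 3" rows are realised as [90, ∞) and
[30, ∞), so 89.5 → 3 and 29.5 → 4.

Two distinct SpO2 absences are kept apart end to end: a value missing
from the record (imputed downstream) versus a *non-measurable* saturation
(CSV sentinel `NM`), which almost always reflects profound shock or
arrest and is therefore coded 0 — the lowest category — by default
(`nm_spo2_zero=False` leaves it missing instead).

The NTS is reported to 4 dp internally and 2 dp in human-readable output.
Arithmetic on the published 4-dp coefficients gives score extremes
1.2018–10.6858; the published extremes (1.2019, 10.6867) evidently come
from unrounded internal coefficients, so agreement is asserted to 1e-3
and the 4-dp coefficients are treated as canonical.

MGAP and GAP points follow their source publications and are frozen in
`MGAP_POINTS` / `GAP_POINTS`: MGAP adds the GCS, 5 for age < 60, 4 for
blunt mechanism and 5/3/0 for SBP ≥120 / 60–119 / <60; GAP adds the GCS,
3 for age < 60 and 6/4/0 for SBP >120 / 60–120 / <60. Secondary sources
disagree on whether GAP's upper SBP band includes 120 exactly; here
SBP = 120 falls in the middle band (threshold "> 120").

## Outcome orientation

All regressions model **survival** (1 = survived in-hospital). This makes
the published signs coherent: odds ratios above 1 for more favourable
physiology, a negative intercept, and Ps directly interpretable as
predicted survival. Triage positivity for survival-oriented scores is
`score < threshold`; undertriage is 1 − sensitivity and overtriage
1 − specificity at that rule.

## Statistical machinery

**Logistic regression** is fitted by IRLS (via a binomial GLM), with the
covariance taken from the observed information. Perfect or
quasi-separation is detected (diverging estimates or fitted probabilities
pinned at 0/1) and raised as an explicit error rather than returned as a
spuriously converged fit. Wald 95% intervals are used for coefficients
and odds ratios.

**AUC** uses the midrank (Mann–Whitney) convention: the probability a
random event-case outranks a random non-case, ties counted one half. Unit
tests pin it to an O(n²) pair-counting oracle to 1e-12.

**DeLong's test** for paired ROC curves computes placement values
(structural components) by midranks, the 2×2 covariance of the two
scores' components within cases and controls, and a two-sided z-test on
the AUC difference with a 95% Wald interval. With identical score vectors
the variance is zero and the degenerate result (difference 0, p = 1) is
returned explicitly. No multiplicity adjustment is applied to pairwise
comparisons, matching common reporting practice.

**Hosmer–Lemeshow.** χ² = Σ_g (O_g − E_g)² / (E_g(1 − p̄_g)) over g
equal-count risk groups, df = g − 2. Grouping is the one genuinely open
choice. The default (`ties="split"`) forms g equal-count groups by rank,
splitting tied predictions across boundaries, so g stays at `n_groups`;
a 1000-replicate null calibration on refitted well-specified models at
n = 3263 rejects at 5.0% at the nominal 5% level. The alternative
(`ties="merge"`, quantiles of the predictions with ties kept together) is
what much clinical software reports, but for heavily tied scores like the
NTS (one dominant healthy profile) the deciles collapse — to g = 5 here —
and the χ²_{g−2} reference becomes conservative (2.75% empirical
rejection over 2000 replicates). With g = 2 the classical df is 0 and the
p-value is reported as NaN. Note the nominal-rate guarantee is a property
of *refitted* models; scoring known-true probabilities shifts the null
toward χ²_g.

**Operating points** maximise specificity among thresholds whose
sensitivity meets the target (default 95%), found by an exhaustive sweep
over distinct score values; when only the all-positive rule qualifies it
is flagged as such.

**Cohort description** uses median (IQR) with the asymptotic tie-corrected
Mann–Whitney U test for continuous variables and n (%) with the χ² test
for categorical ones.

## Multiple imputation

MICE with predictive mean matching imputes SBP, RR, GCS, SpO2 and ISS
conditional on age, sex, the outcome and each other (mechanism is not in
the imputation model). Defaults: m = 10 completed datasets — chosen to
exceed the largest missingness fraction in percent (ISS, 8.9%) — 10
chain iterations, and a donor pool of the k = 5 observed values with the
nearest predicted means. Chains are run independently with seeds derived
from a single user seed, so results are bit-reproducible and chains are
mutually independent. PMM guarantees every imputed value is an observed
donor value, preserving integer variables and observed ranges.
Non-measurable SpO2 is held at 0 in the imputation model (it is known,
not missing) and restored afterwards. Regression coefficients across
completed datasets are pooled by Rubin's rules (total variance =
mean within-imputation variance + (1 + 1/m) × between-imputation
variance); rank-based quantities such as AUCs are instead computed
per-imputation and summarised by their median, since Rubin pooling is
defined for approximately normal estimators, not for ROC areas.

## Synthetic cohort generator

The generator emulates a single-centre adult blunt-trauma cohort with the
marginals a derivation registry of this kind exhibits: age median 60
(IQR 46–73), 66% male, 94.4% blunt, SBP median 130 (110–140) mmHg, RR
median 20 (18–20), GCS median 15, SpO2 median 98% (96–99), ISS median 9,
and MCAR missingness at the reported per-variable rates (ISS 8.9%, SpO2
3.2%, ≤0.1% for SBP/RR/GCS).

Covariates are drawn from a two-component mixture rather than independent
marginals, so deranged vitals co-occur: a *stable* component concentrated
at normal physiology produces the degenerate medians, and an *injured*
component has depressed GCS/SpO2 and dispersed SBP, including an explicit
hypertensive (≥150 mmHg) tail. Survival is Bernoulli(Ps) under the
published NTS coefficients, so the generator's outcome law is exactly the
model the derivation machinery should recover, and the higher mortality
of the ≥150 band relative to 110–149 emerges from the code-3-vs-4 gap
alone, with no extra model term. The mixing weight (`severe_fraction =
0.20`) was calibrated once against the 11.3% in-hospital mortality target
and frozen; 200 replicates at n = 3263 give mean mortality ≈ 11.35%.
ISS is a severity-correlated lognormal ordinal draw used only as an
imputation covariate; no anatomical meaning is claimed.

What the generator does *not* reproduce: real registries have
measurement error, informative (non-MCAR) missingness, covariate effects
outside the score (age, comorbidity, mechanism), and deaths among
normal-vitals patients driven by anatomy rather than physiology. Because
the outcome here is exactly the NTS model, score discrimination is high
by construction (NTS AUC ≈ 0.92 at cohort size) and comparisons between
scores favour the NTS; passing tests establish the correctness and
calibration of the *machinery*, not the clinical performance figures of
any score. One visible consequence: deaths inside the dominant
(GCS 15, normal-vitals) profile are indistinguishable from survivors, so
T-NTS sensitivity above ~92% is attainable only by the all-positive rule
on synthetic data, and fixed-sensitivity comparisons are exercised at
targets the cohort supports (80–90%) plus the degenerate 95% case.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200,000
patients for parameter recovery (each coefficient recovered within 3
fitted SEs), 200 cohorts of n = 3263 for the mortality average, 2000
replicates of n = 500 for DeLong null calibration, 500 replicates of
n = 3263 for Hosmer–Lemeshow calibration, and 50 replicates of n = 400
for MCAR mean-recovery of the imputation. These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping the full suite
around a minute on one CPU.

## Known limitations

- The registry reader validates hard physiological invariants only; it
  does not check internal consistency (e.g. an ISS implying death).
- The cohort filter supports optional `dead_on_arrival` / `ed_discharge`
  boolean columns, but disposition coding varies across registries and no
  attempt is made to infer it.
- Separation detection is heuristic (diverging norms / pinned fitted
  probabilities); penalised (Firth) fits are not provided.
- No bootstrap CIs for single AUCs, no net-reclassification or
  decision-curve analysis, and no survival-time modelling — the outcome
  is binary in-hospital death.
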