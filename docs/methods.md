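# Methods

`locumcompare` re-creates, end to end, an observational comparison of locum
and permanent GPs in English primary care: consultation-level clinical
practice outcomes, prescribing-safety indicators evaluated over longitudinal
event streams, and multilevel logistic models for the locum exposure. Because
the real data source (a CPRD-GOLD-style extract with hospital linkage) is
access-restricted, the package ships a synthetic generator with a retrievable
ground truth, and every downstream stage is validated against that truth or
against independent oracles.

## The generative model

Each consultation carries, for every outcome *o*, a Bernoulli event with

    logit(p) = a_o + b_o * locum + x' g + u_practice + u_patient

where `a_o` is the outcome intercept, `b_o` the locum log-odds contrast, `x`
standardised covariates with shared effects `g`, and the `u` are independent
Gaussian random intercepts (SDs `practice_sd`, `patient_sd`, log-odds scale).
Covariates enter on interpretable scales: (age−45)/10, female indicator,
multimorbidity score, deprivation quintile−3, (years registered−15)/10,
(list size−7000)/3500, and financial year centred on the window midpoint.

Defaults encode the study conditions of the source setting: intercepts at the
observed permanent-GP outcome rates (revisit 8.2%, antibiotics 9.0%, strong
opioids 2.3%, hypnotics 0.9%, referrals 4.3%, tests 3.2%, hospital outcomes
0.15–0.39%), locum contrasts at the observed adjusted odds ratios (antibiotics
1.21, revisits 0.88, tests 0.80, ...), 10% locum staffing among GP
consultations, and covariate distributions matching the observed cohort
(age 46 (SD 23.7), 55% female, multimorbidity 0.46, 16.4 years registered,
list size 7,020 (3,493), rurality 1.16). Consultation counts per patient-year
are Poisson (default mean 4) with dates uniform over each patient's active
period; staffing is per-consultation Bernoulli, optionally confounded with
multimorbidity via `locum_confounding` so tests can separate confounded and
unconfounded regimes. Locum role is per-consultation; placement length
(short- vs long-term locums) is deliberately not modelled.

Events materialise as records: prescriptions become therapy rows coded from
synthetic codelists (real Read/BNF lists are drop-in replacements), tests and
referrals become consultation-linked event rows, hospital outcomes become
HES-like rows (ACSC admissions carry an ICD-10 primary code from the
configurable ACSC chapter registry), and a fired revisit inserts a follow-up
consultation 1–7 days later staffed by "other" so it can never enter an index
set. Indicator-relevant background prescribing (NSAIDs, gastroprotection,
anticoagulants, antiplatelets, beta-blockers, inhalers, antipsychotics) is
drawn per consultation at configurable rates so the indicator engine sees
non-degenerate at-risk sets.

What the generator does *not* emulate: informative staffing (who sees a locum
is random given multimorbidity at most), seasonality, repeat-prescription
structure, coding error, practice-level data-quality windows, or linkage
failure. Passing tests therefore demonstrate correctness of the pipeline's
logic and estimators under a known model — not robustness to the messiness of
real primary-care data.

Two emergent-rate caveats. The *marginal* event rate exceeds
`logit⁻¹(intercept)` whenever covariate or cluster effects are non-zero
(Jensen's inequality); rate-recovery tests therefore zero those effects.
And the revisit flag also fires from the organic consultation stream
(about 1−exp(−rate·7/365) ≈ 7% at the default rate), which attenuates the
observed revisit odds ratio toward 1 relative to `b_revisit`; parameter
recovery tests use a prescribing outcome, which has no such contamination.

## Cohort construction

Financial years run 1 April–31 March. Patients whose recorded *year* of death
precedes the study start year are excluded outright (year granularity,
matching how such deaths are recorded); consultations dated after the death
*date* are dropped individually; consultations of patients missing age or
gender are dropped. All removals are counted in `meta['exclusions']` and
logged, so the attrition cascade is auditable. A patient is active in a year
if the closed registration interval intersects it on at least one day.

Design 1 samples exactly one face-to-face GP consultation (locum or
permanent) per active patient per financial year, uniformly over the
patient's eligible consultations, with candidates pre-sorted by
(date, consultation id) and a per-year seeded draw so results are independent
of storage order and of which years are processed. Each year is drawn
independently. Design 2 keeps *all* face-to-face GP consultations satisfying
an indicator's index predicate, repeats included.

Age at index is financial-year start year minus birth year (day-level birth
dates are unavailable in the emulated source). The multimorbidity score is a
configurable weighted sum over condition flags recorded on or before the end
of the baseline calendar year (31 December of the study's first year) and is
held fixed thereafter. The shipped weights are simplified stand-ins on the
scale of published comorbidity weights, not the validated published values.

## Outcome windows

All day arithmetic is calendar-day differences with windows inclusive at both
ends. A revisit is any consultation — any staff role, any mode, telephone and
online included — 1..7 days after the index; day 0 is excluded so the index
(or a second same-day visit) never counts as its own revisit. Hospital
outcomes split into same-day (day 0) and days 1..7; an ACSC admission is an
emergency admission whose primary ICD-10 code starts with a registry prefix,
so it also fires the emergency-admission flag. Prescription, test and
referral outcomes are records linked to the index consultation itself. The
hypnotic outcome is the union of the benzodiazepine and z-drug lists.

## Prescribing-safety indicators

Indicators are declarative (`data/indicators.yaml`, overridable): an index
predicate defines the at-risk denominator and a trigger defines the
numerator. Windows: 91 days operationalises "the preceding 3 months" for
gastroprotection lookbacks (A, B, C, E, F) and the ICS lookback (H); 28-day
prescription coverage is the concurrency convention for drug combinations
(D, E, F); "more than 6 weeks" of antipsychotic exposure (J) means an episode
longer than 42 days, chaining prescriptions whose successive gaps are at most
a 28-day grace period. Condition histories (asthma, peptic ulcer, heart
failure, dementia, psychosis) are ever-recorded on or before the index date.

Three definitional choices were genuinely open and are resolved as follows,
guided by the published numerator/denominator magnitudes:

* **G and I** treat the prescription (non-selective beta-blocker; NSAID) as
  the index and the condition history (asthma; heart failure) as the trigger
  — the published denominators are far too large for the condition to be part
  of the at-risk predicate.
* **E** takes the antiplatelet prescription as the index with the
  anticoagulant as a concurrent coverage-window co-prescription. "In
  combination" is symmetric; this orientation keeps D's and E's at-risk sets
  disjoint, which also makes injected test fixtures exactly recoverable.
* **H** indexes standalone LABA prescriptions (combination LABA/ICS products
  are a separate codelist group) in patients with asthma, triggering when no
  ICS is co-prescribed at index or in the lookback.

Published rate cells that do not recompute from their own printed numerators
and denominators (indicator C locum, H permanent, I both) are treated as
typographical and excluded from verification. Rates render as percentages
with round-half-up at one decimal (two decimals in the descriptive table).

The scenario injector plants known triggered/mitigated cases on distinct
clean host patients, attaching supporting prescriptions to "other"-staff
consultations so only the intended index event enters a denominator. Exact
count recovery holds per indicator on bundles without organic
indicator-relevant prescribing; the indicator set itself overlaps (every
NSAID index event for A or B is also in I's denominator), so recovery is
asserted on per-indicator fixtures.

## Models

Both designs are mixed-effects logistic regressions for the locum exposure,
adjusted for gender, age, multimorbidity, years registered, list size and
deprivation quintile (ordinal by default, configurable to categorical), with
region and financial-year fixed-effect indicators; design 1 adds practice
random intercepts, design 2 practice and patient-within-practice intercepts.
Non-binary covariates are standardised internally for conditioning; the locum
coefficient is unaffected.

The fitter (`glmm.py`) maximises the Laplace-approximated marginal likelihood
in two stages: a fast penalised-likelihood stage over (fixed effects, random
effects) for starting values, then L-BFGS-B over (fixed effects, log SDs)
with the random effects profiled by inner Newton iterations — the same
scheme as standard Laplace (nAGQ=1) mixed-model software, with which it
agrees to about 10⁻³ on fixed effects in our checks (tested at 0.01
tolerance). Standard errors come from the fixed-effects block of the inverse
joint observed information at the optimum, conditional on the estimated
variances. Wald CIs default to the 95% level the published tables print;
significance flags additionally honour the declared 1% alpha, and both are
reported. Separation or non-convergence is flagged on the result
(`converged=False`, infinite CI bounds possible) and single-class outcomes
raise an estimation error — never a silent fallback. Variance SDs are
box-constrained to [10⁻⁴, 8] on the log scale; a boundary solution at the
lower bound reproduces the plain logistic fit.

The sensitivity interface refits every model on the table restricted to a
subset of financial years (e.g. dropping the final three pandemic-period
years) and reports full-vs-restricted pairs.

## Problem sizes and numerical checks in the test suite

Oracle equivalence runs 50 random bundles of a few hundred events each
against a deliberately naive row-scanning oracle. Parameter recovery and
type-I error use the stated design — 100 practices × 50 patients × 1 year,
antibiotic prescribing at its 9% base rate, 10% locum share — over 200
replicates each (about two minutes apiece on one CPU); recovery asserts mean
log-OR within ±0.02 of 0.2 and 95% CI coverage in [0.92, 0.98], and type-I
asserts the 5%-level rejection count inside the exact central 99% binomial
band. Reference agreement with an external Laplace GLMM implementation is
checked on six seeded datasets (five one-level, one two-level) at 0.01
log-odds. The demo pipeline (24 practices, ~3,600 patients, three years) is
run twice for byte-identical-output determinism. `scripts/acceptance.py`
reports a larger run (60 practices, ~15,000 patients, three years, ~220,000
consultations), chosen to keep the whole computation around a minute.

## Known limitations

* Synthetic codelists and multimorbidity weights are stand-ins; analyses of
  real extracts must supply the published lists and weights as files.
* Indicator windows beyond the worked 3-month example are package defaults,
  not published operational values; the registry file is the override point.
* The generator's shared covariate effects across outcomes and shared random
  intercepts are simplifications; they do not affect the validity of
  exposure-recovery tests but understate real between-outcome heterogeneity.
* At demo scales the rare hospital outcomes and condition-restricted
  indicators routinely yield single-class or separated fits; these surface as
  recorded failures rather than estimates, which is the intended behaviour.
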