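# locumcompare

Do temporary (locum) GPs practise differently from permanently employed GPs?
`locumcompare` is a tested, reusable pipeline for answering that question on
CPRD-GOLD-style primary-care records with hospital linkage: it builds twelve
consultation-level clinical-practice outcomes (practice revisit within 7
days; antibiotic, strong-opioid and hypnotic prescribing; same-day and 1–7
day A&E visits, emergency admissions and ACSC admissions; test ordering;
referrals), evaluates ten PINCER-style prescribing-safety indicators (A–J)
over longitudinal event streams, and estimates adjusted locum-vs-permanent
odds ratios with multilevel mixed-effects logistic regression.

Real extracts of this kind are access-restricted, so the package includes a
seeded synthetic-data generator that emulates the cohort structure — patients
nested in practices nested in regions, consultation streams with a staff-role
field, codelist-grouped prescriptions, diagnosis flags, hospital events and
deprivation quintiles — with a retrievable ground truth, making every stage
testable end to end.

## The model

For outcome *y* of an index consultation (one randomly sampled face-to-face
GP consultation per patient per financial year), the package fits

    logit P(y=1) = β₀ + β_locum·locum + x'γ + region + year + u_practice,
    u_practice ~ N(0, σ²)

reporting exp(β_locum) with Wald confidence intervals; `x` contains gender,
age, multimorbidity score, years registered, practice list size and
deprivation quintile. Indicator models use all at-risk index events (repeated
consultations) and add patient-within-practice random intercepts. Estimation
is maximum likelihood under the Laplace approximation (agreeing with lme4's
`glmer` to ~10⁻³ on fixed effects in the test suite).

An indicator is a declarative pair (index predicate, trigger): e.g. indicator
A's at-risk set is every consultation where an oral NSAID is prescribed to a
patient aged ≥ 65, and it triggers when no ulcer-healing drug was
co-prescribed at the consultation or in the preceding 91 days. Definitions,
windows and codelists are all file-overridable. See `docs/methods.md` for the
full conventions.

## Worked example

Run the whole pipeline on the shipped demo configuration (24 practices,
~3,600 patients, financial years 2010–2013):

```
locumcompare all --config src/locumcompare/data/demo_config.yaml --seed 7 --output demo_out
```

`demo_out/models/or_table.csv` then contains, among others (output from this
exact command):

```
         outcome                     rendered  converged  n_obs
      revisit_7d          1.11 (0.92 to 1.33)       True   8783
   rx_antibiotic          1.22 (0.99 to 1.51)       True   8783
        referral          0.94 (0.69 to 1.30)       True   8783
            test          0.84 (0.57 to 1.22)       True   8783
```

Each row is the adjusted locum odds ratio for one outcome with its 95% CI:
at this demo scale the antibiotic contrast (generative truth 1.21) is
estimated at 1.22 but rare outcomes are noisy — the revisit estimate (truth
0.88, attenuated by organic revisits) has a CI spanning 1. Outputs also
include a Table 1-style descriptive summary (`outcomes/table1.csv`), the
indicator numerators/denominators/rates per prescriber role
(`indicators/indicator_results.csv`), coefficient-plot data
(`models/plot_data.csv`), and a manifest with seeds and row counts; rerunning
with the same seed reproduces every file byte for byte. The same stages are
available programmatically (`generate_bundle`, `filter_eligible`,
`sample_index_consultations_all_years`, `build_outcome_table`,
`evaluate_indicator`, `fit_patient_level`, ...) and as individual subcommands
(`simulate`, `cohort`, `outcomes`, `indicators`, `fit`, `report`).

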