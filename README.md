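# concordkit

Race/ethnicity concordance and missingness analysis for linked EHR + census
cohorts.

## The problem

Electronic health records are increasingly used for population health
assessments, but the demographic identifiers they carry are often missing
(roughly one patient in five lacks race/ethnicity) and, where present, can
*disagree* with what the same person reports to a census or household survey
— because of practice intake forms that omit a Hispanic option or a
multi-select race field, third-party reporting, household-level responses,
changing federal standards, and genuine fluidity of self-identification.
When group membership comes from one labeling source rather than another,
group-level disease prevalence estimates move, sometimes by several
percentage points, and most for the smallest groups (AIAN, NHPI,
Multiracial).

`concordkit` is a tested pipeline for quantifying this, aimed at registry
analysts, health-services researchers and statistical-agency collaborators
working with person-level linked data (an anonymized person key shared
between an EHR extract and census-style survey observations).

## What it computes

1. **Harmonization** to the 1997 OMB categories — Hispanic (any race), and
   non-Hispanic White, Black, AIAN, Asian, NHPI, Multiracial — from raw EHR
   strings (via a configurable mapping table) and from census-style
   (Hispanic flag, race set) responses.
2. **Census resolution**: among a person's multiple survey observations,
   drop allocated (imputed) responses and any same-source-same-year
   conflicting group, then prefer the decennial source over the ACS-style
   source and the most recent year within source.
3. **Classification** of each person as concordant, partially concordant (a
   single EHR race contained in the census Multiracial race set),
   discordant, or nonreporting (EHR race/ethnicity absent), plus the full
   8×7 cross-tabulation with row/column percentages.
4. **Outcome coding**: ICD-9/SNOMED → ICD-10 crosswalk, collapse to
   3-character stems (E11 = Type 2 diabetes, I10 = essential hypertension,
   …), per-patient ever-indicators, top-K selection.
5. **Estimation**: group × outcome prevalence p̂ = k/n with
   continuity-corrected Wilson score intervals; the **prevalence shift**
   Δ = 100·(p̂_census − p̂_EHR) per group × outcome, with a Wald interval from
   a logistic regression on the stacked denominators transformed by the
   delta method, person-clustered for the overlap; Bonferroni adjustment at
   family-wise error 0.05; disaggregation of each group aggregate into its
   recording-pattern constituents.
6. **Cohort contrasts**: 39 continuity-corrected two-sample proportion
   tests (13 demographic levels × 3 group pairs), practice-level OLS
   regressions, and concentration reports for practice-driven discordance
   patterns.
7. **Disclosure demo**: exact discrete Gaussian count noise
   (P(X=x) ∝ exp(−x²/2σ²)) with clamp-then-round release, mimicking
   agency protocols (not certified disclosure avoidance).
8. **Synthetic linked cohorts**: a generator with latent identities,
   practice recording defects, per-category missingness, reporting fluidity
   and outcome logits — with *closed-form* expectations for every pipeline
   quantity, so parameter recovery is testable end to end.

## Worked example

```python
from concordkit import (synthetic, categories, census_resolution,
                        concordance, outcomes, estimation, pipeline)

cfg = synthetic.study_config(n_patients=200_000, seed=7)
bundle = synthetic.generate(cfg)
ehr_labels = categories.harmonize_ehr_table(bundle.ehr)
census_labels = census_resolution.resolve_table(bundle.census)
records = pipeline.build_records(ehr_labels, census_labels)

print(f"{100*concordance.discordance_rate(records):.1f}%")        # 8.0%
print(f"{100*concordance.discordance_rate(records, True):.1f}%")  # 5.5%
print(f"{100*concordance.missingness_rate(records):.1f}%")        # 19.5%

matrix = outcomes.ever_indicators(bundle.events, persons=records["person_key"])
ehr_lab = records.set_index("person_key")["ehr_category"]
ehr_lab = ehr_lab[ehr_lab != "Unreported"]
cen_lab = records.set_index("person_key")["census_category"]
shifts = estimation.prevalence_shift_table(ehr_lab, cen_lab, matrix,
                                           ["E11"], n_comparisons=350)
print(shifts[shifts["group"] == "NHPI"].iloc[0])
```

Output (seed 7): cohort 195,339; strict discordance **8.0%** dropping to
**5.5%** when partial concordance is allowed; EHR missingness **19.5%**
overall and **39.5%** for census-labeled NHPI patients; NHPI Type 2
diabetes (E11) prevalence **14.2%** under the EHR labeling vs **16.4%**
under the census labeling, a shift of **+2.2 pp** with Bonferroni-adjusted
interval [−7.0, +11.4] — wide, because only ~0.1% of the cohort is NHPI.
That is the phenomenon in miniature: the relabeling moves the point
estimate of a small group by a sixth of its value.

From a shell, the same run is:

```bash
concordkit run --seed 7 --out run7/        # full pipeline, synthetic input
concordkit simulate --n 20000 --seed 1 --out sim/   # just the data bundle
concordkit harmonize --ehr sim/ehr.csv --out labels.csv
```

Every stage also exists as a subcommand (`resolve`, `classify`, `outcomes`,
`estimate`, `compare`, `protect`) operating on delimited files with the
schemas the manifest documents.

## Layout

```
src/concordkit/
  categories.py          OMB category system + harmonizers (+ mapping fixture)
  census_resolution.py   allocation/conflict filtering, source-priority resolution
  concordance.py         classification, cross-tab, rates, compositions
  outcomes.py            ICD crosswalk, 3-digit collapse, ever-indicators, top-K
  estimation.py          Wilson CC intervals, shifts (logit + delta method), patterns
  cohort_comparisons.py  two-proportion tests, 39-row contrasts, practice models
  disclosure.py          exact discrete Gaussian noise + release rounding
  synthetic.py           generator + closed-form expected_metrics
  pipeline.py / cli.py   orchestration, manifest, `concordkit` CLI
docs/methods.md          model, assumptions, parameter choices, limitations
```
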