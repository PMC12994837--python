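# Methods

This note documents the statistical procedures, the generative model behind
the synthetic cohorts, the numerical choices, and what the tests do and do
not establish about real linked data.

## 1. Category system and harmonization

The analysis unit is the 1997 OMB race/ethnicity taxonomy: Hispanic or
Latino of any race, then non-Hispanic White, Black, AIAN, Asian, NHPI, and
Multiracial (two or more selected races). `Unreported` is a nonreporting
state, never a race-set member. Hispanic ethnicity dominates any race
selection in both sources.

EHR source strings are mapped through an external two-column table
(`source_code,category`), compared case-insensitively after trimming,
because decentralized practices vary in casing and vocabulary. The shipped
fixture covers common EHR strings; real deployments supply their own
dialect table, which keeps the engine auditable across systems. "Declined",
"unknown" and blank all collapse to Unreported: the analysis treats EHR
missingness as a single nonreporting state, whatever its proximate cause.
One representational choice: an EHR dialect can carry a bare "multiracial"
string whose component races are unobserved, so an EHR-side Multiracial
label may have an *empty* race set (census Multiracial labels always carry
the observed set of ≥ 2 races). Partial-concordance logic reads only the
census-side set, so this does not affect classification.

## 2. Census observation resolution

Persons can have up to one decennial response per census year (2000, 2010,
2020) and annual ACS-style responses (2005–2022). Before prioritization:

1. allocated responses (imputed by survey processing) are dropped;
2. if a person's responses within one (source, year) disagree after
   harmonization — a signature of linkage error — the whole (source, year)
   group is dropped; identical duplicates collapse to one.

Among survivors, the decennial source wins over the ACS-style source even
when an ACS response is more recent, and recency decides within source.
The cross-source interaction is genuinely underdetermined; the alternative
(global recency with source priority as tie-break) is available behind
`decennial_priority=False`. Conflicts are judged on harmonized labels, not
raw race sets, because the category is the analysis unit. Allocation
filtering runs before conflict detection, so an allocated response can
never poison a reported one.

Resolution is order-invariant and monotone in allocated observations; the
scalar and vectorized implementations are cross-checked against each other
on random tables in the test suite.

## 3. Concordance classification

Given a person's EHR label and resolved census label (the cohort requires a
valid census label; EHR Unreported is the missingness being studied):

- EHR Unreported → `NONREPORTING`;
- equal categories → `CONCORDANT` (Multiracial vs Multiracial concordant
  regardless of race-set identity — set-level agreement is a stricter
  criterion the small Multiracial counts cannot support);
- census Multiracial whose race set contains the single EHR race →
  `PARTIAL` when partial concordance is enabled;
- otherwise `DISCORDANT`.

Partial concordance is defined only in the census-Multiracial direction.
The mirrored case (EHR Multiracial set containing the census single race)
is discordant by default; `mirror_partial=True` flips it, and is off
because the EHR side's multi-select defect — not the census side's — is the
mechanism partial concordance was defined to capture. A Hispanic label has
no race set, so Hispanic-vs-single-race pairs are always discordant.

Rates: discordance is the discordant share of persons reporting in both
sources (PARTIAL counts as non-discordant only when enabled; by
construction `rate(allow_partial=True) ≤ rate(allow_partial=False)` on any
input). Missingness is the nonreporting share of the full cohort, overall
or within a census-category column. Percent displays round half-even to
one decimal.

## 4. Outcome coding

ICD-9 and SNOMED CT codes are crosswalked to ICD-10 and every ICD-10 code
is truncated to its 3-character stem (letter + two digits), the level at
which the general condition is named. The shipped crosswalk is a fixture
covering the common primary-care stems; the national GEM/SNOMED maps are
external reference data a deployment would substitute. Unmapped and
malformed codes are dropped with a tallied log rather than failing the run
— real extracts contain junk. Ever-indicators span the whole record window
with no date filtering; prevalence here measures *recorded care-seeking*,
not population disease burden. Top-K selection sorts by descending patient
count with lexicographic tie-break; administrative Z-codes can be excluded
by prefix.

## 5. Estimation

**Wilson intervals.** Group × outcome prevalence intervals use the
continuity-corrected Wilson score form: the bounds solve
|p̂ − p| − 1/(2n) = z√(p(1−p)/n), with lower = 0 at k = 0 and upper = 1 at
k = n, clipped to [0, 1]. The closed form is validated against numeric
roots of the score equations to 1e-10.

**Prevalence shifts.** For group g and outcome o, the shift is
Δ = 100·(p̂_census − p̂_EHR) percentage points. The interval comes from
stacking the two denominators with a labeling-source indicator, fitting a
binomial GLM (logit link, intercept + indicator), and transforming to the
probability-difference scale by the delta method; the variance is
person-clustered (sandwich) because concordant persons appear in both
denominators and ignoring that overlap overstates the variance. Weights
default to 1 — no recoverable weighting scheme exists for the source
analysis, and at weight 1 the estimand is exactly the difference of group
proportions — but a weight column is accepted. When a group is degenerate
(no events, or all events) the ML fit is replaced by the closed-form
normal difference-of-proportions interval and flagged in `method`. The
cluster-delta interval is validated against a 2,000-replicate
person-resampling bootstrap (width agreement within 15%; zero-coverage
agreement on ≥ 95% of synthetic scenarios).

**Multiplicity.** Intervals are Bonferroni-adjusted at family-wise error
0.05: family 350 for the shift analyses (7 groups × 50 outcomes), family 39
for the demographic contrasts (13 levels × 3 group pairs). By default the
shift family is the groups × outcomes grid actually estimated.

**Pattern disaggregation.** Each focus aggregate (e.g. census-NHPI) is
partitioned by the counterpart label and status into constituent cohorts
(including EHR-Unreported), each with count, prevalence and Wilson
interval; constituent counts and events sum exactly to the aggregate. The
number of distinct patterns is data-dependent, never hard-coded.

## 6. Cohort contrasts and practice models

Covariates band as: age (< 18, 18–64, ≥ 65) computed from date of birth at
a configurable reference date (default 2021-12-31, the record-window end);
sex (male, female; other/missing excluded from sex rows only); SVI
percentile quartiles [0,25], (25,50], (50,75], (75,100]; RUCA tiers
metropolitan (1–3), micropolitan (4–6), small town (7–9), rural (10).
Band shares use the **full group size** as denominator; persons missing an
address-derived covariate appear in no band row, so SVI/RUCA rows do not
total 100%. This is the convention under which the published contrast
values reproduce exactly.

The two-sample proportion test is the classic continuity-corrected z/χ²
analysis: Yates-corrected chi-square p-value on the 2×2 table, and interval
diff ± (z·SE_unpooled + (1/2n₁ + 1/2n₂)) at the adjusted level.

Practice-level analysis summarizes each practice (size, discordance rate
among reporting patients, missingness rate, census-labeled non-White
share) and fits simple OLS regressions across practices. The source
analysis names "three simple linear regression models" but discusses five
relationships; the model set is configurable with a five-model default
(discordance~size, missingness~size, discordance~missingness,
discordance~nonwhite share, missingness~nonwhite share) so every reported
relationship is covered. A constant regressor degrades only its own model.
Concentration reports rank practices by pattern-member count and return the
top-N share; the zero-Multiracial screen flags practices above 1,000
patients with no Multiracial EHR record.

## 7. Disclosure mechanism

Released count tables get additive integer noise with
P(X = x) ∝ exp(−x²/2σ²), sampled exactly by rejection from a discrete
Laplace base (no floating-point normal rounding), then clamp-at-zero and
round-to-nearest-10 (clamp first: released tables contain no negative
counts). Defaults σ = 4, base 10 — chosen because released counts in this
product family are multiples of 10; the true agency parameters are
unpublished. The module exists for fixture realism and privacy
demonstrations; it performs no formal privacy accounting and makes **no
certified disclosure-avoidance claim**. Derived percentages must be
recomputed from protected counts.

## 8. The synthetic generator

Each person has a latent identity drawn from `category_probs` (Multiracial
mass split over explicit race-set combinations), a practice, and then:

- **practice defects**: a `NO_HISPANIC_OPTION` practice records
  latent-Hispanic patients under a fallback single race (default White); a
  `NO_MULTISELECT` practice records latent-Multiracial patients as one
  component race, uniformly;
- **missingness**: the EHR label masks to Unreported with a per-category
  probability keyed to the latent identity;
- **fluidity**: with probability `fluidity_rate` the census-reported
  category differs from the latent one via a confusion kernel — a single
  per-person, time-invariant relabeling, because the data cannot separate
  fluidity from error and one kernel exercises every pipeline branch. The
  default kernel moves mass preferentially Hispanic↔White, single race →
  Multiracial-containing-it (`AUGMENT`), Multiracial → one component
  (`COMPONENT`), and AIAN/NHPI → White, qualitatively matching the heavy
  off-diagonals of observed agreement matrices;
- **census observations**: 1–3 per person across decennial years and an
  ACS-style year range, with per-observation allocation flags and injected
  same-source-year conflicts at configured rates — both independent of
  identity, so conditioning on cohort inclusion (≈ 2% of persons lose all
  observations at the defaults) leaves every expectation unchanged;
- **outcomes**: ever-indicators drawn from logit(intercept +
  category-offset) on the latent identity, emitted as 1–2 coded events per
  positive (mixing ICD-10/ICD-9/SNOMED codes plus a 0.2% junk-code rate);
- **covariates**: uniform ages 0–90, sex ≈ 46/52.5/1.5%, uniform SVI and
  metropolitan-heavy categorical RUCA with 7% missing each — simple
  parametric stand-ins, not fit to any population.

Because every branch is a finite mixture, `expected_metrics` computes the
exact population value of each pipeline quantity by enumerating (latent
type × defect × fluidity outcome × masking): this is the closed-form oracle
for all parameter-recovery tests, entirely independent of the sampling
path.

**Study-condition defaults** (`study_config`): category masses from
the census-standpoint composition of large primary-care linked cohorts
(White 0.729, Hispanic 0.120, Black 0.080, Asian 0.032, AIAN 0.008,
Multiracial 0.0298, NHPI 0.0012); per-category missingness set so the
census-standpoint rates land at ≈ 17.7% (White), 35.2% (Asian), 39.1%
(NHPI) and ≈ 19.3–19.4% overall; fluidity 5%; defect fractions (17%
no-Hispanic-option, 49% no-multi-select) solved in closed form so strict
discordance is 8.0% falling to 5.4% with partial concordance allowed — the
no-multi-select fraction is large because the bulk of single-vs-Multiracial
discordance is concentrated in practices with no Multiracial records at
all; outcome logits set so census-labeled Type 2 diabetes prevalence is
≈ 17.0% for NHPI vs ≈ 11.5% for White, with hypertension, rhinitis, low
back pain and a general-exam Z-code as the other outcome groups. All of
these are closed-form calibrations of the generator's expectations, not
simulation fits.

What passing tests do **not** show about real data: the generator has no
geography, households, temporal dynamics within the record window, name
fields, linkage error beyond the conflict mechanism, or correlation between
missingness and outcomes given identity. Recovery results certify the
pipeline's correctness, not the realism of any particular EHR network.

## 9. Numerical and testing choices

- Tie-breaks: top-K outcomes break count ties lexicographically; resolution
  deduplicates identical rows and is order-invariant by sorting.
- Degenerate inputs: empty denominators raise `UndefinedRateError`; empty
  groups are skipped with a flag; a constant regressor degrades one model;
  σ = 0 noise is deterministically zero.
- Problem sizes: parameter recovery pools 20 seeds at n = 100,000 (the 3-SE
  Monte-Carlo check applies to pooled estimates, with the partial≤strict
  monotonicity asserted per seed); interval coverage uses 200 replicates at
  n = 5,000 against the family-350 adjusted level; the bootstrap agreement
  check uses 100 scenarios × 2,000 replicates; the discrete-Gaussian
  total-variation check uses 10⁶ draws at σ = 2 against the directly
  normalized pmf.
- All randomness flows through `numpy.random.default_rng` seeds; generation
  is byte-deterministic under (config, seed).

## 10. Known limitations

- The harmonization fixture and ICD crosswalk are deliberately small; real
  deployments must supply full dialect tables.
- The shift interval assumes independent persons apart from the modeled
  overlap clustering; practice-level dependence is not modeled
  (multi-level extensions are out of scope).
- The disclosure module is a mechanism demonstration, not a privacy
  guarantee.
- EHR-side mislabeling beyond the two practice defects (e.g. staff-assigned
  race) is not separately modeled; it is absorbed into fluidity, so
  EHR-standpoint compositions of the synthetic discordant set are less
  heterogeneous than real ones.
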