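# Methods

## Linkage model

The cascade is deterministic (rule-based) record linkage: an ordered
family of composite match keys, each a concatenation of identifier
fragments, tried from most to least specific. A roster record links to a
registry record at the lowest level whose keys agree on both sides; the
level ordering encodes prior confidence, so earlier agreement always
pre-empts later agreement. The built-in key table is:

| level | components |
|---|---|
| 1 | SSN |
| 2 | first (1–6), last, DOB |
| 3 | last (1), last (3–8), first (2–8), DOB |
| 4 | last (1), last (3–8), first (2–8), birth month, birth year |
| 5 | last (1), last (3–8), first (2–8), birth day, birth year |
| 6 | last, first (1–2), DOB |
| 7 | last (1–3), first (1–3), DOB |
| 8 | last (1–4), first (1–4), birth year |
| 9 | first (1–3), last (1–3), birth month, birth year |
| 10 | first (1–3), last (1–3), birth day, birth year |
| 11 | first (1–3), last (1–3), birth month, birth year |

Conventions adopted where the rule table alone under-determines
behavior:

- **Letter indexing** is 1-based inclusive. A name shorter than a
  slice's start position yields no key at that level (the level is
  skipped for that record); a name shorter than the slice's end
  contributes its available substring. This keeps every key well-defined
  on short names without padding artifacts.
- **Level 3 skips letter 2 of the last name** (first letter + letters
  3–8). It is implemented exactly as specified; the skipped letter
  plausibly tolerates a single typo or transposition early in the name.
- **Level 11 is textually identical to level 9**, making it unreachable
  (any pair agreeing at 11 already agreed at 9). It is retained as
  printed rather than "repaired" into a guessed variant (e.g. birth day
  + birth year, which level 10 already covers); a warning is logged once
  per run.
- **Missing data**: an SSN that is not exactly 9 digits after
  normalization is missing; a missing component (SSN, DOB, too-short
  name) removes the affected levels from consideration rather than
  producing a sentinel key.
- **Normalization**: names are upper-cased, trimmed, NFKD-decomposed
  with combining marks dropped, and stripped to A–Z; idempotent by
  construction.

### Validation score

Accepted practice validates rule-based links with a field-agreement
score; the score here is a transparent surrogate for the proprietary
score of commercial linkage tools: a weighted mean of per-field
agreements rescaled to 0–100, with default weights SSN 40, first name
15, last name 15, and 10 per DOB component. Name agreement is
`1 − Levenshtein/max-length` (via edlib); SSN and DOB components agree
exactly or not at all. Fields missing on either side are excluded from
the weighting — absence is no evidence either way; a pair identical on
its comparable fields scores 100. The acceptance threshold default is
80, matching the conventional operating point for scores on this scale.
With the default weights, a level-2+ match with exact names and DOB
scores 100, one clean name plus a one-letter typo in the other stays
comfortably above 80, and a DOB component error on top of a name typo
can fall below it — the threshold therefore prunes exactly the weakest
fallback-key matches.

### Review, deduplication, determinism

Partial-name levels 7–11 carry a review flag. Manual review cannot be
automated, so it is modeled as a policy: `auto_reject` (drop all flagged
links), `auto_accept` (pass review), or `score_gate` (the default:
review is the score threshold itself). The global threshold applies to
every link regardless of policy.

One-to-one linkage is enforced (a cohort participant is one surveillance
person): among decisions sharing either ID, the lowest level wins, then
the highest score, then the lowest registry ID, then the lowest roster
ID. All inputs are sorted internally, so decisions are independent of
input row order and identical runs are bit-identical.

A quadratic all-pairs, all-levels reference implementation
(`brute_force_match`) serves as the oracle for the indexed cascade on
instances up to 500×500.

## Population and indicator rules

All date intervals are closed. The eligibility window for labs is
2011-01-01 – 2016-12-31, the outcome year 2017, the suppression window
2011-01-01 – 2017-12-31.

- *Eligible PLWH*: diagnosed; the most recent lab dated on or before the
  window end falls inside the window and carries the in-jurisdiction
  flag; alive at the end of the outcome year (taken from the supplied
  vital-status field). A person whose most recent lab predates the
  window is excluded even if older labs fell inside it — the definition
  keys on the *last* lab. Each excluded person lands in exactly one
  tally bucket, assessed in a fixed order, and tallies conserve totals.
- *Eligible roster*: consent date inside the window, resident, no
  withdrawal date. Withdrawn enrollees are therefore analyzed with the
  non-cohort group.
- *Stage*: an AIDS-defining OI forces stage 3; otherwise the CD4 count,
  when present, takes precedence over the CD4 percent (CDC convention
  for discordant values). The percent boundary is closed as stage 1 iff
  % ≥ 29 (the "> 29%" phrasing read as the complement of the 14–28%
  band). Count boundaries: < 200 stage 3, 200–500 stage 2, > 500
  stage 1. Stage in 2017 uses the most recent count and percent on or
  before 2017-12-31, ties on date broken by input order (last row wins,
  consistently in both implementations).
- *Suppression*: VL ≤ 200 copies/mL, inclusive; "detectable" is its
  complement (> 200), which the source definitions leave implicit.
  Suppression "in 2017" is computed both ways — any 2017 VL, and the
  chronologically last 2017 VL — because the two definitions genuinely
  differ for rebound trajectories; the clinical table reports the
  last-lab variant and exposes both. A person with no 2017 VL is
  *not applicable* (missing), not false, for the last-lab indicator.
- *Time to suppression*: days from the first VL > 200 to the first
  subsequent VL ≤ 200, divided by 30.4375 (mean Gregorian month);
  undefined when no detectable VL precedes the first suppressed one.
  The 0–24-month category is inclusive at 24.

Indicators are computed twice: a vectorized pandas implementation used
by the pipeline and a per-person composition of the individual rule
functions; a test asserts frame-level equality on a noisy synthetic
world.

## Comparison statistics

Pearson chi-square (no continuity correction) on category × group
counts with expected counts from the margins; one-way ANOVA for
continuous measures. Column percentages are computed over non-missing
values and rounded half-up to one decimal (`decimal`-based, since
floating-point banker's rounding differs on exact halves); ratios are
displayed to two decimals and p-values to three ("<.001" below that).

Adjusted prevalence ratios come from a binomial GLM with log link
(statsmodels IRLS, tolerance 1e-10, 200 iterations). The fit is
accepted only if IRLS converged with fitted probabilities in (0, 1];
otherwise the model is refit as log-link Poisson with HC1 sandwich
variance and flagged `poisson_robust_fallback` — the standard remedy
for log-binomial non-convergence. An exposure level with zero outcome
events short-circuits to `converged=False`. With no covariates the fit
reduces to the closed-form ratio of proportions with the delta-method
CI (asserted to 1e-8 in tests). Covariates enter as the adjustment set:
gender identity, age at the reference date (continuous, years),
race/ethnicity, years since HIV diagnosis (continuous), transmission
mode; categorical covariates are dummy-coded with the first level as
reference; complete-case handling with a logged drop count. A logistic
model on the odds-ratio scale is available behind `scale="odds_ratio"`.

The four-model suite: (1) receipt of care in the outcome year, (2) ever
suppressed, (3) suppressed at the last outcome-year lab (not-applicable
persons drop), (4) slow suppression (> 24 months vs 0–24) among
ever-suppressed persons with a defined category.

## Synthetic data generator

The generator emulates a surveillance registry (~13,000 PLWH by
default, matching the scale of a high-prevalence US city) and a cohort
roster (40% enrollment by default). It targets the *structure* of such
data, not any real person-level records.

- **Identity**: names from a bundled static list (including short
  names, apostrophes, hyphens, diacritics, so normalization and partial
  keys are exercised); unique random 9-digit SSNs; birth dates uniform
  over ages 20–80 at the end of the outcome year.
- **Demographics** follow configurable categorical distributions whose
  default labels and proportions mirror a typical urban HIV
  surveillance profile (gender identity Male/Female/Transgender;
  race/ethnicity White/Black/Hispanic/Other; transmission MSM, IDU,
  MSM/IDU, heterosexual contact, perinatal, other, not identified).
- **Corruption** is applied per roster record in fixed order — SSN
  missingness, one-character name typo, prefix truncation (≥ 3 letters
  kept), single DOB-component error — so one seeded stream fully
  determines output. Default rates (SSN 0.15, typo 0.05, truncation
  0.05, DOB 0.02) are conventions chosen to populate all reachable key
  levels at plausible magnitudes; no published identifier-quality
  statistics exist to estimate them from.
- **Clinical trajectories**: per person, a Poisson number of labs (mean
  8 — roughly annual monitoring over the window with extra visits) with
  dates uniform in the window; lab types VL 55% / CD4 count 35% / CD4
  percent 10%. Group-differential behavior flows from three
  probabilities per group (defaults set to the engagement gap the
  pipeline is designed to detect: cohort 0.835/0.837/0.614, non-cohort
  0.717/0.781/0.505): *care* = P(≥ 1 outcome-year lab | ≥ 1 lab ever),
  realized by redating the last lab (and half the time a second one)
  into the outcome year; *ever suppressed* = P(any VL ≤ 200 | ≥ 1 lab);
  *last-lab suppressed* = P(last outcome-year VL ≤ 200 | an outcome-year
  VL exists). Within an ever-suppressed trajectory the suppressed VLs
  form a date-suffix after a uniform changepoint — the natural
  "achieved suppression" shape that also gives time-to-suppression a
  defined value — except a forced rebound when the last-lab flag is
  false. A person whose single VL cannot satisfy both flags resolves
  toward the last-lab flag; at the default lab intensity this affects
  well under 1% of persons. The flag mixture is constructed so the
  three probabilities are recovered exactly in expectation
  (ever = last ∨ Bernoulli((p_ever − p_last)/(1 − p_last)) for in-care
  persons), verified within 3 binomial standard errors at n = 10,000.
- **Eligibility structure**: small fractions are non-resident (5%),
  deceased (3%), stale (last lab before the window, 4%), or withdrawn
  after consent (2%), so every exclusion bucket is exercised.

What the generator does **not** emulate: realistic name/SSN frequency
structure (no shared family names beyond chance, no twin/junior
collisions), address history or migration, correlation between
demographics and clinical outcomes, ART regimens, reporting delay, or
duplicate registry records. Passing tests therefore demonstrate that
the algorithms implement their definitions correctly and recover known
generating parameters — not that real-world linkage at these corruption
rates would achieve the same precision/recall, since real identifier
error is more structured than independent per-field noise.

## Problem sizes

The analysis scripts run the study at n = 13,000 persons. The test
suite and acceptance script use smaller worlds chosen for speed at
equal coverage: 300–1,000 persons for linkage behavior (large enough
that every reachable key level appears), 10,000 for 3-standard-error
calibration checks, n = 20,000 with 500 (test) / 300 (script)
replicates for prevalence-ratio recovery, and 200 replicates for
null-effect coverage.

## Known limitations

- Level 11, as printed, can never fire; pairs it would catch are caught
  at level 9.
- The validation score is a surrogate: it reproduces the published
  decision rule (accept at ≥ 80) but not any proprietary score's exact
  values.
- Log-binomial fits near the probability boundary can be fragile; the
  Poisson fallback changes the variance estimator, and mixed-method
  suites should be compared with that flag in view.
- The roster-into-registry direction is implemented; bidirectional
  matching (registry-into-roster) is not.
- With percentages rounded half-up to one decimal, reconstructed
  percentages can differ from independently rounded published values by
  0.1 when the underlying count was itself derived from a rounded
  figure.
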