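# cohortlink

Record linkage between an HIV surveillance registry and a clinical cohort
roster, and a comparison of care-continuum outcomes between enrolled and
non-enrolled people living with HIV (PLWH).

## The problem

Clinic-based HIV cohorts are widely used to study care and treatment, but
their participants may not represent the jurisdiction-wide population of
PLWH — participation bias. Measuring that bias requires (1) linking the
cohort's enrollment roster into the health department's surveillance
registry using imperfect personal identifiers, and (2) contrasting
demographics and clinical outcomes between linked (cohort) and unlinked
(non-cohort) PLWH using only surveillance-reported laboratory data, so
both groups are measured the same way.

`cohortlink` implements that pipeline for epidemiologists and
surveillance analysts:

- **Deterministic 11-level match-key cascade.** A roster record links to
  a registry record at the lowest level whose composite key agrees: SSN
  (level 1); first name (letters 1–6) + last name + date of birth
  (level 2); down through partial-name keys such as last name (1–3) +
  first name (1–3) + DOB (level 7). Levels 7–11, built from partial names
  only, carry a review flag and are gated by a configurable policy.
  Candidate links are scored by a weighted field-agreement score rescaled
  to 0–100 (SSN 40, names 15+15, DOB components 10+10+10 by default;
  names by normalized edit-distance ratio) and accepted when the score is
  at least the threshold (default 80). Deduplication enforces one-to-one
  linkage with (level, score, ID) tie-breaks.
- **Population definitions.** Eligible PLWH: diagnosed, last reported
  lab on or before 2016-12-31 falling inside 2011–2016 with an
  in-jurisdiction address, alive at end of 2017. Analysis-eligible
  roster: consented 2011–2016, resident, not withdrawn.
- **Care-continuum indicators** from CD4/viral-load labs: CDC disease
  stage (stage 1: CD4 > 500 cells/µL or CD4% ≥ 29; stage 2: 200–500 or
  14–28%; stage 3: < 200, < 14%, or an AIDS-defining opportunistic
  infection), ever stage 3, receipt of care (≥ 1 CD4/VL lab in 2017),
  viral suppression (VL ≤ 200 copies/mL; ever, at last 2017 lab, any
  2017 lab), and time to suppression (first detectable VL to first
  subsequent suppressed VL, in 30.4375-day months, 0–24 vs > 24).
- **Comparison statistics.** Contingency tables with one-decimal column
  percentages and Pearson chi-square tests, one-way ANOVA for continuous
  measures, and adjusted prevalence ratios (APR) from log-link binomial
  regression — `log P(Y=1) = β₀ + β₁·cohort + γ'x`, APR = exp(β₁) — with
  Wald 95% CIs, adjusting for gender identity, age at 2017-12-31,
  race/ethnicity, time since HIV diagnosis, and transmission mode. When
  the log-binomial IRLS fit fails, a log-link Poisson fit with robust
  (HC1) variance is used and flagged.
- **Synthetic data generator** with ground-truth identity links,
  configurable identifier corruption (missing SSN, typos, truncation,
  DOB component errors) and group-differential care/suppression
  behavior, so linkage accuracy and downstream statistics are testable
  against a known answer. No real surveillance data is included or
  required.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
jurisdiction of 13,000 PLWH (≈ 40% enrolled, default identifier noise):

```sh
python analysis/01_simulate.py          # registry + roster + truth
python analysis/02_link.py              # cascade linkage + evaluation
python analysis/03_define_population.py # eligibility + cohort split
python analysis/04_indicators.py        # care-continuum indicators
python analysis/05_compare.py           # tables + adjusted models
```

With the default seed this prints, among other things:

```
registry: 13000 persons, 104428 labs, 5125 diagnosis events
roster:   5244 enrollees (40.3% of registry)
accepted 5208 links; precision 1.0000, recall 0.9931
per-level accepted: {1: 4453, 2: 613, 3: 13, 4: 6, 5: 5, 6: 59, 7: 59}
cohort 4464 (39.1%), non-cohort 6944
...
                 variable category cohort_cell non_cohort_cell p_value
                care_2017      yes 3698 (82.8)     5002 (72.0)   <.001
 suppressed_last_lab_2017      yes 2311 (51.8)     2640 (38.0)   <.001
...
   model1_retained_in_care 1.15 (1.13-1.17) log_binomial 11408
    model2_ever_suppressed 1.06 (1.05-1.08) log_binomial 11408
```

Reading this: 85% of roster records matched on SSN alone, the rest
through the name/DOB fallback keys; one accepted link in ~700 is a false
match and 0.7% of true links are missed at the default corruption rates.
After eligibility filtering, cohort members are substantially more
likely to have a 2017 lab (82.8% vs 72.0%) and to be suppressed at their
last 2017 VL (51.8% vs 38.0%), and remain 15% more likely to be in care
after covariate adjustment (APR 1.15, 95% CI 1.13–1.17) — the engagement
gap the generator builds in and the pipeline is designed to detect.

The same pipeline runs from one command (`cohortlink repro`) or on real
CSV extracts via the other subcommands (`cohortlink link --registry ...
--roster ...`); see `cohortlink --help`.

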