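# Methods

## Cohort algorithms

A person's event history is reduced to dated, coded facts (conditions and
drug exposures) classified by a concept-set registry.  The algorithm rules
are:

1. **First diagnosis code.** `t_first` is the earliest event carrying the
   `sle_diagnosis` role.  Incidence is anchored on this minimum date; no
   separate "clean window free of SLE codes" is needed, because nothing can
   precede the minimum.
2. **Confirmation (2X only).** Some SLE diagnosis code must fall 31–365
   days after `t_first`, both endpoints inclusive.  The window is anchored
   on the first *diagnosis* code, not the corrected index: the confirmation
   is a statement about repeat diagnosis coding, not about entry timing.
3. **Index-date correction.** Among events with role `sle_sign_symptom` or
   `sle_treatment_drug` falling 1–90 days before `t_first`, the earliest
   becomes the index date (ties break on role, then vocabulary and code,
   so cohorts are independent of input row order).  There is no chaining:
   a precursor 91+ days out never qualifies, even if bridged by another
   precursor.  Drug precursors participate on equal footing with signs and
   symptoms.
4. **Look-back (incident only).** The *corrected* index date must lie
   inside the person's observation period with at least 365 days of
   observation before it.  Evaluating the washout at the corrected index
   means a precursor can pull an otherwise-eligible person out of the
   incident cohorts; that is intended — the washout protects the claim
   that disease onset was observed.

A person enters each cohort at most once, at the first qualifying episode;
re-entry and exit logic are out of scope.  All windows are measured in
whole days and written as closed ranges.

The comparator algorithms (`barnado_3x_am`, `barnado_3x_am_excl`) require
three SLE codes on **distinct calendar days** — a guard against same-day
duplicate billing rows; whether duplicate rows should count is genuinely
ambiguous, and distinct days is the conservative reading — plus any
antimalarial exposure, with the index at the later of the third distinct
code and the first antimalarial.  Their index therefore *follows* the
first diagnosis code; the `index ≤ first code` bound holds only for the
four correction algorithms.

Concept matching is exact string equality on `(vocabulary, code)` with no
hierarchy expansion; the shipped registry is a deliberately small default
(the canonical SLE codes SNOMED 257628 / ICD-10 M32.9 / ICD-9 710.0,
five sign/symptom codes, three treatment drugs, two antimalarials, the two
comparator exclusions, two comorbidities).  Real analyses should supply
complete local code lists via the YAML config.

## The simulator

The generator emulates the *structure* of administrative claims/EHR data —
it is not fit to any real database, whose data are proprietary.  Per
person, in fixed draw order from one seeded generator:

1. **Demographics and observation.** Sex Bernoulli(0.5); age at
   observation start ~ Normal(38, 16) clipped to 18–85 (claims databases
   skew young-adult); one observation period with start uniform in the
   calendar window (default 2010–2020) and duration exponential with
   median `followup_years_median` (default 1.5 y), floored at 30 days and
   truncated at the window end.  One period per person keeps episode logic
   unambiguous.
2. **Latent status.** P(case) = incidence × person-years × m /
   (1 − prevalent_case_fraction), where m multiplies a female:male hazard
   ratio (default 7.3, giving ≈88% female cases) by a 10-year age-band
   shape peaking at the configured band (default 50–59), normalised to
   population mean 1 so the realised *observed-onset* rate matches the
   configured 16 per 100,000 PY.  With probability
   `prevalent_case_fraction` (default 0.3) onset precedes observation
   start by 1–3650 days; otherwise it is uniform within observation.
3. **Coding process (cases).** The first code falls a geometric number of
   days after onset (mean `dx_delay_days_mean` = 45); later codes arrive
   on a 30-day grid as Bernoulli(`repeat_code_prob_per_month` = 0.25)
   hits; only codes inside the observation period are recorded, so
   prevalent cases are seen only through ongoing repeat coding and a case
   whose delay outruns observation is never coded at all (a structural
   false negative).  With probability `prodrome_prob` = 0.45 the case has
   1–3 sign/symptom or treatment-drug events uniform in the 90 days
   before its first recorded code; with probability `hcq_prob_cases` =
   0.38 a hydroxychloroquine exposure follows the first code.
4. **Noise.** Non-cases receive one spurious (rule-out) SLE code with
   probability `ruleout_code_prob` = 0.002 — never repeated and never
   co-occurring with an antimalarial, exactly the asymmetry the 2X and
   comparator rules exploit; background sign/symptom events arrive as a
   Poisson process (default 0.3/PY); comorbidity codes are Bernoulli per
   person at case/non-case rates (defaults: rheumatoid arthritis
   0.15/0.01, renal impairment 0.10/0.01).

What the simulator does **not** emulate: visit-level billing structure,
multi-payer churn and re-enrollment, laboratory results (ANA testing),
coding-system drift over calendar time, regional practice variation, or
correlated comorbidity burden.  Passing tests on simulated data therefore
demonstrate the *logic* and *direction-of-effect* properties of the
algorithms, not their numerical performance on any real database.

## Evaluation conventions

- Case status is matched at the person level with no date tolerance;
  timing accuracy is a separate quantity (`index_date_error`, signed days
  from true onset).
- The denominator excludes true cases whose onset falls after their
  observation ends (or who have no observation): no database can detect
  them, and including them would deflate every algorithm's sensitivity by
  a constant that says nothing about the algorithm.
- 95% CIs are Wilson score intervals (stable at proportions near 1, e.g.
  specificities of 0.999+); F1 is reported without a CI.
- Cross-database summaries are unweighted arithmetic means of point
  estimates, reported to the nearest whole percent (half rounds up).

## Diagnostics

- **SMD.** The binary standardized difference is
  `(p1 − p2)/√(p1 q1 + p2 q2)` — without the conventional /2 inside the
  root.  The published comparison values this package reproduces are
  consistent with the no-/2 form and not with the textbook form; the
  textbook variant is available via `pooled=True`.
- **Incidence.** At-risk time runs from 365 days after observation start
  (aligning denominators with the incident washout) to the earlier of the
  index date and observation end; persons observed under a year contribute
  nothing.  Stratification by sex, 10-year age band at the at-risk
  midpoint, and calendar year (person-time split across years).
- **Matching.** Controls are drawn without replacement (globally) from
  non-cohort persons with the same sex and 5-year age band and at least
  one clinical event in the case's index month; that event dates the
  control's matched index, which must carry ≥365 days of prior
  observation.  Age is matched on 5-year bands to keep 1:10 feasible at
  simulation scale.  Note that with the default background event rate of
  0.3/PY the candidate pool is visit-sparse and 1:10 is often infeasible;
  matching studies on this simulator should raise
  `background_symptom_rate_per_py` to a visit-dense value (≈6/PY, typical
  of claims visit frequency), which is what the package's matching tests
  do.

## Quantitative bias analysis

The corrective equations are the standard outcome-misclassification
estimators with known sensitivity and specificity (the implementer's
choice; Rogan–Gladen form): prevalence
`(p_obs + sp − 1)/(se + sp − 1)` clipped to [0, 1], and incidence via
corrected events `(events − (1 − sp)·n_at_risk)/(se + sp − 1)` floored at
0.  Both require se + sp > 1 (an informative classifier) and degrade
sharply as se + sp → 1⁺, which the precondition guards.  Uncertainty
propagation draws (se, sp) from Beta distributions moment-matched to the
point estimate and 95% CI (keeping draws in [0, 1]); draws with
se + sp ≤ 1 are discarded; zero-width CIs collapse to the deterministic
correction.

## Numerical and test-design choices

- Statistical checks on stochastic quantities use fixed seeds and problem
  sizes chosen for power: e.g. the index-event-breakdown check runs
  100,000 persons at elevated incidence with background noise off, so the
  fraction of entries re-anchored on a precursor is an unbiased,
  low-variance estimate of `prodrome_prob` (with prevalent cases and
  background noise on, the fraction is diluted and the comparison would
  test the noise, not the correction).
- Incidence calibration is checked against the 95% Poisson envelope of
  the configured rate at 200,000 persons.
- Degenerate inputs: empty databases yield empty cohorts; metrics with a
  zero denominator are reported as absent (`None`), never as 0; SMD is
  absent when both proportions sit at the same degenerate endpoint.

## Known limitations

- The shipped concept sets are a minimal default, not a complete clinical
  code list; results on real data depend strongly on the supplied lists.
- The simulator's event processes are independent across persons and
  mostly independent within person; real claims exhibit strong visit
  clustering.
- Cohort exit, era logic, and multi-episode membership are out of scope.
- Performance numbers obtained on simulated data characterise the
  simulator's assumptions, not any real population.
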