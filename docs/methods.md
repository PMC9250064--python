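# Methods

## The problem being modelled

EHR-based vaccine studies must pick an index date for the unexposed
comparison — an "anchor". Because EHR covariates are *measured at
encounters*, the anchor determines how much of the baseline record is
visible around day 0. This package simulates the whole measurement process
so that anchoring artifacts arise mechanistically rather than being painted
on, and then quantifies them with standardized-difference balance
accounting.

## Generative model (`anchorbias.simulate`)

Per person *i* over an observation period of *D* days (all dates are
integer offsets from the observation start; everyone is observed for the
full period):

1. **Demographics.** Age at start from a configurable categorical
   distribution (preset: uniform 18–84 years); sex female with probability
   `sex_probability` (presets use the study-population shares ≈0.61–0.63).
2. **Latent health burden.** `h_i ~ Gamma(shape, scale)`; presets use
   Gamma(2, 0.5) (mean 1, SD ≈0.71). `h` is never exported to any analysis
   input — downstream code sees it only through utilization and records.
3. **Chronic-condition presence.** Concept *c* is present with probability
   `logistic(α_c + β_c h_i + γ_c age_i/10)`. Presets: 40 concepts,
   intercepts spread linearly over [−4, −1] (prevalences roughly 5–60%),
   burden loading 0.6, age loading 0.15 per decade. Age always enters
   rate/logit models in decades to keep coefficients O(1).
4. **Visits.** Homogeneous Poisson process with per-day rate
   `λ0 · exp(b_v h_i + a_v age_i/10)`; visit days deduplicated. Presets:
   λ0 = 0.006/day, b_v = 0.5, a_v = 0.12/decade — ≈6–7 visits/year and a
   daily visit probability q ≈ 0.02 at the population mean, typical of a
   care-engaged EHR population.
5. **Recording (the crux).** At each visit, each *present* chronic concept
   is recorded with probability 0.35; each of 30 measurement concepts with
   0.20 and each of 30 drug concepts with 0.15 (unconditionally — labs and
   dispensings are utilization-driven); each of 20 acute concepts with 0.03
   (transient complaints, no latent presence). Between visits nothing is
   recorded.
6. **Vaccination** (at most one per person — a single index exposure).
   Assigned with probability `logistic(c0 + b_x h_i + a_x age_i/10)`; date
   uniform over the vaccination window (presets use a ~3-month campaign
   placed so every vaccination and every self-controlled prior anchor
   admits a 450-day lookback). With probability κ
   (`visit_coupling_prob`) the date is *coupled*: moved to a uniformly
   chosen existing visit inside the window, or, if none exists, a new visit
   is created on the sampled date. Uncoupled vaccinations do not touch the
   visit process, so they coincide with a visit only by chance; the
   expected same-day-visit fraction is κ + (1−κ)q.

### Presets

| parameter | influenza_like | covid_like | null |
|---|---|---|---|
| κ (visit coupling) | 0.558 | 0.027 | background q (≈0.02) |
| vaccination burden coef b_x | +0.8 | −0.8 | 0 |
| vaccination age coef | +0.05/decade | +0.05/decade | 0 |
| interpretation | vaccination at encounters, sicker vaccinees | mass sites, healthier vaccinees | random vaccination |

The κ values are the observed shares of vaccinations with a same-day visit
in large hospital and claims EHR sources for the two vaccine types; the
signs of the health-selection coefficients encode influenza vaccination
targeting vulnerable patients versus COVID-19 vaccination reaching the
general (healthier-than-EHR-average) public. In the null preset κ equals
the background daily visit probability computed at the population-mean
burden and age; under the coupling semantics above, the vaccinated day-0
visit probability is then κ + (1−κ)q ≈ 2q — a small residual excess (day-0
SMD ≈ 0.05 on measurement covariates at preset rates) that stays well
inside the 0.1 balance band and is the closest "no-mechanism" scenario the
coupling model admits.

Concept counts (40 chronic / 20 acute / 30 measurement / 30 drug) are
config-exposed conventions, not estimates. Concept IDs are small integers
in per-class blocks (1000/2000/3000/4000) with a domain column
(condition/measurement/drug; "procedure" is a legal domain value the
default generator does not emit) — deliberately not a real OMOP vocabulary.

## Cohorts and anchoring (`anchorbias.cohorts`)

- **Target**: vaccinated persons whose vaccination date admits the 450-day
  lookback; exclusions are counted in an attrition table.
- **Matched comparators**: unvaccinated persons, exact on (sex, age bin,
  calendar date), greedy in a seed-shuffled target order, 1:1 without
  replacement by default. Age bins are 5 years (conventional coarse exact
  matching). The *arbitrary-date* comparator is indexed on the target's
  calendar date with no encounter requirement; the *visit* comparator must
  additionally have a visit that day (strict same-day by default; an
  opt-in ±d tolerance indexes on the visit date itself, preferring the
  nearest day, earlier on ties). Unmatched targets are dropped from the
  comparison (complete-pair analysis) and reported. With
  `with_replacement=True` a comparator may serve several targets; its rows
  then repeat and summaries weight it by multiplicity.
- **Self-controlled anchors**: for each vaccinated person, one control
  index uniformly sampled from the eligible days (`prior_date`) or the
  person's visit days (`prior_visit`) in [vaccination − 450, vaccination −
  180], clipped so the control index itself admits the lookback. Persons
  with no eligible day/visit leave the design on both sides. The sampler
  contract is fixed for reproducibility: one `default_rng(seed)`, persons
  in ascending ID order, one uniform draw each.

## Covariates and balance

Extraction windows (closed intervals, days relative to index): day 0
`[0,0]`, day −1 `[−1,−1]`, short `[−30,−1]`, medium `[−180,−31]`, long
`[−450,−181]`. Short+medium+long tile `[−450,−1]` exactly; day −1 is
intentionally also inside the short window because each window is an
independent extraction. Binary covariates are patient proportions (events
deduplicated within person × concept × window; absence counts as 0, so
`n_persons` is the cohort size for every covariate) with SD `√(p(1−p))`;
the continuous covariate is the per-person visit count (mean, sample SD).
The covariate universe is every concept observed anywhere in the dataset,
so any two cohorts from one dataset are compared over the same universe.

SMDs use the pooled-variance standardized difference (Bernoulli variances
for proportions). Degenerate cases: SMD = 0 whenever the two statistics
are equal (including 0 vs 0 and 1 vs 1); when they differ but the pooled
variance is 0 (e.g. 1 vs 0) the SMD is flagged as signed infinity and
counted as imbalanced (it is the most extreme imbalance), and reported
separately in the imbalance table. The balance rule is **imbalanced iff
|SMD| ≥ 0.1** — the "balanced iff < 0.1" convention; the threshold is a
parameter, and strictly-greater counting is available by passing any
threshold. Signed SMDs are retained in the balance table; absolute values
are used only for counting.

## Pipeline and determinism

`run_experiment` derives independent sub-seeds for simulation, matching and
self-controlled sampling from the experiment seed via `SeedSequence`, writes
the fully resolved scenario and experiment configuration alongside every
run, logs row counts at stage boundaries, and emits per-design balance,
imbalance, scatter and attrition artifacts plus a manifest. Outputs contain
no timestamps; re-running a manifest reproduces every artifact byte for
byte (the only exception is the copy of the experiment spec, which embeds
the output path). Identical scenario config + seed gives bit-identical
population tables.

## Problem sizes used in the checks

The mechanistic checks run both non-null regimes at 20,000 persons
(≈6,000–6,500 vaccinated; ≈400,000 visits; ≈6–7 million events), where
every directional contrast holds with wide margins; the null calibration
pools 20 seeds at 5,000 persons, bounding the imbalanced fraction per
window at 0.10 (the pooled fraction observed is ≈0.01, dominated by
sampling noise at ≈1,500 matched pairs). These sizes were chosen as the
smallest at which per-covariate sampling error (SE of an SMD ≈ √(2/n
pairs) ≈ 0.02 at 6,000 pairs) is clearly separated from the 0.1 balance
threshold.

## What the generator does and does not emulate

It emulates the features that make anchoring bias exist: encounter-
conditional recording, utilization that rises with (latent) morbidity and
age, health-selected uptake, and tunable vaccination-visit coupling. It
does **not** emulate disease natural history, care pathways, seasonality,
pandemic-phase dynamics, multi-dose schedules, differential observation
periods, coding-practice quirks, or hierarchical vocabularies. Passing
checks therefore demonstrate that the *designs* behave as expected under a
known data-generating process — not that any particular real-world
covariate list would show the same counts; the real-data analogues of
these quantities depend on proprietary source populations.

## Known limitations

- Everyone is observed for the whole period; eligibility is a pure
  lookback condition rather than enrollment-based person-time.
- Matching is exact and greedy; no propensity scores, calipers or
  variable-ratio designs.
- One continuous covariate (visit count); others would be straightforward
  but are not needed for the balance phenomenology.
- The visit process is time-homogeneous, so "arbitrary date" and "average
  visit behavior" are stationary — calendar-time confounding is out of
  scope by construction.
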