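# Methods

## 1. The emergent-symptom (ES) measure

For a chosen item set (Part IB, Part II, or IB+II of the MDS-UPDRS — all
patient-reported, ordinal 0–4) and threshold τ ∈ {1, 2, 3}:

- an item is **eligible** for a subject if it was scored exactly 0 at the
  baseline visit (items *missing* at baseline are ineligible: a baseline
  zero cannot be verified, and a missing response is never treated as 0);
- an **ES event** at a post-baseline visit is an eligible item scored ≥ τ
  at that visit (items missing at the visit contribute nothing there);
- a subject is an **ES patient** at a visit if they have ≥ 1 event.

ES is always evaluated against baseline only: an item that emerges,
resolves, and recurs counts at every visit at which it meets the
threshold. This matches per-visit tabulation; a time-to-first-event
reading would be a different measure.

Two stability variants address response instability:

- **`confirmed_baseline_zero`** — the baseline 0 must be confirmed by a 0
  at the *first post-baseline visit with a non-missing score* for that
  item (two consecutive zeroes to enter the eligible set). A stricter
  reading would demand a non-missing 0 specifically at the first scheduled
  follow-up and drop the item otherwise; we let isolated missing
  assessments pass through to the next observed one, so missingness does
  not silently shrink the eligible set.
- **`two_consecutive_emergent`** — the event must persist: the item must
  also score ≥ τ at the *next visit with a non-missing score* after the
  qualifying visit. An event at the subject's final observed visit cannot
  be confirmed and is not counted under this rule.

"Consecutive" therefore means adjacent in the subject's sequence of
non-missing assessments of that item, not adjacent on the calendar.

Per-visit denominators (`n_evaluable`) count subjects with ≥ 1 non-missing
item-set score at that visit, so N varies with attrition. Percentages are
reported to one decimal, half-up.

## 2. Analysis population

Two record-level filters define the analysis set:

1. only protocol-class *scheduled* visits are analyzed (unscheduled,
   telephone, safety and washout visits are dropped — they are usually
   adverse-event driven and do not consistently carry the scale);
2. subjects with no scored item at any post-baseline scheduled visit are
   removed entirely (they cannot contribute to change-from-baseline).

Both filters are idempotent and never add records. Visit identity is by
scheduled visit code; mapping calendar dates into visit windows for real
trial exports is out of scope.

## 3. Synthetic cohort generator

The generator exists so the whole pipeline is testable without
access-controlled trial data. It is a stated world, not a tuning knob: the
defaults were calibrated once against the published baseline profile of a
297-subject de novo PD cohort and then frozen.

Subject *i*, item *j*, visit at nominal time *t* (months):

    x_ijt  = a_i + b_i (t/12) m_i − dip(t) + d_j + ε_ijt
    score  = #{ cutpoints ≤ x_ijt }      (ordinal 0–4)

| parameter | default | meaning |
|---|---|---|
| `intercept_mean`, `intercept_sd` | 0.35, 0.85 | latent baseline severity a_i (latent units) |
| `slope_mean`, `slope_sd` | 0.35, 0.35 | progression b_i, latent units / year |
| `treatment_slope_multiplier` | 1.0 | m_i for the active arm (1 = futile treatment, arms exchangeable) |
| `dip_amplitude`, `dip_duration` | 0.35, 6 mo | transient post-baseline improvement |
| `flicker_sd` | 0.55 | i.i.d. per item-visit response instability ε |
| `category_cutpoints` | (0, 1.5, 3, 4.5) | latent → ordinal mapping |
| `item_difficulties` | per-part linspace | fixed offsets d_j; common → rare within each part |
| `stx_baseline_hazard`, `stx_severity_coef` | 0.028 / mo, 0.25 | discrete-time logistic hazard of starting symptomatic therapy |
| `dropout_hazard` | 0.006 / mo | constant monthly dropout hazard |
| `missing_item_prob` | 0.01 | per present item-visit masking |

Design choices worth recording:

- **One latent severity per subject** drives all items (graded-response
  flavour). This is the simplest mechanism that yields both progression
  and correlated item endorsement; it has no item-specific trajectories.
- **The dip applies only after baseline**: dip(0) = 0 and
  dip(t) = A·max(0, 1 − t/duration) for t > 0. A formulation that
  subtracts the most at t = 0 would *raise* group means from baseline —
  the opposite of the transient improvement the term emulates. The
  amplitude is a free calibration choice; no published magnitude exists.
- **Flicker is fresh noise each item-visit.** It deliberately produces
  baseline-vs-week-3 endorsement reversals — the instability phenomenon
  the stability rules are designed to probe.
- **STx is absorbing and has no effect on scores** by default: observed
  12-month ES rates do not differ by STx status, so no symptomatic-benefit
  term is included. Severity feeds the hazard (`stx_severity_coef > 0`),
  so STx-yes subjects are more severe on average — which reproduces the
  elevated early ES rates in that group.
- **Draw order is fixed** (subject block, flicker cube subject-major,
  STx uniforms, dropout uniforms, missingness mask) from one seeded
  generator, so identical config + seed gives byte-identical datasets.

Calibration targets (verified by seeded tests): baseline IB+II sum mean in
[8, 12] and SD in [5, 8]; symptomatic-therapy uptake by month 12 in
[0.2, 0.4]; group-mean IB+II sum non-increasing from baseline to week 6.

What a green calibration test does **not** establish: the generator's
homogeneous flicker lacks the between-subject heterogeneity of real
patient-reported data, so it *overstates* threshold-1 ES prevalence at
month 12 (~87 % vs ~75 % in the real cohort) and understates the spread of
per-subject event counts; threshold-3 events are rarer than observed. Real
features not modelled at all: rater effects for Part III, levodopa
pharmacodynamics after STx, visit-window jitter, administrative censoring
from early trial termination, informative dropout.

## 4. Statistical suite

- Proportion tests: chi-square with Yates continuity correction (one- and
  two-sample), matching the defaults of the statistical environment such
  analyses are habitually reported from; the correction is switchable.
  Degenerate pooled margins return p = 1 with a warning flag.
- Location tests: Welch (unequal-variance) t-test; Wilcoxon rank-sum with
  exact enumeration when the pooled sample is ≤ 20 and tie-free, else the
  tie- and continuity-corrected normal approximation.
- Correlations: Pearson (p via the t transform on n − 2 df) and Spearman
  (Pearson on mid-ranks). Summed-score blocks (Part I = IA+IB, II, III,
  I+II+III, IB+II) are complete-case: one missing item invalidates the
  sum; no imputation anywhere. Correlating the 0/1 ES indicator with a
  sum is the point-biserial coefficient — our reading of a per-subject
  "number of ES patients" correlate, flagged in output metadata. Cells
  with < 3 complete pairs or a constant measure are marked unavailable.
- No multiple-testing adjustment: tables report raw p-values.

## 5. Exact Fisher power and sample size

The two-sided Fisher p-value uses the probability-mass ordering: condition
on the margins, sum the hypergeometric probabilities of all tables no more
probable than the observed one (ties compared at 1e-7 relative tolerance).

Power is unconditional exact: enumerate every joint outcome
(x₁, x₂) ∈ {0..n}², apply the test, and sum
Bin(x₁; n, p₁)·Bin(x₂; n, p₂) over rejections. Outcomes sharing a column
margin share one hypergeometric distribution, so the (n+1)² grid costs
O(n²) pmf evaluations and the grid is cached per n.

The minimum per-arm n scans upward from 2 and reports the *first* crossing
of the target power; the exact power function is saw-toothed, so larger n
can momentarily dip back below the target. The search cap defaults to
10 000. Dropout inflation is ceil(n / (1 − d)) with a guard against float
noise on exact quotients. When an effect is given as a relative reduction,
the treated rate is first rounded to one decimal on the percent scale
(75.1 % → 52.6 %), because that is the precision at which such designs are
specified and published.

A normal-approximation or arcsine-effect-size shortcut does **not**
reproduce the published per-arm 78 for 75.1 % vs 52.6 % at α = 0.05 and
power 0.8; the exact enumeration does (power 0.7983 at 77, 0.8046 at 78).
The acceptance test asserts 78 exactly and fails loudly on any ±1 drift.

## 6. Numerical and degenerate-input conventions

- Missing scores are explicit (<NA> / blank CSV field), never 0.
- Subjects lacking a baseline assessment raise an eligibility error in
  per-subject calls and contribute vacuously zero events in cohort tables.
- ES at the baseline visit is a domain error, as is the last-visit-before-
  therapy query for a subject not on therapy by the cutoff.
- Zero-variance inputs: correlation raises; the t-test returns p = 1 with
  a warning when both groups are constant and equal.
- All-zero or single-outcome 2×2 tables give Fisher p = 1.

## 7. Known limitations

- The pipeline analyzes nominal visit codes only; real-trial exports need
  external visit-window mapping first.
- The generator is calibrated to one cohort's baseline profile; its
  absolute ES percentages are not expected to match any real trial, and
  tests treat them as qualitative structure, not targets.
- Exact-power enumeration is O(n²) per candidate n and linear in the
  search range; designs needing thousands per arm are better served by
  asymptotic approximations (out of scope here beyond the search cap).
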