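# Methods

## Scores

Index4 counts four binary criteria (ECOG PS > 1, creatinine clearance
< 40 mL/min, albumin < 35 g/L, stage 4); CARG sums eleven weighted items to a
0–23 total mapped to low (0–5) / intermediate (6–9) / high (>= 10). Two
conventions deserve emphasis because they change individual patients' groups:

* **Strict thresholds.** Every criterion is worded as a strict inequality
  ("below 40", "older than 72") and is implemented that way: CrCl = 40.0,
  albumin = 35.0, age = 72 and CARG totals of exactly 5 or 9 all fall on the
  *lenient* side. Units are fixed (hemoglobin g/dL, albumin g/L, CrCl mL/min,
  LDH U/L) and the CSV layer rejects — never converts — other declarations.
* **No imputation.** A missing item aborts scoring for that patient with an
  error naming the field. Both scores are short; silently imputing one item
  can move a patient across a category boundary.
* The CARG instrument is sometimes described with a 0–19 range, but its
  stated item weights sum to 23; this implementation uses the stated weights,
  so totals up to 23 are attainable.
* The descriptive anemia cut-off used in cohort tables (< 12 g/dL men / < 11
  women) is deliberately a separate function from the CARG hemoglobin item
  (< 11 / < 10); conflating them is a common transcription error.
* `cockcroft_gault` is a convenience helper; the pipeline's canonical input
  is a precomputed creatinine clearance, since source datasets rarely state
  which formula (or which weight) produced their values.

## Evaluation statistics

* **Confusion metrics** are plain ratios; a zero denominator yields an
  *undefined* metric (`None`), not zero and not a record-level error.
  Percentages are rounded half-up to one decimal only at the reporting layer.
  When comparing against previously printed tables note that some published
  sources truncate rather than round; agreement is therefore asserted at the
  printed decimal (|difference| < 0.1 percentage points), not at half-up
  equality.
* **ROC/AUC** is computed on the raw ordinal totals (Index4 0–4, CARG 0–23)
  by default — collapsed categories are available via a flag — and equals the
  Mann–Whitney concordance probability with ties counted ½. The default 95%
  CI is DeLong's asymptotic interval via the placement-value decomposition
  (variance = var(case placements)/m + var(control placements)/n); a seeded
  bootstrap (2000 resamples) is the alternative. The DeLong implementation is
  cross-checked in the test suite against R's pROC.
* **McNemar** defaults to the central two-sided exact binomial test on the
  discordant counts; a continuity-corrected χ² flavour is available. The
  odds ratio b/c gets an exact conditional CI: Clopper–Pearson bounds on
  p = b/(b+c) mapped through p/(1−p). With c = 0 the OR is reported as
  infinite with a one-sided interval; b + c = 0 gives p = 1 and an undefined
  OR. The paired-comparison convention treats CARG as the standard and
  Index4 as the experimental tool: within the outcome-present stratum a tool
  is "correct" when its positivity rule fires, within the outcome-absent
  stratum when its negative-classification rule fires, and OR > 1 favours
  Index4.
* All tests are two-sided; p < 0.05 is used only for report annotation,
  never for filtering.

## Synthetic cohorts

The generator emulates a published 117-patient validation cohort known only
through aggregate tables. Design:

1. **Index4 item patterns.** The joint distribution of the four indicators
   over its 16 patterns is fitted once (SLSQP, ridge-regularised) with the
   published score distribution (61/28/15/13/0) as an exact constraint and
   the four item marginals as least-squares targets. The published tables
   are mutually inconsistent — the item counts imply a score total of 100
   points, the score distribution 97, and one albumin row differs from its
   own margin — so each item marginal lands about 0.65 percentage points
   below its printed value. The score distribution, which downstream
   statistics condition on, is exact.
2. **Attributes.** Age is truncated-normal (location 76.6, scale 5, floor
   70 — the printed mean/SD; under truncation the realized mean is 77.5 and
   the over-75 fraction 69%, vs. the also-printed 52.1%, another source
   inconsistency the model cannot reconcile). Sex, cancer type and
   non-metastatic stage are multinomial at the published frequencies,
   sampled independently (no joint was published). Labs are drawn uniformly
   within the band their indicator dictates (e.g. CrCl from (24, 40) when
   the low-CrCl indicator is set, (40, 110) otherwise); hemoglobin uses
   three sex-specific bands so the CARG item rate and the descriptive anemia
   rate (23.9%) are both honoured. LDH is missing completely at random at
   4/117.
3. **Questionnaire/treatment items** (falls, hearing, walking, medication
   help, social activity, polychemotherapy, dose) are free parameters.
   Functional items get a fixed probability bump for "frail" patients
   (ECOG > 1 or albumin < 35), inducing realistic correlation between the
   two scores beyond their shared labs. Base probabilities were tuned once
   by `scripts/calibrate_defaults.py` (Nelder-Mead on a 300k-patient common
   random-number objective, ridge-pulled toward clinical priors) so the
   CARG split matches 23/54/40; the frozen defaults reproduce it to within
   0.15 percentage points.
4. **Outcomes** depend on risk groups only — sufficient for every statistic
   the evaluation module computes, and stated as a simplification. The
   2×3 (Index4 group × CARG category) probability grids are solved by
   classical three-way iterative proportional fitting of the
   (group × group × outcome) cell-mass table, after raking the empirical
   joint to the exact study margins so both published stratum-rate sets
   become mutually consistent targets; convergence is below 1e-9 on expected
   counts. Probability-space raking (scaling the grid itself) oscillates
   near 1e-4 and is not used.
5. **Outcome sampling.** Default mode is `balanced`: within each group cell
   the number of events is the integer part of n·p plus one Bernoulli draw
   on the remainder, at randomly permuted positions. Each patient's marginal
   event probability is still exactly p, but cell counts carry almost no
   Monte-Carlo noise, so a single 50,000-patient cohort recovers every
   configured stratum rate to within 0.5 percentage points — the point of a
   calibration-replay generator. Classical i.i.d. `bernoulli` mode is
   available and is what the mean-recovery Monte-Carlo tests exercise; under
   it, per-stratum rates at n = 50,000 fluctuate with standard errors up to
   ~0.5 percentage points, which is why exact single-cohort replay requires
   the balanced mode.
6. **Length of stay** is drawn for admitted patients from normals centred at
   the published group means (12.3 / 18.5 days), SD 6, floored at 1.

What passing tests on these cohorts show: the pipeline (I/O → scoring →
evaluation) is correct for data whose marginal structure matches the
published cohort. What they cannot show: performance on real joint
structure. In particular, because outcomes condition on collapsed groups,
within-group score information is uninformative and synthetic AUCs
(~0.57 Index4, ~0.66 CARG for grade 3–4 toxicity) are necessarily lower than
the published patient-level AUCs (0.76, 0.83), which cannot be reproduced
from aggregates and are treated only as plausibility bounds.

## Reconstructed paired comparisons

The published report prints McNemar p-values, odds ratios and CIs but not
the discordant pairs themselves. The pairs shipped in
`geritox.reference.PUBLISHED_MCNEMAR` are reconstructed: b − c is forced by
the two tools' marginal correct counts, and b/c by the printed OR, which
determines (b, c) uniquely; every reconstructed pair then reproduces the
printed p-value and both CI bounds at their printed precision (the source
truncates decimals). They are packaged as machine-readable inputs, clearly
labelled as reconstructions.

## Numerical and degenerate-input choices

* Exact binomial/beta/hypergeometric computations go through scipy;
  enumeration oracles in the tests use exact integer/rational arithmetic.
* Confusion tables require non-empty inputs; ROC requires both classes;
  paired comparison requires a non-empty stratum; degenerate contingency
  tables (empty row/column) are errors.
* IPF infeasibility (targets no grid can satisfy) raises an error naming the
  worst-violated stratum constraint rather than returning a clipped grid.
* Problem sizes: the calibration script uses 300k/600k-patient cohorts; the
  acceptance script and recovery tests use 50,000; Monte-Carlo mean-recovery
  tests use 300 cohorts of 117.

## Known limitations

* Stage and cancer type are sampled independently; the real cohort shows
  association (e.g. breast cancers concentrated in low-risk groups).
* Outcomes are conditionally independent of raw attributes given risk
  groups, and the four outcomes are mutually independent given the cell —
  real ED visits and admissions are nested events.
* The questionnaire-item defaults are one of many parameter sets consistent
  with the published aggregates; they are calibration targets, not estimates
  of the true item prevalences.
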