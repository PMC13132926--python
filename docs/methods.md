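# Methods

This note documents the analytic conventions, the synthetic-data model and
the numerical choices behind `tswp`, in the order the pipeline applies
them.

## Trial stream and preprocessing

A trial log is long-format text, one row per response, with the block
context (kind, condition, duration, run) carried on every row; the
per-block table, including which single-task blocks serve as the
fast-switch reference for which switching block, is derived from it.
`trial_type` and `seq_position` are stored redundantly and cross-checked
against the task sequence, so malformed logs surface as named violations
rather than silent misscoring. Practice-phase trials are ingested but
excluded from analysis; the 60-s warm-up switching block at the start of
each run is generated and ingested but excluded from analysis summaries by
default (`include_warmup` flips this).

The exclusion cascade: responses slower than 5000 ms (strict) are flagged
first; among the remaining correct responses, RTs deviating more than 2
SDs (strict, sample SD with n−1) from the mean of their trial-type ×
block cell are flagged as outliers, in a single pass. Cells with fewer
than 3 eligible trials are never flagged (the SD is unreliable there).
Flags never delete rows. Discard rates are reported under two accounting
conventions — (A) too-long + outlier trials over all analyzed trials of
the condition, (B) additionally counting error trials, which leave only
the RT analyses — with A the default; under the generator's study
conditions convention A yields ≈ 4% (the suite asserts the 3–7% band).
Participant QC requires < 20% errors in every experimental block and
≥ 40 trials per task × condition cell.

## Fast-switch scoring

* **Threshold.** First quartile of eligible (correct, unflagged)
  single-task RTs from the run's subsequent single-task block(s),
  task-matched by default (`pooled` by config), linear-interpolation
  quantile (the common "type 7" rule). The quantile convention is
  config-exposed because classification counts can be
  threshold-sensitive. References from fewer than 4 RTs are computed but
  flagged `low_n`.
* **Candidacy.** Inclusive: RT ≤ threshold, on correct unflagged switch
  trials only.
* **Intervals.** The three same-task responses immediately preceding the
  switch, summed regardless of correctness (elapsed time is elapsed
  time); a run containing a too-long response yields a null interval. The
  first switch of a block has a truncated run and hence no interval.
* **Baseline.** Mean interval over the *non-candidate* switches of the
  same participant and condition, pooled across that condition's analyzed
  switching blocks (candidacy by the RT criterion alone; error and
  flagged switches are non-candidates). Condition-level pooling maximizes
  baseline stability.
* **Verdict.** A candidate stays fast iff interval − baseline ≤
  mean(single RT) − switch RT. Declassified candidates do not re-enter
  the baseline (single pass; no fixed-point iteration). Where the check
  is inapplicable — truncated run, null interval, undefined baseline —
  the candidate verdict stands. The benefit term uses the full-sample
  single-task mean (not the fastest-quartile mean); config-switchable.

One subtlety worth knowing: with the compensation check active, the fast
count is not exactly monotone in the threshold (newly promoted candidates
leave the baseline and shift it); the monotonicity property holds for
candidate counts always and for fast counts with the check disabled.

FSR = fast / correct switches; a participant with no correct switches in
a condition gets an explicit null (never a default 0) and the label
`unclassifiable` downstream.

## Classification

Cutoffs are c1 = mean + 1·SD and c3 = mean + 3·SD of a reference FSR
sample (proportions; affine-equivariant, so percent scales work
unchanged). Labels: serial < c1 ≤ semi-overlapper < c3 ≤ overlapper
(lower-inclusive at c1, inclusive at c3). Numeric cutoffs are deliberately
not shipped: callers supply an explicit pair or a reference sample, since
published cutoffs are anchored to a specific no-preview dataset.

A structural property of this procedure, visible in the recovery analysis
(`analysis/04_recovery_checks.py`): for any nonnegative reference sample,
c3 ≤ 3·c1, so the +1/+3 SD boundaries cannot be placed independently. A
reference distribution with a low mean (a few percent) can therefore not
simultaneously put c1 well below and c3 well above an intermediate group
whose FSR sits around 15%; on the simulated cohorts the semi-overlapper
group straddles c3 and classification accuracy against generative labels
plateaus near 0.73–0.79. This is a property of the cutoff procedure under
these group means, not of the implementation; the confusion matrix in the
recovery script makes the boundary cases explicit.

## Robust statistics

* **Trimmed mean** M_t removes g = ⌊n·trim⌋ per tail (default trim 0.20);
  the winsorized variance uses the winsorized sample with the n−1
  denominator and the same g; SE(M_t) = s_w / ((1 − 2·trim)·√n). trim = 0
  reduces everything to the classical statistics.
* **Between × within ANOVA** on trimmed means: per group, the winsorized
  covariance matrix over within levels (columns winsorized marginally,
  pairing preserved) scaled by (n−1)/(h(h−1)), h = n − 2g, estimates the
  covariance of the trimmed-mean vector; Johansen-type quadratic forms
  with successive-difference contrasts test the between, within and
  interaction effects against an adjusted F with estimated (df1, df2).
  Degenerate (e.g. constant) cells are handled with a pseudoinverse so
  the statistic is 0 rather than an error. The null simulation
  (`analysis/05_robust_calibration.py`: unequal n 15/30, variance ratio
  4:1, 2000 replicates) puts each effect's type-I error at 0.047–0.058
  at nominal 0.05.
* **AKP effect size**: c_γ · (M_t difference) / winsorized SD, pooled for
  independent samples, difference scores for paired contrasts. The
  scaling constant c_γ (the SD of a winsorized standard normal, ≈ 0.642
  at 20%) is evaluated from the normal integral at import, not
  hard-coded. 0.20 / 0.50 / 0.80 read as small / medium / large.
* **KMS effect size**: variance-weighted standardized separation of
  independent groups using trimmed means and normal-consistent winsorized
  variances, reported as 2·√(Σ qⱼ(mⱼ − m̄)²/vⱼ) so that two equal-sized,
  equal-variance groups a SD apart score 1 (Cohen's-d scale). For the
  omnibus within/interaction rows of the ANOVA table, AKP is computed on
  the extreme within-level difference scores (pooled, respectively
  between the extreme groups); these omnibus conventions are package
  choices, documented here because published robust effect-size variants
  differ.
* **Classical RM / mixed ANOVA** delegates to pingouin;
  Greenhouse–Geisser correction is applied to within effects with more
  than two levels (ε = 1 exactly at two levels), and partial η² is
  recomputed from the sums of squares as SS_effect/(SS_effect+SS_error).
  Constant-response designs return F = 0 by convention.

## Synthetic cohorts

The generator is a measurement-level emulator, not a cognitive process
model: its purpose is to give the pipeline inputs with known ground truth
(every injected fast event and latent parameter is recorded in sidecar
tables).

* **Blocks.** Per condition run: 60-s warm-up switching, two 120-s
  switching blocks, one 60-s single-task block per task (single-task
  order alternating across runs). Trials are drawn until the summed RT
  crosses the duration; the crossing trial is kept. Condition order
  follows a Williams design (balanced Latin square); in the
  preview-position experiment the full-preview baseline always comes
  first. Order effects are not modelled in the RTs.
* **RTs.** Lognormal, median 600 ms (per-participant jitter 0.06 on the
  log scale), σ = 0.25 — CV ≈ 25%, typical of speeded classification.
  Repeat and pre-switch trials add 20 / 10 ms. Non-fast switches add a
  per-participant switch cost drawn uniformly from 50–500 ms (serial
  mode) or 90–160 ms (semi-overlappers and overlappers, whose residual
  switch costs are small). These ranges also give serial participants a
  small, bounded rate of ordinary switches crossing the quartile
  threshold — matching the fact that empirical no-preview FSRs are
  rarely exactly zero and have real between-person spread.
* **Preview use.** When the preview is visible somewhere in the preceding
  run, the upcoming switch is a "fast event" with the participant's use
  probability attached to the *latest* visible position (so all
  preview-length conditions load on position 3, while the
  preview-position conditions dissociate positions). Mode means at
  position 3 are 0.02 / 0.15 / 0.45; per-participant propensities are
  Beta-dispersed (concentration 10 for the serial mode — strongly
  right-skewed, as in empirical reference distributions — and 150
  otherwise). A fast event draws the switch RT from a prepared-response
  distribution (lognormal, median 0.4 × the single-task median, σ = 0.1):
  fast enough to clear the quartile threshold and to keep the benefit
  term well above interval noise, but not so extreme that the 2-SD
  trimming removes it from low-rate participants' switch cells. With
  probability 0.2 a used preview costs 100 ms of compensatory
  prolongation, spread over the three preceding trials — small, because
  consistent preview users show no elevated pre-switch RTs. Errors are
  independent Bernoulli(0.035).

These defaults are the package's study conditions: under them the cohort
averages ≈ 195 single-task and ≈ 360 switching trials per condition,
discard rates ≈ 4%, per-mode FSR recovery errors ≤ ≈ 0.065 and a
position-selectivity gap ≈ 0.16 (all recomputed by
`scripts/acceptance.py`). The generator deliberately omits many features
of real data — practice effects, sequential dependencies, post-error
slowing, speed–accuracy coupling, condition-order effects — so passing
recovery tests demonstrates that the pipeline measures what the generator
injects, not that real data are this clean.

## Problem sizes

The test suite and acceptance script use cohorts of 48 participants (16
per mode, the study's scale), ~120k trials per cohort, 2000-replicate
null simulations, and miniature cohorts (30–45-s blocks) for the
brute-force oracle comparisons; the full suite runs in about a minute and
the acceptance script in about twenty seconds.

## Known limitations

* The compensation correction has an intrinsic false-declassification
  rate driven by interval noise (three-trial sums fluctuate); on the
  default cohorts it removes ~10–15% of genuinely injected fast events.
  It is faithful to the published rule; users comparing FSRs across
  pipelines should be aware the corrected FSR is a thresholded,
  conservative measure of preview use, not an unbiased use-rate
  estimate.
* The +1/+3 SD classification boundaries inherit the c3 ≤ 3·c1 constraint
  discussed above; intermediate-rate groups near a boundary will straddle
  it.
* Robust ANOVA covers one-between × one-within designs (the FSR
  analyses); three-factor robust designs are out of scope, as are
  process-level (diffusion-model) analyses.
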