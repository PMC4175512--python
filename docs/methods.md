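# Methods

## Setting and estimands

Two placebo-controlled randomized trials of different active drugs in the
same indication. Trial A (the "IPD trial") contributes patient-level data;
trial B (the "comparator") contributes only published aggregates: baseline
medians/proportions, Kaplan–Meier figures with numbers-at-risk, hazard
ratios with 95% CIs, and adverse-event rates. Both trials let placebo
patients cross over to active therapy after progression, so intention-to-
treat overall survival (OS) in each placebo arm partially reflects active
treatment. Progression-free survival (PFS) is unaffected by crossover.

Four estimands are assembled:

1. **Anchored active-vs-active PFS** through the common placebo comparator
   (Bucher combination of relative effects).
2. **Unanchored active-vs-active OS/PFS**, pooling the weighted IPD active
   arm with the comparator's reconstructed active arm; placebo arms are
   excluded for OS because crossover destroys the common comparator.
3. **External-control OS**: weighted IPD active arm versus the comparator's
   placebo arm (which itself includes crossover, so the contrast
   understates the effect against a pure placebo), summarized as an HR and
   as numbers needed to treat at 12 and 24 months.
4. **Negative control**: placebo-arm PFS across trials. Under exchangeability
   after weighting this HR is 1; a deviation estimates the direction and
   size of residual (unmeasured) imbalance.

## Weight estimation

Weights make the IPD trial's weighted baseline summaries equal the
comparator's reported ones. Writing `x_i` for the matched covariate vector
(binary indicators; continuous covariates enter as `1{x > reported median}`
balanced to 0.5, ties counting as below) and `x̄*` for the targets, the
weight is `w_i = exp(a'(x_i − x̄*))` with `a` the minimizer of the convex
objective `Q(a) = Σ_i exp(a'(x_i − x̄*))`. `∇Q = 0` is exactly the moment
condition `Σ_i w_i (x_i − x̄*) = 0`, i.e. exact balance. This
method-of-moments exponential tilting is the standard population-adjustment
estimator when the comparator has no IPD to support an actual enrolment
logistic regression; the two are equivalent up to normalization.

Numerics: damped Newton iteration with analytic gradient and Hessian from
`a = 0`; convergence when the weighted-mean deviation of every matched
column is ≤ 1e-10, verified post hoc at ≤ 1e-8. A diverging coefficient norm
(‖a‖∞ > 200) signals a target outside the convex hull of the sample
(separation) and raises an error that says so, distinct from a plain
tolerance failure. `ESS = (Σw)²/Σw²` reports the surviving information;
weights are used raw for within-trial estimation and rescaled only where a
convention is needed (below).

**Weight normalization in pooled fits.** A weighted Cox fit of the IPD arm
*alone* is invariant to rescaling all weights. A *pooled* fit against a
unit-weight pseudo-IPD arm is not: the relative total mass of the two arms
enters the risk sets. The package therefore rescales the IPD weights to sum
to the ESS before pooling. This pins the weighted arm's mass to its actual
information content (avoiding anti-conservative risk-set dominance) and
restores invariance of the pooled estimate to the input weights' scale.

**Eligibility and missingness.** Before weighting, patients in ECOG grades
the comparator excluded (grade 2 by default) are removed, then complete-case
removal on the matched covariates; both counts are reported. **Balance
tests** on the unweighted sample use a pooled two-proportion chi-square
(no continuity correction) against the reported proportion at the reported
n; for continuous covariates only a median is published, so the t
approximation treats the reported median as the comparator location and
borrows the IPD standard deviation — adequate for flagging gross imbalance,
not a calibrated test under skew.

## Pseudo-IPD reconstruction

Digitized curve coordinates `(t_j, S_j)` plus the at-risk table `(t_k, n_k)`
are converted to per-patient times by iterative interval allocation: within
each interval between at-risk times, an integer censoring count is guessed,
censor times are spread uniformly over the interval's interior, event counts
at each digitized point follow from the survival ratio against the running
product-limit value, and the guess is adjusted until the implied count at
the next at-risk time matches the published one. Conventions that matter:

- the survival drop at an interval's right boundary belongs to that
  interval, and the published at-risk count is compared *after* that drop —
  the consistent choice when curves are digitized on a regular grid;
- event times sit exactly at digitized drop times (preserving visible
  steps); rounding is half-away-from-zero for determinism;
- beyond the last at-risk time, the prior censoring rate is extrapolated,
  or, when a reported total event count is supplied, the censoring count is
  iterated until the total is honored;
- a published count larger than the curve permits is reduced with a logged
  note; a curve that keeps dropping after the allocation is exhausted
  raises an error naming the interval.

Each reconstruction should be verified against whatever the source reported:
the package recomputes the HR (against a paired reconstructed arm) and the
median, with default pass tolerances of 10% relative on the HR and 2 months
on the median, both configurable. On grid-digitized synthetic curves the
reconstruction reproduces the digitized points essentially exactly; real
figure extraction adds digitization noise this cannot remove.

## Survival estimation

Weighted Kaplan–Meier and weighted Cox proportional hazards via lifelines:
Efron tie handling, robust sandwich variance treating weights as fixed
(the standard choice in population adjustment; it ignores the estimation of
the weights themselves), Wald CIs and p-values on the log scale with the
normal quantile fixed at 1.959964. A fit with no weighted events in a group
is refused as non-estimable rather than returned at a boundary.

NNT at horizon `h` is `1/(S_active(h) − S_control(h))` from the weighted KM
curves, reported to one decimal; evaluation beyond follow-up is flagged as
extrapolated, a zero difference yields a flagged non-finite result, and a
negative difference is reported as number needed to harm.

Adverse events: IPD observations are censored at the matching comparator
arm's maximum follow-up before counting, then each event's contrast is the
ratio of within-trial odds ratios with Woolf variance. Weighted 2×2 cells
are weighted proportions scaled to the per-arm ESS, so the variance reflects
post-weighting information rather than raw weighted counts. Zero cells get
the 0.5 continuity correction (flagged); events under the comparator's 5%
reporting threshold are flagged non-comparable; no multiplicity adjustment
is applied by design (exploratory contrasts), though downstream correction
is trivial on the returned p-values.

## Synthetic trial generator

The generator emulates the data situation, not any particular dataset.
Conditional on covariates, progression and death times are exponential with
log-linear effects (proportional hazards by construction); PFS is the
minimum of progression and death; a Bernoulli-selected fraction of placebo
progressors crosses over exactly at progression, after which the death
hazard is multiplied by `exp(post_crossover_log_hr_os)` (piecewise-constant
hazard; the memoryless redraw is exact). Administrative censoring at each
trial's cutoff. Age is a shifted gamma jointly calibrated so that its median
and its >64 tail probability match the configured margins; categorical
covariates are drawn independently (only marginals are published, so no
correlation structure is identified).

Default study conditions mirror the emulated pair of trials: IPD trial
n = 205/arm with pre-match margins (ECOG-0 68.8%, prior somatostatin
analogues 49.2%, prior chemotherapy 48.7%, ≥3 disease sites 35.0%, distant
metastases 96.2%, median age 58), placebo median PFS 4.6 months, PFS HR
0.35, OS HR 0.61, 73% crossover, 39-month cutoff; comparator n = 86/arm at
its reported margins, placebo median PFS 5.5 months, PFS HR 0.42, 69%
crossover, 30-month cutoff. The differing placebo PFS medians build a true
negative-control hazard ratio of ≈1.2 into the default scenario. Prognostic
covariate effects (ECOG-0 −0.5, prior chemotherapy +0.25, ≥3 sites +0.30,
distant metastases +0.35 on the log-hazard) are moderate oncology-scale
values chosen once; the post-crossover hazard ratio 0.70 produces visible
ITT OS attenuation. Adverse-event onsets are exponential with arm-specific
monthly hazards chosen so each emulated drug has its characteristic excess
(edema/fever vs neutropenia/hypertension).

What the generator does *not* emulate: scan-schedule interval censoring of
progression (both real trials assessed on imaging grids; an accurate model
is unidentified from the published information), covariate correlation,
non-proportional hazards, dropout other than administrative censoring, and
delayed crossover. Passing tests therefore demonstrate the estimation
machinery's correctness under the stated generating model, not robustness
to these real-data features.

## Validation experiments and problem sizes

- **Bias removal** (`crosstrial.validation.bias_recovery_experiment`): one
  binary prognostic covariate (log-HR 0.7) at prevalence 0.70 in the IPD
  trial vs 0.30 in the comparator — an imbalance of the size seen between
  real trial populations. 500 replicate trial pairs (150 vs 100 per active
  arm); truth is the marginal log-HR from a 100,000-per-arm simulation drawn
  from the *comparator's* covariate distribution, fitted with
  scikit-survival as an independent implementation (the marginal HR of a
  covariate mixture has no closed form, and with continuous times the tie
  convention is immaterial). The unadjusted comparison is biased by >30 MC
  SEs; the matching-adjusted one is within 3.
- **Reconstruction round trip**: two exponential arms, n = 200 each, rates
  0.05 and 0.025/month, 40-month cutoff, 1-month digitization grid, at-risk
  every 8 months; the refitted log-HR lands within 0.05 (typically < 0.005)
  of the IPD fit.
- **Oracle equivalences**: the weighted Cox log-HR against a 1e-4 grid
  search of a hand-coded partial likelihood; weighted KM against a
  brute-force product over risk sets; the tilting coefficient against a
  bisection root of the scalar moment equation.

These sizes keep the full test suite under ~2 minutes while leaving every
Monte-Carlo margin wide.

## Known limitations

- Sandwich variance conditions on the estimated weights; bootstrap-style
  weight-uncertainty propagation is not implemented.
- Unanchored comparisons inherit the usual assumption that *all* prognostic
  differences are captured by the matched covariates; the negative control
  can detect, but not correct, violations.
- The balance t-test for continuous covariates is a location approximation
  (median treated as mean, IPD dispersion borrowed).
- Reconstruction assumes noise-free curve coordinates; digitization error in
  real extractions propagates into the pseudo-IPD and is only caught by the
  HR/median verification step.
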