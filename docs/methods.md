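# Methods

`vlpag` implements the complete analysis chain for single-unit recordings
from the ventrolateral periaqueductal gray (vlPAG) during three-cue
probabilistic fear discrimination, together with a synthetic session
generator that lets every stage run at desk scale.  This note documents the
models, the conventions the code commits to where the experimental
literature leaves them open, what the generator does and does not emulate,
and the problem sizes the shipped tests use.

## The behavioral task and its data

A session is 32 trials of Pavlovian discrimination over three 10 s auditory
cues: danger (foot-shock probability 1.00), uncertainty (0.375) and safety
(0.00).  Six danger, six uncertainty-shock, ten uncertainty-omission and
ten safety trials are presented in random order; the 0.5 s shock begins
2 s after cue offset on shocked trials.  The realized uncertainty
composition 6/16 = 0.375 equals the programmed probability exactly, and
`SessionDesign.validate` enforces this identity (to 1e-9) for the default
design.  Animals nose-poke for food on a variable-interval schedule
throughout; fear is read out as conditioned suppression of poking.

All times are seconds from session start (float64); analysis windows are
half-open `[t0, t1)`; trial indices are 1-based.  Sessions are stored as
plain-text bundles (JSON manifest + CSVs with full float precision) for
diffability; no proprietary acquisition formats are parsed.

## Fear output: suppression ratios

For a trial with pre-cue baseline poke rate `b` and cue poke rate `c`, the
suppression ratio is

    rho = (b - c) / (b + c)

so 1 means complete suppression (high fear), 0 none, negative values
facilitation.  The ratio is computed for the whole 10 s cue (*total fear*),
for each 1 s cue interval (*interval fear*), and for each 500 ms post-cue
window (used by the post-cue regressions; the same definition is applied
without modification).  Conventions:

* **Baseline window** — 10 s immediately pre-cue, configurable.  The
  source procedure does not state the behavioral baseline length; 10 s is
  long enough to stabilize rate estimates at ~1 poke/s and is validated
  not to reach into the previous trial's shock window.
* **Undefined ratios** — a 0/0 ratio is NaN, excluded from averages and
  counted, never imputed as 0: a silent zero would read as "no fear".
* **Short-interval inflation** — at low poke rates, expected interval
  ratios exceed the total-cue ratio for the *same* underlying behavior
  (a property of the ratio of small Poisson counts).  The test suite
  reproduces this; interval ratios are therefore treated as relative, not
  absolute, measures of fear.

Cross-session discrimination summaries use sessions as the statistical
unit (per-session per-cue means, paired t-tests per cue pair, Bonferroni
0.05/10 for the ten interval-wise tests).

## Unit classification

Each unit carries three features: baseline firing rate (mean over 2 s
pre-cue windows), waveform half-duration ((trough − peak time)/2, ms) and
amplitude ratio ((n − p)/(n + p), maximal depolarization vs. initial
hyperpolarization).  K-means with k = 2 partitions units into low- and
high-firing-rate classes (LFR/HFR); features are standardized to unit
variance first (the sources are silent on scaling; standardization makes
the observation that rate alone drives membership a finding rather than an
artifact), the seed is fixed and exposed, and a per-feature one-way ANOVA
across clusters is reported either way.

Cue-responsiveness screening is a paired two-tailed t-test of per-trial
2 s baseline rate against the first (or last) 1 s cue interval, per cue,
uncertainty trial types collapsed, at p < 0.05/3 ≈ 0.017.  A flag
additionally requires a mean *increase* (the screen targets excitatory
responses).  Labels are assigned by precedence: first-interval responsive
→ onset; else last-interval responsive and LFR → ramping; else
last-interval responsive and HFR → hfr_cue_responsive; else nonresponsive.
Onset units falling in the LFR class is verified empirically on synthetic
cohorts, not enforced.

## Firing normalization

Two Z schemes, both using the population SD (divide by N; the choice is
not recoverable from the sources and statistical conclusions are invariant
to it — it is fixed here so the contracts are exact):

1. **Whole-epoch.**  Rates in 100 ms bins from 10 s pre-cue to 12 s
   post-offset (320 bins for a 10 s cue), averaged per trial type,
   baseline-subtracted (that type's 2 s pre-cue mean), then Z-scored with
   one mean/SD pooled over all trial types × bins.  Phasic excitation
   contributes to the pooled mean, so baseline Z is below zero for
   responsive units — a visible and intended consequence.
2. **Per-interval.**  For one interval of interest, each trial's
   differential rate (interval minus that trial's own 2 s baseline) is
   computed and the 32 values are Z-scored across trials.  This maximizes
   the firing distribution within the interval and is the response
   variable of every trial-by-trial regression.

Constant-rate units (zero SD) raise a normalization error and are excluded
with a log entry; the pipeline aggregates exclusions in its report.
PSTH smoothing is a 5-bin centered moving average whose boundary-truncated
kernels are renormalized per input bin, so total area is conserved
exactly.

## Population analyses

* **Sliding departure** — paired t-tests across units between two cues'
  population Z in a 1 s window stepped at 100 ms across the cue
  (91 windows); departure is the start time of the first window below
  threshold.  The Bonferroni divisor defaults to windows × comparisons
  (182 for the two standard comparisons) and is configurable, including
  the fixed divisor of 200 used in prior reports whose window count
  cannot be reconstructed exactly.
* **Rate of increase** — (Z in last window − Z in departure window) / Δt;
  NaN-flagged when no departure exists or it coincides with the last
  window.
* **Pattern categorization** — each unit's mean Z to the three cues maps
  to one of six strict orderings; ties (measure-zero for continuous Z)
  break deterministically by danger > uncertainty > safety priority and
  are logged.  Chance counts come from 1000 within-unit shuffles of the
  three values; box-plot summaries (median, quartiles, most extreme
  non-outliers within 1.5 IQR) are reported and an observed count above
  the upper whisker is flagged.
* **Bias tests** — Pearson R² with its t-based p, plus an exact two-tailed
  binomial sign test excluding ties (all-ties → NaN).  Note the exact sign
  test has a discrete, conservative null: its p-values are not uniform
  under the null, only valid (P(p ≤ α) ≤ α), and the tests assert exactly
  that.
* **Proportions** — Pearson chi-square on the 2×2 table, no continuity
  correction by default (Yates by flag).
* **Poke-cessation control** — spontaneous poke-free gaps ≥ 5 s lying
  wholly inside inter-trial intervals; firing in the 2 s after gap onset
  (last poke) is compared to the 2 s before by paired t-test.  Gap
  threshold and windows are package conventions (none are stated in the
  sources) and are recorded in the result object.

## Trial-by-trial regression

For one unit and one interval, the 32 trials (ordered by type: danger,
uncertainty-shock, uncertainty-omission, safety) form the design

    z = b0 + b1 * interval_fear + b2 * total_fear + b3 * probability + e

fit by OLS with classical n − k t-based coefficient p-values (the contract
of any textbook least-squares routine; no small-sample correction is
applied because none is indicated).  Rank deficiency — e.g. zero
behavioral variance making fear columns constant — raises an error naming
the collinear columns.

The packaged example table (32 trials of first-interval firing of an onset
unit, shipped as `fixtures/worked_example_regression.csv`) reproduces
betas 0.24 / −0.14 / 2.19 at two decimals; full-precision values are
0.2442, −0.1372, 2.1905.

* **Interval sweep** — the fit repeated over the ten 1 s cue intervals;
  population summaries report mean ± SEM per regressor per interval with
  one-sample t-tests against zero at Bonferroni 0.05/10 = 0.005.
* **Threat tuning** — nine refits with the uncertainty probability
  assignment swept over 0–1 in 0.125 steps (danger fixed at 1, safety at
  0); the mean probability beta per assignment forms the tuning curve and
  its argmax is the peak.  The curve value at 0.375 equals the base fit
  exactly.  The top of the curve is intrinsically flat (for the 6/16/10
  composition, the pure-probability drop from the peak to its neighbors
  is ~3%), so population curves should be pooled across sessions before
  taking the argmax; single-session cohorts share one behavioral
  realization and their argmax is unstable between adjacent grid points.
* **Post-cue regression** — 500 ms intervals over the 5 s after cue
  offset, total fear removed (it samples only the cue period) and the
  2.0–2.5 s shock interval excluded: nine fits with
  {constant, interval fear, probability}.  Uncertainty trial types are
  split for post-cue alignment but keep the single 0.375 probability.
* **Beta correlation matrix** — per-unit probability betas correlated
  between the nine post-cue intervals; the 4 delay × 5 post-shock block
  (20 cells) is summarized by significant-cell counts at p < 0.05 and at
  0.05/5, and two populations' proportions are compared by chi-square.
* **Pairs analysis** — per 1 s interval, simple regression of one unit's
  per-trial Z on a simultaneously recorded unit's (with intercept);
  intervals with significant negative slope are flagged as evidence
  against independence.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
the biology that produced it.

* **Trials** — exact 6/6/10/10 composition, uniformly random order,
  inter-trial intervals `min_iti + Exponential(mean_iti − min_iti)` with
  mean 3.5 min by default (the stated mean; the distribution itself is a
  package choice) and a configurable shorter mean for desk runs.
  `min_iti` must exceed 12.5 s so the 10 s behavioral baseline clears the
  previous trial's shock.
* **Latent fear state** — each trial draws a latent suppression target
  `rho = clip(target_cue + N(0, trial_noise_sd), rho_floor, 1)`.  Defaults:
  targets 0.80 / 0.53 / 0.03 (the session-mean ratios the task produces);
  `trial_noise_sd = 0.25`, matching the within-cue spread of per-trial
  total fear visible in the published per-trial table (~0.27 for
  uncertainty, ~0.34 for safety, danger compressed by the ratio ceiling);
  `rho_floor = −0.8`, bounding the implied poke rate at 9× baseline
  because the ratio inversion diverges as rho → −1.  This trial-level
  variance is what keeps interval fear, total fear and probability from
  being collinear in synthetic regressions.
* **Pokes** — homogeneous Poisson at `baseline_poke_rate` (default
  1 poke/s, a typical variable-interval response rate) outside cues;
  during each cue the rate is the latent target inverted through the
  ratio, `b(1 − rho)/(1 + rho)`, optionally shaped per 1 s interval.
  Measured session-mean ratios round-trip to within ±0.05 of the targets.
* **Spikes** — inhomogeneous Poisson by exact thinning (baseline train
  everywhere; within modulated windows, candidates at the bounding rate
  thinned by intensity/bound; intensities clipped at zero).  Profiles:
  onset (gain × exp(−t/1.5 s) from cue onset, confined to the cue),
  ramping (gain rising linearly from 2 s after onset to the shock time,
  sustained through the delay, truncated after shock), hfr (step over the
  last cue second and delay on a high baseline) and nonresponsive.  Decay
  constants and ramp onsets are qualitative choices — no quantitative
  shapes are published — and are exposed as configuration.  Gains default
  to a few-fold of baseline; the HFR gain (12 Hz on a 15 Hz baseline) is
  sized so a planted step is reliably detectable by the paired screen at
  six danger trials, which is what membership in a "cue-responsive" class
  means operationally.  Ramping units weight fear and probability equally
  (8 Hz each), consistent with the two betas being statistically
  indistinguishable in the recorded ramping population.
* **Fear coupling is latent, not measured.**  Units with `fear_gain ≠ 0`
  receive the latent rho, not the measured ratio.  The measured ratio is
  then an errors-in-variables proxy in the regression, so the total-fear
  regressor captures the neural fear component only partially — which is
  why a mixed fear+probability cohort's tuning curve peaks right of 0.375
  (at 0.5–0.625), as a mixed population should.  Coupling to the measured
  ratio instead would let the regressor absorb the fear signal exactly
  and pin the peak at 0.375 regardless of mixing.
* **Shock artifact** — spikes in the 500 ms shock window are optionally
  zeroed (default on), mimicking the exclusion of that window from
  analysis in recordings where artifacts cannot be ruled out.

What the generator does **not** emulate: learning within or across
sessions, reward-delivery dynamics, non-Poisson spike statistics
(refractoriness, bursting), electrode drift, spike-sorting errors, and
any coupling between poke micro-structure and spiking beyond the shared
latent fear state.  Passing tests therefore certify the *analysis
machinery* — its algebra, calibration and power at the design's trial
counts — not the biological claims themselves.

## Problem sizes and numerical choices

The shipped test suite runs sessions with a 40 s mean ITI (the design
exposes it; composition and timing are otherwise the defaults), cohorts of
tens of units, 300-unit null screens, 1000-design OLS oracle comparisons
and 1000-shuffle pattern nulls; the whole suite completes in about half a
minute on one CPU.  The acceptance script simulates five independent
50-unit cohorts for the tuning-recovery target.  Statistical tolerances in
tests are 3 standard errors (or 3-sigma Monte-Carlo bounds) unless an
exact contract applies; exact contracts (Z moments, OLS vs. normal
equations, area conservation) are asserted at 1e-9.  Seeds are fixed
everywhere; `numpy.random.SeedSequence` spawning keeps streams independent
across sessions, stages and units.

## Known limitations

* The tuning-curve argmax is a coarse statistic on a flat-topped curve;
  conclusions about "the" peak should always be read together with the
  curve itself (the pipeline emits both).
* The exact sign test and the screening t-tests are applied to small
  per-cue trial counts (6–16), as in the source procedure; their power at
  these sizes is limited and quantified only by the shipped simulations.
* The printed chi-square values in the source literature for the
  delay/post-shock proportion comparison do not match the standard
  Pearson statistic for the stated tables under any obvious convention;
  this package reports the standard Pearson (and optional Yates) form and
  makes no attempt to reproduce the variant.
* Departure times are reported as window *start* times; other conventions
  (window center or end) would shift reported latencies by up to 1 s.
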