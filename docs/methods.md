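# Methods

This note records the model, the numerical choices, and the design
decisions behind `osascreen`, an audio-only screening pipeline for
obstructive sleep apnea (OSA) evaluated end-to-end on a synthetic cohort.

## Problem

Overnight audio of a sleeping subject carries two usable kinds of
information:

1. **Macro-structure** — regular breathing is quiet and periodic; apneic
   sleep alternates long silences with loud recovery breaths ("chokes").
   The *complexity* of the audio energy envelope over hours separates
   severe OSA from normal sleep.
2. **Micro-structure** — the first breath after an apnea (class **F**)
   has a different spectral shape than a snore (**S**) or ambient noise
   (**N**), so short event windows can be classified from spectral
   features.

The package implements both arms and evaluates them with
subject-stratified cross-validation against the binary screening label
`AHI >= 15` (apnea–hypopnea index, events per hour).

## Severity arm

### Envelope

From each recording we take a fixed 240-minute analysis window starting
30 minutes in (sleep-onset guard). The window is split into
non-overlapping segments of `dsr` seconds (`dsr ∈ {0.5, 1, 2}`), and the
envelope value of each segment is `ln(var(segment))` (population
variance, floored at `eps = 1e-12` to keep silence finite). The log
makes the envelope invariant (up to an additive constant, `2·ln c`) to
recording gain.

### Multiscale entropy (MSE)

Coarse-graining at scale `τ` averages `τ` consecutive envelope points in
non-overlapping blocks (length `⌊N/τ⌋`). Sample entropy
`H_s(m, r) = −ln(A/B)` where `B` counts ordered pairs of length-`m`
templates within Chebyshev distance `r·σ` (self-matches excluded) and
`A` the same at length `m+1`; both counts restrict template start
indices to `0..N−m−1` so the ratio is a true conditional probability.
`σ` is the standard deviation of the **scale-1** series and is reused at
every scale, so entropy changes across scales reflect structure, not
tolerance renormalisation. Undefined entropies (zero counts) are NaN
and handled downstream by imputation (LDA) or natively (forest).

Scales are `(1, 2, 4, 8, 16, 32, 65, 130, 180)`; the grid searched per
training set is `m ∈ 1..8`, `r ∈ {0.10, 0.15, 0.20, 0.25}`, `dsr` as
above.

The match counter enumerates, per diagonal offset `d = j−i`, runs of
consecutive element-wise matches; a run of length `L` contributes
matches of every template length up to `L`, so one O(N²) pass (numba)
yields exact counts for all `m` at once. Tests pin it integer-for-
integer against a brute-force pairwise oracle.

### Classifiers

* **LDA** (as commonly used in this literature): Gaussian
  class-conditionals with a *pooled diagonal* covariance — a naive-Bayes
  form. Missing features are train-mean imputed; zero-variance columns
  are dropped per training fold.
* **MCMC tree forest**: 50 trees, each with two axis-aligned splits and
  one linear leaf contribution `slope·x + offset`, applied only to
  samples passing both splits; samples with a missing contribution
  feature that pass the splits receive `0.5·slope·mean(mapped feature)`.
  Features are first mapped through a per-feature normal-quantile
  transform (rank/(n+1) → Φ⁻¹) fitted on training data; missing values
  stay missing and fail splits. The forest score is
  `inverse-logit(intercept + Σ tree contributions)` with
  `intercept = logit(mean outcome)`. A Metropolis–Hastings sampler
  re-randomises two trees per iteration jointly, accepting on the
  Bernoulli log-likelihood ratio; 10⁴ iterations, 20% burn-in, ~100
  thinned snapshots, 2 restarts; the prediction is the mean over all
  snapshot forests.

### Evaluation protocol

Outer loop: 5-fold cross-validation stratified by subject label —
events/envelopes of a subject never straddle a fold. Inner loop: per
outer training set, five random 70:30 subject splits score every
`(dsr, m, r)` combination by validation accuracy; the modal winner (ties
broken by mean accuracy, then the smallest key) is refit on the full
training set. Feature sets: the 9-scale MSE profile alone, and MSE +
demographics (gender, age, neck, height, weight, BMI, ESS). Metrics:
sensitivity, specificity, PPV, NPV, accuracy (percent; NaN on a zero
denominator) and rank (Mann–Whitney) AUC, averaged over outer folds.

The inner grid (~480 fits per outer fold per classifier) uses a lighter
sampler (25 trees, 2000 iterations, 1 restart) than the final refit;
the grid only has to *rank* parameter combinations, and this keeps a
full nested-CV run on one CPU in minutes. This is a deliberate
package-level choice, recorded here because results quote the final
(full-sampler) fits only.

## Event arm

Annotated events are clipped to fixed windows of 0.5/1/2/3 s starting at
the annotation onset; events shorter than the window, or running past
the end of the recording, are excluded (exclusion counts are reported
per class and are non-increasing in window length by construction).

Per window, one frame of features:

* **L** — LPC-8: autocorrelation method + Levinson–Durbin on the
  mean-removed window; minimum-phase by construction.
* **C** — MFCC c1..c12: linear detrend, Hamming window, next-power-of-2
  rFFT power spectrum, 24 HTK-mel triangular filters spanning 0..fs/2,
  log (floored at 1e-30), orthonormal DCT-II; c0 excluded.
* **D** — the 7 demographics of the subject.

LDA classifies F (positive) vs S/N over subject-stratified 5-fold CV for
every block combination (L, C, LC, LD, CD, LCD) and window size.

## Synthetic cohort

No clinical recordings ship with the package; a generator produces
cohorts whose *population statistics* match published OSA clinic
demographics per severity group (normal / snorer / mild / moderate /
severe): age, neck circumference, height, BMI, ESS and male fraction,
with weight derived as `BMI·height²` for internal consistency, and AHI
drawn within the group's band (<5, <5, 5–15, 15–30, ≥30). Truncation to
physiologic ranges is symmetric about the mean so group means stay
unbiased.

Audio mode renders, at 4 kHz: band-limited breathing noise amplitude-
modulated at 0.2–0.3 Hz; apneas as 10–60 s gaps at 2% amplitude, one per
equal time block so the realised event rate tracks the subject's AHI,
each terminated by a loud F burst (1–6 s, band-limited 200–1500 Hz);
snores as breath-gated harmonic trains (f0 60–180 Hz, 1–12 s) at
severity-dependent rates; noise transients (clicks/beeps/bursts,
0.5–15 s); events never overlap. Envelope-only fast mode shares the
same event schedule but renders the log-variance envelope directly
(amplitude-squared profile per window plus Gaussian jitter), which is
what makes 60-subject × 240-minute severity studies cheap.

**What the generator does not emulate:** hypopneas (all events are full
gaps), room acoustics/reverberation, position changes, bed-partner
sounds, night-to-night variability, and any correlation between
demographics and audio beyond the severity group. Absolute accuracy
numbers on this cohort are therefore optimistic and serve as
*recovery* checks (can the pipeline find structure that is present by
construction?), not clinical estimates.

## Numerical choices

* Tolerance anchor `σ` strictly from the scale-1 series; `r·σ`
  comparisons use `<=`.
* Envelope `eps = 1e-12`; MFCC log floor `1e-30`.
* Pooled LDA variance uses denominator `n − 2` (two estimated means).
* Quantile-map extremes clamp to the outermost training knots;
  interpolation is linear in between.
* All sub-seeds are drawn as `default_rng([seed, salt]).integers(2**31)`
  so every study is reproducible from one integer and seeds stay below
  2³¹.
* Thresholded predictions use `score >= 0.5`; clinical threshold rules
  use `value >= threshold`.

## Limitations

* Synthetic-cohort performance does not transfer to clinical data; the
  clinical baselines script exists to keep the comparison honest.
* The MH sampler explores by full re-randomisation of two trees; it is
  a valid symmetric-proposal chain but mixes slowly on large feature
  sets, hence restarts and pooling.
* The event arm classifies annotated events; it does not detect events
  in continuous audio.
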