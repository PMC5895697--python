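# Methods

This note records the models, conventions and numerical choices behind
rhythmkit, the defaults and why they were chosen, and what the synthetic
cohorts do and do not establish about real data.

## Cosinor model and phase conventions

Each calendar day (midnight to midnight on the recording clock) of each
analysis signal is fitted with a fixed-period 24-h sinusoid via the linear
parametrization

    y(t) = M + a·cos(ωt) + b·sin(ωt),   ω = 2π/24 h,

solved by ordinary least squares; amplitude = √(a²+b²), MESOR = M, and
phase = (24/2π)·atan2(b, a) mapped into [0, 24) — the clock time of the
fitted peak. Days with < 75% of minutes present are skipped (configurable
`min_coverage`); a zero-variance day returns amplitude 0 with the phase
flagged undefined (NaN), which then propagates through averages and
differences rather than silently becoming 0.

Daily fits are averaged per participant: MESOR and amplitude
arithmetically, phase as the **circular mean** on the 24-h circle. The
circular mean is the only convention invariant under shifts of the time
origin; an alternative phasor average (argument of the mean A·e^{iφ},
the literal "average of the daily sinusoids") is available via
`phase_method="phasor"`. Cross-modality differences are computed between
the averaged phases and wrapped to [−12, 12) h, positive meaning the first
signal peaks later; `difference_method="average_of_daily"` instead
averages per-day differences over days where both phases are defined.
The dispersion reported for phase differences is the ordinary (linear)
standard deviation of the wrapped values.

## Preprocessing

**Heart-rate cleaning.** One forward pass: each sample (never the first or
last) is compared with the *original* value at the preceding minute; if it
exceeds 150% or falls below 50% of it, it is replaced by the mean of the
original preceding and succeeding values. No convergence loop is run — the
rule describes a single comparison per recorded instance. Consequence
worth knowing: an isolated spike large enough (×>2 up, or any ×<0.6 down)
also makes its *successor* trip the ratio rule, so the expected adjusted
fraction is ≈1.6× the underlying spike rate under the generator's spike
law; the `CleanReport` counts what was actually replaced.

**Integration.** Activity and the sleep proxy are the moving sum of the
(globally) mean-removed signal over a 6-h window shifted one sample at a
time — equivalently a moving average times the window length. The window
is **centred** by default: a trailing window would delay every channel's
fitted phase by +3 h and contaminate the cross-modality differences that
are the core outputs. A centred 6-h moving mean multiplies a 24-h sinusoid
by sinc(π/4) = sin(π/4)/(π/4) ≈ 0.9003 and leaves its phase unchanged
(verified analytically and in tests, to < 0.02 h — the residual being the
half-sample asymmetry of an even-length window). `window_mode="trailing"`
exists for comparison. The *global* series mean is removed, not a
per-window mean: "remove the mean, then integrate" is taken literally.

**Gaps.** Interior gaps up to 60 min are linearly interpolated before
integration; longer gaps split the recording into segments that are
integrated independently and remain NaN, and the 75% daily-coverage rule
then excludes affected days from fitting. Both thresholds are explicit
configuration, not estimates.

**Sleep proxy.** The vertical acceleration axis, integrated exactly like
total acceleration. No posture or lying-down detection is attempted; the
"sleep" label means only this proxy.

## Mood components

PCA is fitted once on entries pooled across all participants and groups,
and frozen — per-group refits would change the meaning of scores between
groups. Items are standardized by default (correlation PCA): the items
share a 0–6 scale but differ several-fold in variance, and standardizing
keeps a single high-variance item from owning the first component;
covariance PCA is available (`pca_standardize: false`) and the choice is
recorded in `mood_model.yaml`. PCA signs being arbitrary, components are
oriented deterministically: component 1 so that the summed loading of
(sad, anxious, angry) is positive → "negative"; component 2 by
(elated, energetic) → "positive"; component 3 by irritable →
"irritable". Components are ordered by explained variance; the labels
carry meaning only when the cohort's variance structure actually ranks
negative > positive > irritable, as pooled mood-disorder cohorts do
(stable between-subject differences in negative mood dominate).

Scores are interpolated linearly to the 1-min grid between the first and
last entry, bridging the overnight no-prompt gap; nothing is extrapolated.
Diurnal profiles are minute-of-day means over all participant-days, with a
band of (per-minute SD)/√(group size) and a mask marking minutes outside
the prompt window where the curve rests on interpolation only. Note that
the overnight bridge attenuates ultradian (4 c/d) content of interpolated
series substantially; analyses of ultradian mood structure should use the
scores at prompt times.

## Coherence

Magnitude-squared coherence C_xy = |G_xy|²/(G_xx·G_yy) from Welch
estimates: 24-h Hann segments, 50% overlap, per-segment mean removal
(optional linear detrend off by default — the signals are mean-dominated
diurnal). On the standard 4-day analysis window this gives 7 segments and
a 1 cycle/day frequency resolution, resolving both frequencies of
interest (1 and 4 c/d). These estimator settings are declared defaults,
not inferences; all are configurable. Coherence from a single segment is
identically 1 and therefore refused (≥ 2 segments required). Only
recordings of ≥ 4 days enter coherence, truncated to their first 4 days to
standardize the estimate; mood series enter raw (interpolated, not
integrated). The estimator is clipped to [0, 1] only against
floating-point overshoot; a vanishing autospectrum yields NaN (undefined),
never 0. Small-sample bias is real: for independent signals E[C] ≈ 1/K
with K segments — group *comparisons*, not absolute levels, are the
supported inference.

## Group statistics

- **Vs-zero:** one-sample Wilcoxon signed-rank on the wrapped per-subject
  phase differences (two-sided). A rank-sum-against-a-zero-vector variant
  exists (`vs_zero_method="mannwhitney_zero"`) for fidelity comparisons,
  since the two rank-test names are often conflated; signed-rank is the
  defined one-sample procedure.
- **Between groups:** two-sided Mann–Whitney rank-sum (independent,
  unequal-size groups), exact null for small tie-free samples and normal
  approximation with continuity correction otherwise, midranks for ties
  (scipy's policy).
- **Multiplicity:** Storey positive-FDR q-values with π₀ estimated at
  λ = 0.5 (configurable), capped at 1, step-up monotonized. Two families
  are corrected separately: the within-group vs-zero tests and the
  between-group comparisons.
- **Permutation testing:** at each frequency the observed two-sided
  rank-sum deviation is compared against its distribution under random
  reassignment of group labels to participants (group sizes preserved; one
  assignment shared across frequencies, since labels belong to
  participants). p = (1 + #{perm ≥ obs})/(n_perm + 1) — never zero. When
  fewer distinct assignments than n_perm exist they are enumerated
  exactly and flagged. The correction is pointwise per frequency by
  default; `permutation_mode="maxstat"` offers family-wise control via
  the cross-frequency maximum statistic.

Calibration figures the test suite and acceptance script actually compute:
the pointwise permutation test's empirical type-I error at α = 5% over 200
exchangeable-null replicates (two groups of 20) lands within 5% ± 2
points, and null permutation p-values are super-uniform (ECDF at 0.05
≤ 0.06 over 500 datasets).

## Synthetic cohorts: what they emulate, and what they don't

Channels are built as MESOR + diurnal cosine + optional 4 c/d ultradian
term + Gaussian noise, then artifacts and missingness are injected:

- **HR 5-min-average semantics:** the stochastic component of HR is
  boxcar-averaged over 5 samples before sampling, giving noise the
  correlation structure of 5-min means while leaving the deterministic
  sinusoid exact — so noiseless channels equal their analytic form to
  machine precision, which the residual-check tests rely on.
- **Artifacts:** multiplicative spikes, ×U(1.6, 2.5) or ×U(0.3, 0.6) with
  equal probability, so they trip the 150%/50% cleaning rule by
  construction; ~0.9%/sample by default, matching a realistic adjusted
  fraction.
- **Missingness:** contiguous runs with geometric lengths (mean 30 min)
  rather than i.i.d. holes, totalling the configured fraction — device
  dropout, exercising the interpolation and coverage paths realistically.
- **Injected lags:** when a group specifies an HR−activity lag, each
  participant's HR phase is set relative to the diurnal phase of the
  noiseless *total-acceleration norm* (computed analytically from the
  day-length Fourier bin), because the analysed activity signal is the
  norm of the three axes and its first-harmonic phase is not any single
  axis phase. Lags are drawn N(mean, sd) per participant and wrapped to
  [−12, 12); a common per-participant phase jitter shifts all channels
  together, adding between-subject variability without disturbing lags.
- **Mood:** six items are quantized (rounded, clipped to 0–6) projections
  of three latent components. Positive mood carries a 1 c/d term (default
  amplitude 1.5 Likert units peaking at 15:00); negative and irritable
  latents can be phase-locked to the HR ultradian waveform with a
  configurable gain — the mechanism that plants group differences in
  physiology–mood coherence at 4 c/d. Latent levels vary between subjects
  (defaults 0.8/0.4/0.5 Likert units), which is what makes negative mood
  the leading pooled PCA component, as in real cohorts. Prompts: 10 per
  day, evenly spaced 10:00–20:00 with ±15 min uniform jitter.

Not emulated: medication effects, age/BMI covariates, weekday/weekend
structure, posture, beat-to-beat HR variability, non-stationary rhythm
drift, and floor/ceiling response styles in mood ratings. Passing
parameter-recovery tests therefore shows the *pipeline* is correct and
calibrated under known structure — not that real cohorts satisfy these
generative assumptions.

## Numerical and degenerate-input choices

- Phase wrapping maps the float corner case (−ε mod 24) = 24.0 back to 0.
- Amplitudes below 1e−12 of the signal scale flag the phase undefined.
- Coherence overshoot beyond 1 by more than 1e−9 raises rather than clips
  (it would indicate inconsistent densities); below that it is clipped.
- Rank-sum permutation comparisons use a 1e−9 tolerance so midrank ties
  count as exceedances.
- Identical samples in the rank-sum test return the maximal attainable
  p (capped at 1); an all-zero sample in the signed-rank test returns
  p = 1 exactly.
- All randomness flows from numpy `default_rng` seeded per participant as
  (cohort seed, group index, participant index), so any participant is
  reproducible in isolation; file outputs are byte-identical across runs
  with one config + seed.

## Problem sizes used in tests

The suite fits its statistical checks to desk scale: 200-seed Monte-Carlo
calibrations for phase recovery and test power (n = 22 cohorts, 4 days),
200 replicates for permutation type-I error, 500 for FDR control and
p-value super-uniformity, 100 random vectors for the Storey oracle and
50 noisy days for the cosinor grid-search oracle. These sizes give
binomial/Monte-Carlo error comfortably inside each asserted band.

## Known limitations

- Calendar-day fitting means a participant whose rhythm crosses midnight
  contributes slightly biased daily phases near the wrap; circular
  averaging absorbs this but does not remove it.
- The coherence frequency grid is coarse (1 c/d at the default 24-h
  segment); finer grids trade segment count (bias) for resolution.
- Storey's π₀ estimate at a single λ is noisy for small families; for the
  9-test families here q-values should be read as ordering, not exact FDR.
- The permutation test assumes exchangeability of participants across
  groups under the null; systematic group differences in recording
  quality would violate it.
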