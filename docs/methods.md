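# Methods

## Signal model and processing chain

The device model is a wrist-worn tri-axial accelerometer sampling at 50 Hz
in units of g. A recorded axis is the sum of a quasi-static gravity
projection (≈ 1 g on whichever axis points down), broadband sensor noise,
and movement. The chain applied per axis is

1. Butterworth low-pass, 1 Hz, 2nd order — suppresses sensor noise;
2. full-wave rectification;
3. Butterworth high-pass, 5 Hz, 2nd order — removes the DC/gravity
   component surviving rectification;

and the axes are combined as the Euclidean norm. Two properties of this
chain matter downstream:

- **Degree-1 positive homogeneity.** Linear filters, |·| and the norm all
  commute with positive scaling, so scaling the raw signal by k scales the
  output magnitude by exactly k. Activity counts therefore scale linearly
  with movement amplitude, and the synthetic generator can calibrate bout
  amplitudes exactly (below).
- **Low transmission.** With the cutoffs as configured (low-pass 1 Hz
  *then* high-pass 5 Hz) the pass-bands barely overlap: only harmonics of
  the rectified signal above 5 Hz survive. A unit-amplitude 1 Hz sinusoid
  yields a mean output magnitude of roughly 0.009 g. The cutoffs are kept
  exactly as configured defaults rather than "corrected", because they are
  the definition of the measure being studied; both are `PipelineConfig`
  fields, so a user who believes the stages should be swapped can swap
  them. A consequence is that synthetic bout amplitudes calibrated to the
  default AC cut-points are numerically large; this is a unit question
  (next section), not a modelling error.

Filtering is zero-phase (`scipy.signal.filtfilt`, odd-extension padding),
doubling the effective order; there is no real-time constraint and phase
lag would skew bout boundaries. A single-pass causal mode
(`zero_phase=False`) exists and is the mode checked sample-exactly against
a pure-loop difference-equation oracle (the zero-phase path is checked
against a loop re-implementation of the forward-backward procedure).

## Active time, activity counts, intensity

A sample is active iff at least 50 % (`window_fraction`) of the samples in
the 10-s window centered on it are ≥ 0.015 g (`active_threshold_g`).
Comparisons are inclusive, so a signal sitting exactly at threshold is
active. The window steps one sample at a time; at stream edges the
truncated window actually available is used, which keeps detection
deterministic and covers every sample. Contiguous active samples merge
into half-open bouts (0-based sample indices).

A bout's AC is the trapezoidal integral of the magnitude over the bout, in
g·s, with the sample at the bout's right edge serving as the closing
integration boundary (so a constant c over T seconds integrates to exactly
c·T). The LIA/MIA/HIA cut-points 90.0 and 180.0 are configuration
constants in the pipeline's native AC unit; the boundary belongs to the
upper class (AC = 90 → MIA), mirroring the strict "below the 33rd
percentile" definition of the low class. How the native unit maps to g·s
at 50 Hz is not pinned down externally; the cut-points are adopted as
given and `derive_thresholds` (33rd/66th percentiles, linear
interpolation) recalibrates them for any new corpus.

Intensity proportions are bout-count fractions per class; a
duration-weighted variant is available (`time_weighted_proportions`)
because both readings of "proportion of activities" are defensible.

## Daily and weekly aggregation

Per day: active-time ratio = Σ bout durations / recorded wear time; mean
AC per active minute = Σ AC / active minutes (undefined-as-missing on
bout-free days); class proportions as above. "Recorded time" is the time
spanned by recorded samples; a day with under 1 hour of wear
(`MIN_WEAR_S`) is flagged invalid to exclude
charge-failure fragments — the 1 h floor is this package's choice, made
once. Visit days are deleted before aggregation. Weekly summaries are
arithmetic means over valid days; a week with fewer than 3 valid days is
flagged invalid (returned, never silently dropped). Missing daily PRO
values are excluded pairwise from their own weekly means. Week windows are
anchored on the injection date by calendar offset (preinjection week, days
8–14 and days 22–28 post).

## Validation statistics

- **Normality gate**: Shapiro-Wilk at α = 0.05 per variable; Pearson when
  both variables pass, Spearman otherwise; pairwise deletion of missing
  pairs; family-wise control by Bonferroni (α/m), with m defaulting to the
  number of pairs actually tested and overridable (m = 6 gives the
  familiar 0.008 per-test threshold).
- **ICC**: computed from the two-way ANOVA mean squares. Default is
  ICC(2,1) — two-way random effects, absolute agreement, single measure —
  the conservative choice when sessions/raters are exchangeable; ICC(3,1)
  (consistency) is selectable. Raw values are returned un-clipped.
  Cross-checked in the test suite against `pingouin.intraclass_corr`
  (ICC(A,1)/ICC(C,1)) to 1e-10 on fixed tables.
- **Split-half daily reliability**: session 1 = mean of days 1–3, session
  2 = mean of days 4–6; subjects with < 6 daily values are excluded and
  counted. Averaging m i.i.d. days shrinks within-subject variance by m,
  so the expected coefficient is sigma_b^2/(sigma_b^2 + sigma_e^2/3) — the parameter-recovery
  tests use this closed form.
- **Weighted kappa**: 1 − Σwᵢⱼoᵢⱼ/Σwᵢⱼeᵢⱼ with expected cells from
  marginal products; linear weights by default (ordinal vertebral levels
  are roughly equidistant), quadratic via config. Cross-checked against
  `sklearn.metrics.cohen_kappa_score`.
- **Change groups**: GRCS ≥ +4 improved, −4 < GRCS < +4 stable, GRCS ≤ −4
  worsened; worsened subjects are reported but excluded from both SRM
  groups (a two-group responsiveness design with a rare third outcome).
- **SRM**: |mean Δ| / SD(Δ) with the sample (n−1) SD — the magnitude is
  reported because improvement directions differ across instruments, and
  the signed mean change is retained alongside. Bands: < 0.2 minimal,
  0.2–0.49 small, 0.5–0.79 moderate, ≥ 0.8 large. The baseline timepoint
  for change scores defaults to the assessment immediately before
  injection (`baseline_timepoint="visit1"`).

## Synthetic data: what it emulates, what it does not

`generate_day` builds gravity + white noise (default SD 0.005 g, a typical
MEMS noise floor at this bandwidth) + non-overlapping sinusoid bouts
(default carrier 1 Hz, near the chain's transmission peak; randomized
phase) on the axis orthogonal to gravity. `bout_for_class` calibrates the
amplitude so the bout's AC equals a mid-class target (45/135/270 for
LIA/MIA/HIA): the AC of a unit-amplitude bout is measured once per
(duration, carrier, rate) and scaled exactly, by homogeneity. The planted
class is therefore analytic ground truth, while detection still has to
find the bout boundaries through noise and filter transients.

`generate_cohort` plants, per variable with total variance σ² and true ICC
ρ, a subject latent trait ~ N(μ, ρσ²) plus independent per-assessment
error ~ N(0, (1−ρ)σ²), so Var_between/(Var_between+Var_error) = ρ by
construction. Treatment effects at weeks 2/4 are expressed in SDs of the
change score (σ√(2(1−ρ))) so a planted effect e has expected SRM e in its
stratum. GRCS is a deterministic map of the planted change plus ±1 ordinal
noise, clipped into the stratum-consistent range, so the anchor always
agrees with the stratum. Default study conditions: 38 subjects, ~66 %
improved / 2.6 % worsened, missing days tallied additively at 7.4 %
(forgotten wear, i.i.d. days) + 31.2 % (device data loss, modelled as
whole-week outages since malfunction clusters) = 38.6 % expected loss;
accelerometry values go missing when a follow-up week keeps < 3 days.
Default instrument battery: WORC, QuickDASH, pain/activity VAS, SANE,
strength, range of motion and five accelerometry variables, with baseline
means/SDs typical of a painful-shoulder cohort, true ICCs in the ranges
their literatures report, and effect profiles encoding a delayed
accelerometry response (strong questionnaire change at week 2, activity
change emerging only by week 4).

Not emulated: real arm kinematics (bouts are narrowband sinusoids, not
gestures), posture changes or gravity reorientation, autocorrelated or
non-stationary noise, wear-time fragmentation within a day, floor/ceiling
effects of the questionnaires, or correlated missingness with disease
severity. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure — not that the
instrument battery would behave identically on real patients.

## Numerical and design choices

- Zero-phase filtering falls back to a shorter pad (or a plain double
  pass) on streams shorter than the default pad length.
- `detect_active` refuses streams shorter than one window, directing the
  caller to skip the day.
- Degenerate statistics raise `InputError` rather than returning NaN:
  constant input to the normality gate or correlation, zero total variance
  in ICC, single shared kappa category, zero change-SD with nonzero mean
  change in SRM (zero mean with zero SD returns SRM 0, "minimal").
- Percentile method: linear interpolation between order statistics.
- All stochastic code takes a `numpy.random.Generator` or integer seed;
  identical seeds reproduce streams and tables bit-for-bit.

## Problem sizes

The test-suite and acceptance-script simulations use: 60-s streams for
oracle equivalence; 100 seeded 400-s days for planted-bout recovery; 200
replicates of n = 200 two-session cohorts per true ICC for parameter
recovery; one n = 400 cohort for the delayed-response experiment; 100
seeded n = 38 cohorts for the null false-positive rate; and an n = 1000
cohort for the missingness rate. These sizes give sampling error
comfortably inside the stated recovery tolerances (±0.05 on mean ICC,
±10 s on active time) while keeping a full run to a few seconds.

## Known limitations

- The printed low-pass→rectify→high-pass ordering transmits little signal
  energy (see above); absolute AC values are only meaningful relative to
  the 90/180 cut-points adopted with it.
- The AT ratio denominator uses recorded-samples time; charging gaps
  inside a day are not distinguished from non-wear.
- ICC confidence intervals and F-tests are not implemented — point
  estimates only, as the validation design needs.
- Spearman p-values use the large-sample t approximation (exact
  permutation available only for Pearson at n ≤ 10).
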