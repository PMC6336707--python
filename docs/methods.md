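# Methods

This note documents the measures, the statistical model, the synthetic-data
generator, and the numerical and design choices behind `headsway`.

## Measures

### Movement vigour

Vigour is the mean head speed over a song, in mm/s. Speed is computed as the
Euclidean norm of the between-frame 3-D displacement of the head centre,
scaled by the sample rate (forward differences, yielding N−1 speed samples;
the final frame carries no speed value). The scalar speed series is smoothed
with a second-order Butterworth low-pass at a normalised cutoff of 0.2π
radians per sample — 9 Hz at 90 Hz sampling — applied forward–backward, and
negative post-filter values are clipped to zero. Vigour is the mean of the
smoothed series.

Two operationalisations coexist in the literature: mean smoothed speed, and
path length divided by song duration. For 6 Hz band-limited head motion the
two agree to within about 2% (asserted on simulated data in the test suite);
`kinematics.distance_over_duration` exposes the second form for comparison.
Speed is direction-agnostic (norm of the 3-D displacement vector, not
per-axis), so vigour is invariant under rotation and translation and scales
linearly with position scale. For a single-axis sinusoid of amplitude A and
frequency f, mean speed is 4·A·f exactly — the analytic anchor used
throughout the tests.

### Degree of entrainment

A song's beat period comes from its tempo (60/BPM seconds) or from rater tap
times (mean inter-tap interval, averaged across raters). The metrical
hierarchy places candidate periods at the quarter note (1× beat period),
half note (2×) and whole note (4×).

Head-centre position is analysed in 10 s windows hopped by 5 s; the number
of windows in a song of duration T is ⌊(T − 10)/5⌋ + 1, and a song shorter
than one window is skipped (no single-window fallback). Within each window,
each axis is mean-removed and its normalised autocorrelation computed at
integer-sample lags 0 … round(2 s × rate), endpoint included so that a
whole-note period sitting exactly at the 2 s lag limit (at 120 BPM) stays on
the grid. Periods beyond the lag range are undetectable by construction —
faithful to the stated 0–2 s analysis range.

The window's movement period is extracted as the lag of the first local
autocorrelation maximum whose height exceeds a threshold (default 0.25,
scale-free because the autocorrelation is normalised to unit lag-0 value);
among the three axes, the axis with the strongest such peak supplies the
period. Interior lags must exceed both neighbours; the final lag on the grid
qualifies on a one-sided test so the endpoint period remains detectable. If
no axis shows a qualifying peak the window has no detected periodicity.

A window is entrained when its period p satisfies |p − L|/L ≤ 0.05 for some
metrical level L; each window is counted at most once, and the matched level
is the one with the smallest relative error (the shorter level on ties).
The degree of entrainment is the entrained window count divided by the total
window count.

This period-extraction rule is a reconstruction: published analyses of this
kind delegate to motion-capture toolbox routines whose picking rule is not
printed. The rule here (first qualifying peak, height threshold, strongest
axis) is standard practice for autocorrelation-based period trackers, and
the threshold, tolerance, window, hop and lag range are all exposed as
parameters. Autocorrelation runs on *position*, not velocity — the measure
tracks periodic displacement of the head. Whether a window that matches
multiple levels should count once or per level is another unprinted detail;
counting once follows the definition of the proportion.

## Preprocessing

Pipeline order is fixed: trim → gap-fill → 6 Hz low-pass → head-centre
average → segment → per-song centring.

* **Trimming**: linear interpolation needs a present sample on each side of
  every gap, so the recording is cut to the span between the first and last
  frames at which all four markers have been observed. Interior gaps are then
  filled per marker and axis by straight lines; a gap touching an edge after
  trimming is an error.
* **Low-pass**: second-order Butterworth at 6 Hz, applied forward–backward
  (zero phase) so filtering adds no lag to period estimates. Whether the
  original jitter filter used in concert analyses was zero-phase is typically
  unstated; zero-phase is chosen here because phase lag would bias window
  periods.
* **Head centre**: per-frame arithmetic mean of the available markers. After
  per-marker gap filling, partial availability only arises at trimmed edges;
  averaging the available subset preserves frames rather than discarding
  them.
* **Normalisation**: interpreted as per-song, per-axis mean-centring of
  position — the minimal reading; vigour and entrainment are both invariant
  to location, so this choice has no quantitative effect. Centring is
  idempotent. Because centring is defined per song, segmentation necessarily
  precedes it; the outputs are identical to centring before segmentation for
  every downstream quantity.
* **Time convention**: frame k of a recording carries timestamp
  start_time + k/rate; song spans are half-open [start, end) so adjacent
  songs never share a frame, and frames between songs are discarded.

## Statistical layer

The design is a 2 × 2 × 7 split-plot: concert status (live, album) and
listener preference (fan, neutral) between subjects, song (1–7) within; the
eighth song, being familiar to fans, is analysed separately in a 2 × 2
between-subjects ANOVA.

The decomposition is computed from sum-coded design matrices with Type-III
(partial) sums of squares — the conventional choice for unbalanced factorial
designs (cells default to 15/9/17/8; the sums-of-squares type is a design
decision, since reports of such analyses rarely state it). Between-subjects
effects are tested on subject means against the subjects-within-groups
stratum (denominator df N − 4 = 45 at the default cell sizes); within
effects against the song × subject stratum (df (N − 4)(k − 1) = 270).
Because every included participant has all songs, subject contrasts are
orthogonal to song contrasts and the two strata separate exactly; the
implementation was verified to reproduce an independent reference
implementation of the same model (R's car package, type-III with a
repeated-measures design) to full printed precision on a frozen unbalanced
fixture, including the sphericity statistics below.

Sphericity is assessed with Mauchly's test on the pooled within-cell
covariance of the song vectors, projected through orthonormal contrasts; the
p-value uses the chi-square approximation with Box's second-order series
term, matching the standard references. When Mauchly's p < 0.05 (the trigger
threshold, configurable), Greenhouse–Geisser-corrected degrees of freedom
(both df multiplied by ε̂) determine the reported p. Note that ε̂ is biased
downward in finite samples: under true sphericity with 49 subjects and 7
songs its sampling mean is ≈ 0.87, so values near 0.9 do not by themselves
indicate a violation — the Mauchly trigger, which fires at ≈ α under
sphericity, governs the correction.

Effect size is partial η² = SS_effect/(SS_effect + SS_error), which
satisfies η² = F·df_num/(F·df_num + df_den) on every report row (asserted in
the tests). Cell summaries report mean ± SEM (SD/√n) with each participant
contributing their song-mean, so SEM reflects between-subject variability;
a single-subject level reports SEM as not available. Pairwise comparisons
use the Bonferroni adjustment p·m capped at 1. Experiment-wise correction is
*not* applied to the headline effects, matching the reporting convention the
package mirrors. Musician-versus-non-musician comparisons use pooled-variance
(not Welch) independent-samples t-tests, which give the conventional integer
df n₁ + n₂ − 2 (= 47 at the default 25/24 split), on four outcomes: each
measure's mean over songs 1–7 and its song-8 value.

Cohort filtering removes participants with any exclusion flag (abnormal
hearing, movement restriction, prior song exposure, no follow-up response)
and reports removal counts per reason; no imputation is performed, and a
participant missing any within-subject cell is a hard error.

## Synthetic data

The generator emulates the recording the analysis expects, not audience
biomechanics. Head-centre motion is the sum of:

* **entrained nodding** — a single-axis sinusoid along the
  anterior–posterior axis at a chosen metrical level of the song's beat,
  active on a contiguous leading fraction (`entrained_fraction`) of each
  song. A single axis keeps the ground-truth period unambiguous; the
  contiguous leading segment makes expected entrained-window counts
  analytically computable.
* **postural drift** — sinusoids on the two horizontal axes with period
  30 s by default, far above the 2 s lag range, so drift contributes speed
  but no detectable periodicity.
* **measurement noise** — white Gaussian per marker and axis (default SD
  0.5 mm, typical of optical capture).
* **occlusion gaps** — Poisson-arriving missing spans per marker (default
  2/min, lengths 0.1–0.5 s), independent across markers as real occlusions
  are, and never covering a recording's first or last sample.

The four markers ride rigidly on the head centre at fixed offsets, so
inter-marker distances are exactly constant at zero noise.

Cohort defaults mirror the study design the package targets: cells
live-fan/live-neutral/album-fan/album-neutral of 15/9/17/8 participants
(total 49), eight songs with rock-typical tempi (80–132 BPM) and durations
(212–264 s), 2 s gaps between songs, and a 25/24 musician split. Group
effects enter as multiplicative speed factors (scaling both nodding and
drift amplitude, so true vigour scales exactly linearly) and additive
entrained-fraction shifts per factor level; per-participant heterogeneity is
a lognormal speed multiplier (sigma `between_participant_sd`, default 0.3)
and an additive fraction jitter (`entrain_between_sd`, default 0.05, clipped
to [0, 1]). A single spread parameter cannot serve both roles — one is a
dimensionless multiplier, the other lives on a probability scale — hence the
two fields. Baseline amplitudes (2.5 mm nodding, 6 mm drift) and fraction
(0.05) put null-group vigour and entrainment in the single-digit mm/s and
sub-0.1 proportion range typical of seated audiences. Ground truth (speed
multiplier, entrained fraction, amplitudes, beat period) is emitted in a
sidecar table, never embedded in the marker files, keeping the export
dialect faithful.

What the generator does **not** emulate: rotational head kinematics,
skeletal or biomechanical constraints, tempo drift within songs,
movement coupling between neighbouring audience members, and the broadband
1/f-like structure of natural postural sway. Passing recovery and
calibration tests therefore demonstrates that the pipeline measures what it
claims on signals with known structure — not that real audiences satisfy the
generator's assumptions.

## Problem sizes and calibration experiments

Simulations in the test suite run at desk scale, chosen as the smallest
sizes at which every pipeline stage operates non-degenerately:

* parameter recovery: full cohorts (49 participants) with 20 s songs for
  vigour ratios and 60 s songs (11 windows/song) for entrained-fraction
  recovery at low noise (0.1 mm, no gaps, 5 mm nodding over 3 mm drift);
* type-I calibration at the measure level: 1000 replicates of normal-theory
  null tables through the mixed ANOVA, all seven effects;
* type-I calibration of the full pipeline (marker simulation →
  preprocessing → vigour → mixed ANOVA): 1500 null cohorts of 49
  participants × 7 exchangeable 10 s songs at 90 Hz, with the postural-drift
  period scaled down with the songs (5 s) so per-song summaries average over
  several drift cycles, as they do at realistic song lengths. Without that
  scaling, drift with a period comparable to the song length makes
  neighbouring songs' vigour correlated through their position in the
  session — the songs are no longer exchangeable. Even with it, desk-scale
  songs genuinely violate sphericity (Mauchly fires on essentially every
  cohort), which makes this a sharp test of the Greenhouse–Geisser machinery:
  uncorrected within-effect rates run near 0.085 and the corrected rates are
  the calibrated ones. Vigour is the calibrated measure; entrainment
  proportions at desk scale are coarsely discrete (a handful of windows per
  short song), so their ANOVA calibration is covered by the measure-level
  replicates instead.

The acceptance band for empirical type-I rates, [0.035, 0.065] at α = 0.05
with 1000 replicates, spans about ±2.2 binomial standard errors per effect.

## Numerical choices

* Butterworth designs via scipy (`butter`, order 2), zero-phase application
  via `filtfilt`; coefficient sets are cached per (cutoff, rate).
* Autocorrelation normalised by the window's lag-0 autocovariance; a
  constant axis yields zeros beyond lag 0 and can never produce a peak.
* Sums of squares below 1e-10 of the response's total square are clamped to
  zero so degenerate inputs (all values equal) give F = 0 rather than a
  ratio of round-off residuals; a zero error SS with a positive effect SS
  reports F = ∞, p = 0.
* Pooled t-statistics handle zero pooled variance explicitly (t = 0 when
  means agree, ±∞ otherwise).
* Marker TSV positions are written at micrometre precision (%.6f), lossless
  for optical-capture data; round-trip identity at that precision is
  property-tested.
* All randomness flows through `numpy.random.default_rng` seeded from the
  spec, so identical specifications are bit-reproducible.

## Known limitations

* The entrainment statistic inherits the 0–2 s lag ceiling: metrical levels
  slower than 2 s (whole notes below 120 BPM) are undetectable, as in the
  analysis the package mirrors.
* The period picker reports the first qualifying peak; strongly harmonic
  motion (e.g. double-time nodding with a large half-period component) is
  attributed to the faster level.
* The split-plot ANOVA is the classical univariate approach; no
  multilevel/mixed-effects or phase-based synchrony alternatives are
  provided, by scope.
* Entrainment proportions are bounded and discrete (multiples of 1/windows),
  so normal-theory inference on them is approximate at short song lengths;
  at the realistic default durations (~44 windows per song) the
  discretisation is mild.
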