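# Methods

## Scope and data model

`oculodex` analyzes binocular *horizontal* gaze recordings: strictly
increasing timestamps (seconds) with left/right eye positions in degrees,
positive rightward, nominally 200 Hz per eye.  Timestamps are used as-is —
all derivatives divide by the actual inter-sample interval — so tracker
timestamp jitter needs no resampling.  Vertical channels are accepted in
input files and ignored.

Non-finite samples (blinks, dropouts) and inter-sample gaps longer than 3×
the nominal sample period split a recording into gap-free pieces before any
analysis.  Rates use the sum of analyzed piece durations as denominator, so
a blink neither creates a spurious velocity spike nor inflates a per-second
index.

## Disconjugacy segment detection (DGI)

The detector works on the raw first differences of the two position
signals; no smoothing is applied, because the target events span only 2–4
intervals (10–20 ms) and any low-pass filter would erase them.  Design
choices on points the procedure leaves open:

* **Candidate runs.**  A candidate segment is any *maximal* run of
  consecutive intervals with a strictly negative velocity product.  Runs
  touching the recording (or gap-piece) boundary are kept; a zero product
  (one eye momentarily static) is not opposite-direction motion and
  terminates a run.
* **Direction splitting.**  Within a run, sub-segments are maximal sample
  blocks over which the disparity sign is constant.  An interior `D = 0`
  sample closes the current block and starts the next (the zero sample is
  shared, so block unions cover the run); a zero at a block start adopts
  the next nonzero sign; a direct sign flip splits between the two samples.
* **Direction label.**  A sub-segment is *converging* when |D| at its end
  is below |D| at its start, otherwise *diverging* (ties → diverging):
  convergence is read as reduction of the left-minus-right disparity
  magnitude.
* **Amplitude.**  `|D[end] − D[start]|` in degrees — the net change of the
  disparity across the sub-segment.
* **Dwell filter.**  Retained segments must span ≥ 3 position samples
  (≥ 2 negative intervals, 10 ms at 200 Hz); shorter blips are treated as
  tracker noise.  The threshold is a parameter (`min_samples`).
* **Rate.**  `DGI = count / total analyzed duration`, in segments per
  second; mean duration (ms) and mean amplitude (deg) are arithmetic means
  over retained segments, zero when there are none.

A brute-force enumeration (independent scan of every interval and sample,
in the test suite) reproduces the detector's segment list exactly on
randomized recordings; swap/mirror/gain/time-scaling symmetries are tested
as properties.

## Saccade descriptors

Saccades are detected on the conjugate signal `(Xl+Xr)/2` with a two-stage
velocity threshold: every smoothed-velocity peak ≥ 40 °/s seeds an event,
and its onset/offset are the first/last samples of the surrounding region
where speed stays above 10% of that peak.  Velocity is a central difference
smoothed by a 5-sample cubic Savitzky–Golay filter (25 ms at 200 Hz): wide
enough that noise does not fragment threshold crossings, and — unlike a
boxcar — it preserves saccadic peak height (on a clean synthetic 10°
saccade the measured peak is within 2% of truth).  The micro-segment
detector deliberately does not share this differentiator.

Eight descriptors per saccade (amplitude, duration, peak velocity, average
velocity = amplitude/duration exactly, disconjugate drift over 80 and
160 ms post-offset, total amplitude = amplitude + |drift₂|, fixation
duration to the next onset) are aggregated per recording as mean,
*population* standard deviation (ddof = 0, used consistently in
CV = sd/mean × 100) and trial count.  Aberrant values — windows running off
the recording, a missing successor saccade, |amplitude| > 40°, peak
velocity > 1000 °/s, duration outside 10–400 ms — are set to 0 before
aggregation rather than imputed: outliers are treated as informative
(blinks/artifacts), not as missing at random.  Leftward and rightward
saccades are pooled; amplitude is reported as a magnitude, drifts keep
their sign.

## Synthetic cohort generator

No public recordings accompany the underlying study design, so the
simulator is a first-class, tested component that emulates its conditions:
46 subjects per group × 7 paintings × 30 s at 200 Hz.

**Conjugate scanpath.**  Fixations with Ornstein–Uhlenbeck drift velocity
(sd 0.3 °/s, τ = 0.3 s) alternate with main-sequence saccades
(`Vp = 500·(1 − e^{−A/12})` °/s, raised-cosine velocity profile, log-normal
amplitudes, median 4°, truncated 0.5–20°, ~2.2 saccades/s, gaze confined to
±12°).

**Measurement noise.**  Per-eye tracker noise is modelled as a temporally
smooth wander: white noise filtered by a Gaussian kernel (sd 15 samples =
75 ms) scaled to a marginal sd of 0.002°.  The smoothness is essential, not
cosmetic: real pupil trackers low-pass their output, and a *white* 0.002°
process would carry per-interval velocity noise two orders of magnitude
above the sub-0.005° event velocities, burying every micro-event.  With the
smooth model, noise contributes a small baseline of spurious segments
(~0.9/s) and costs a few percent of event recall.

**Micro-events.**  Disconjugate events ramp the two eyes apart (or
together) linearly over 3–5 samples by a truncated log-normal amplitude
(median ~0.003°, bounds 0.0015–0.02°, so the bulk of segment amplitudes
falls below 0.005° as in the study's histograms), half converging and half
diverging around a per-recording vergence offset of 0.3–0.7° (kept away
from zero so events never flip the disparity sign).  Events are placed
sequentially with dead-time-compensated exponential gaps (≥ 2 quiet
intervals), only inside fixations; the conjugate drift is frozen within
each event window, since opposite-direction motion is unobservable beneath
a shared drift faster than the event itself — consistent with such episodes
being observed mostly during quiet fixation.  Every injected event is
logged in a ground-truth table.

**Population profiles and calibration.**  The packaged control and dyslexic
profiles differ in event rate (13.35 vs 28.5 injected events/s), amplitude
median (0.0030 vs 0.0028°) and duration mix (dyslexic slightly longer).
The injected rates are calibrated so the *measured* pipeline DGI — after
placement losses, noise baseline and detection efficiency — reproduces the
published cohort means of 13.9 (control) and 27.38 (dyslexic) segments/s.
Per-subject event rates are drawn once per subject (reused across
paintings, with a 0.3/s per-recording wobble) from a truncated normal
(sd 5.5/s, clipped at ±2.2 sd) sampled by quantile stratification across
the cohort: stratification pins the simulated cohort mean to the population
mean, reflecting that the study reports cohort-level means as stable
quantities, while preserving between-subject spread.  That spread, together
with per-subject wobble of the amplitude median (log-sd 0.15) and duration
mix (tilt sd 0.35), is calibrated so DGI-based classification lands in the
high-80s-to-low-90s accuracy range rather than being trivially separable,
and so no single segment statistic is a noise-free group marker.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: image-content-driven gaze (saliency), vertical
and torsional eye movements, blink dynamics beyond dropout gaps, pupil-size
artifacts, slow drifts of tracker calibration, and any physiological
coupling between saccade kinematics and disconjugacy.  Group differences
in the *saccade* descriptors are incidental here (both groups share a
scanpath profile), so classification from the 32 saccade features alone is
weak on synthetic cohorts by design; the synthetic benchmark exercises the
DGI pathway.

## Classification pipeline

Three grouping analyses (per-painting: 7 × 92 rows; Op-Art group 1–3 vs
paintings 4–7: 276/368 rows; combined: 644 rows) are evaluated with
stratified 5-fold cross-validation (shuffled, seeded, default seed 42).
Within each fold, features are z-scored using training-fold statistics only
(the scaler lives inside the sklearn Pipeline); zero-variance features get
a unit divisor.  Models are pinned numerically rather than left to library
defaults: RBF-SVM with C = 1 and `gamma = 1/(n_features × mean train
variance)`; logistic regression with ridge C = 1, tol = 1e-4, ≤ 1000
iterations.  No hyperparameter tuning.  Metrics are percent accuracy,
sensitivity (recall on the dyslexic, positive class — screening
convention) and specificity, averaged over folds.

Subjects contribute one row per painting; pooled analyses split folds by
row, not subject, mirroring the stated dataset sizes (92 → 644).  This
leaks subject identity across folds and inflates absolute accuracy; a
`group_by_subject` option is provided for sensitivity analysis rather than
silently changing the design.

Group comparisons use the two-sided Mann–Whitney U with tie-corrected
normal approximation (no continuity correction); z is signed by the first
group's rank tendency.  Feature importance is permutation importance (mean
accuracy drop over 10 shuffles, seeded) on the fitted pipeline.

## Numerical conventions and degenerate inputs

* Durations are seconds internally, milliseconds at interfaces; positions
  and amplitudes are degrees.
* Recordings need ≥ 2 samples (≥ 3 for the conjugate series); empty segment
  lists yield zero means; a recording with no usable samples after gap
  handling raises rather than returning silent zeros.
* Cross-validation requires ≥ 10 rows and both classes with ≥ 5 members;
  metrics for an absent class are NaN-flagged, not zero.
* All randomness flows through seeded `numpy` generators; cohort seeds are
  derived per (cohort seed, group, subject, painting) via `SeedSequence`,
  so recordings are reproducible individually and in aggregate.

## Problem sizes used by the shipped checks

The test suite and acceptance script run the full 46 × 2 × 7 cohort
(644 × 30 s recordings) for calibration and classification checks, 500
randomized short recordings (≤ 200 samples) for oracle equivalence, and a
6-point injection-rate grid (0–40 events/s, two recordings each) for rate
recovery; together they complete in a few minutes on one CPU.

## Known limitations

* The DGI's unit (segments/s) and several of its conventions (segment
  amplitude, direction labelling, boundary handling) are fixed here by
  explicit design decisions; other reasonable conventions would shift
  absolute values, though not the group contrast.
* The dwell filter's "3 samples" is rate-dependent wall-clock time; at
  rates other than 200 Hz the `min_samples` parameter should be
  reconsidered.
* Detection efficiency depends on the noise floor: event amplitudes below
  ~2× the per-interval noise increment are missed at increasing rates.
* The synthetic benchmark demonstrates pipeline correctness and
  calibration, not clinical validity on human data.
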