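# Methods

This note documents the models, estimators and design choices behind
`fretscreen`, and what the simulator does and does not emulate.

## Transient model

A stimulus-evoked calcium transient is modelled on the acceptor/donor FRET
ratio as a piecewise saturating exponential:

- R(t) = R₀ for t < t_on,
- R(t) = R₀·(1 + A·(1 − e^−(t−t_on)/τ_rise)) during the stimulus,
- exponential relaxation toward R₀ with τ_decay after t_off,

continuous at both break points and bounded by R₀·(1+A).  This is the
minimal shape with a well-defined peak and rise rate; the two time
constants are directly interpretable.  Defaults: R₀ = 1.5, A = 0.3,
τ_rise = 5 s, τ_decay = 8 s, with the stimulus window set by the protocol
(onset at the end of the 40 s pre-stimulation phase, 30 s pulse).  The
closed-form peak of the percent-change trace, 100·A·(1 − e^−(t_off−t_on)/τ_rise),
serves as the oracle for the quantification stage.

## Protocol timing

One worm cycle is 100 s: 5 s loading, 40 s pre-stimulation exposure (the
pre-stimulus baseline needs time to settle because the neuron also responds
to the imaging light), 50 s stimulation/recording with the 30 s pulse, 5 s
unloading.  Frames are taken at 2 Hz (0.5 s interval), 180 frames per
recording.  The run log advances on this logical clock, which keeps reruns
deterministic.

## Virtual instrument

**Scene.** The trapped worm is a horizontal autofluorescent band across a
160×100 px frame (0.4 µm/px); the labelled neuron is a 2-D Gaussian spot
(σ = 2 px at focus) in the head-side half (mirrored for tail-first loads),
at a true depth drawn from 30–70 µm inside the instrument's 0–100 µm range.
Defocus grows the spot width linearly (0.25 px/µm) while conserving its
integrated intensity, which makes correlation against a focused-spot
template a unimodal focus metric.

**Channels.** The total expected fluorescence at each pixel is partitioned
donor = total/(1+R), acceptor = total·R/(1+R), so acceptor/donor equals the
model ratio exactly before noise and the channels are anti-correlated, as
in a real FRET sensor.  The worm-body signal shares the partition (treated
as out-of-focus sensor fluorescence), so the ROI ratio identity holds
exactly even over the body; the camera offset (100 counts) is unpartitioned
and removed by background subtraction.  Per-channel photobleaching
multiplies the fluorescent signal by e^−λ_c·t (defaults λ_donor = 0.004/s,
λ_acceptor = 0.0015/s — the donor bleaches faster, so uncorrected ratios
drift upward).

**Noise.** Poisson shot noise on expected counts plus Gaussian read noise
(sd 3 counts) at the image level.  At the trace level the default is 2%
relative Gaussian noise per channel per frame, i.e. ~2.8% noise on the
ratio; at the default amplitude (peak ≈ 30%) that is a trace SNR of ≈ 10,
which is how "default noise" is defined throughout.

**Cohorts.** Between-worm response amplitudes are drawn from a normal
distribution with CV 0.3 (clipped at 0).  Real per-worm variance is not
published for this preparation; the value is a package default, stated
here, not a literature fact.  QC classes are sampled per worm at rates
tail-entry 0.12, too-dim 0.08, too-bright 0.05, dead 0.05 — totalling the
~30% discard rate observed on the physical platform.  Because peak and
slope are linear in amplitude, plate-scale statistical experiments can draw
cohorts at the metric level (amplitude × unit-amplitude metrics) — a path
that is distribution-identical to quantifying each worm's noise-free trace
and is cross-checked against it in the tests.

**What the simulator does not emulate:** optics-accurate PSFs, worm-body
texture and movement, pharyngeal pumping (so death is recorded in the
per-worm metadata as an instrument observation and honored by the pipeline,
mirroring on-chip discard before recording), spectral bleed-through,
hardware timing jitter.  Passing tests therefore validate the estimators
and the orchestration, not robustness to those real-data features.

## Detection

ZNCC is computed exactly (vectorized sliding windows with explicit mean
subtraction — numerically identical to the brute-force double loop, which
the tests assert to 1e−12).  Constant windows score 0 by convention;
constant templates are rejected.  Ties in score break toward the smallest
(y, x) and the lowest z, making reruns deterministic.  The correlation
threshold (0.5 on the [−1, 1] scale) is config: it must be adapted to the
age and brightness of the cohort.  Autofocus scores every plane of the z
sweep in the search region and takes the argmax; if all scores fall below
threshold the worm is rejected as neuron-not-found.  Orientation tries the
head-side region first, then the tail-side.  An edge-detection chain
(Sobel → Otsu → connected components scored by mean intensity × area) is
provided for young worms whose neurons are too small for stable templates;
the age→mode mapping (edge through Day 4, template from Day 5) is config.
Brightness QC is a two-sided gate on the background-subtracted ROI mean at
the chosen focal plane.

## Quantification

Tracking re-matches a patch (cut from the first frame at the detected
position) within a 5 px radius of the previous position; frames scoring
below 0.2 are flagged and hold the last good position.  ROI means (disc,
radius 3 px) minus the background-region median give the raw channels.

Bleach correction fits I(t) = I₀e^−λt per channel by log-linear least
squares (λ clipped at ≥ 0) and divides it out; a failed exponential fit
falls back to a linear envelope, and if both fail the trace is flagged and
left uncorrected.  The fit window defaults to the whole pre-stimulus phase
(0–40 s): the simulator has no light-settling transient, and the longer
lever arm stabilizes extrapolation over the 90 s recording.  The
percent-change baseline stays on the final 10 s before onset.  Both windows
are config.

Metrics are extracted from the percent-change series after an 11-sample
(5.5 s) boxcar.  The peak is the smoothed maximum on
[t_on, t_off + 5 s grace]; onset is the last sample before the peak at or
below 10% of it.  The slope is a least-squares line between the first
crossings of 10% and 90% of the peak — with the crossing thresholds
referenced to a short (2.5 s) local mean ending at the peak rather than the
single maximum sample, because the max of a noisy series is biased upward
and thresholds anchored to it land in the plateau and flatten the fit.
Smoothing width, grace, threshold fractions and the 2% responder threshold
are config.  Numerical edge cases: flat traces (peak ≤ 1e−9) return
P = S = 0 with responder false; non-positive background-subtracted frames
are excluded from the ratio and flagged.

The recovery estimand for the slope is the same estimator applied to the
noise-free ideal trace (the peak has a closed form; the 10–90% slope of a
saturating exponential does not reduce to one once the crossing definition
is fixed).

## Screening statistics

The scheduler visits every compound well once and inserts the next vehicle
control after each block of 9 compound wells (including a trailing partial
block), cycling through the control wells; medium-only edge wells are never
scheduled.  Wash events fire after each configured number of processed
worms.  Each compound well is compared to the control that closes its block
(the first block has no preceding control, so block-closing is the
deterministic age-matched choice).

The per-compound statistic is the percent difference of group mean peaks
with a two-sided Welch (unequal-variance) test on per-worm peaks;
classification is positive/negative by sign when p < α (default 0.05), else
none.  The slope is tested secondarily; a compound significantly increasing
both peak and slope carries a `dual_action` flag.  No multiple-testing
correction is applied by default (matching the screen-design convention of
reporting raw per-compound p-values); Benjamini–Hochberg is available via
`multiple_testing="bh"` and is recommended whenever many compounds share
one control cohort.  The Welch p-value is computed from group summaries
(identical to `scipy.stats.ttest_ind(equal_var=False)`, asserted in tests)
to keep thousand-plate calibration experiments fast.

Time-course analyses: one-way ANOVA across days plus designated pairwise
Welch contrasts for aging trajectories (days binned early ≤ Day 6 — Day 6
is not covered by the conventional early/mid phrasing and is grouped early
here — mid Day 7–8, late ≥ Day 9); two-way (day × treatment) ANOVA with
per-day Bonferroni-corrected comparisons for treated-vs-control
trajectories; one-way ANOVA with pairwise tests against the vehicle group
for dose-response tables.  Days with fewer than two analyzed worms per
group are excluded and logged.

## Calibration facts worth knowing

- Welch's test at n = 15/group with equal variances has true size ≈ 0.049,
  slightly conservative; the null-plate flag rate lands just below α.
- The percent-effect estimator is exactly the generating multiplier on
  CV = 0 cohorts and has a small positive small-sample bias
  (≈ CV²/n from the random control mean in the denominator) that shrinks
  with n — measured in the acceptance script at n ∈ {5, 15, 50}.
- With many null compounds per plate, *some* false flags per plate are
  expected at raw α (≈ 3.7 for 74 nulls at 0.05); per-plate exact partition
  matching is therefore only meaningful on small plates at stringent α.
  The 12-well integration plate uses α = 0.01 for exactly this reason: at
  0.05 a correct implementation would still flag a null well on ~1 plate in
  4.

## Problem sizes

Test-suite and acceptance-script experiments use: 100 random instances for
the ZNCC oracle; 200 simulated z-stacks/worms at default noise (50
noise-off) for focus and orientation rates; 100 transients across
A ∈ [0.05, 0.6] for metric recovery; 1000 plates × 100 compounds for
type-I calibration and 300 replicates of a 107-compound plate (2 positives,
24 negatives) for recovery; one 12-well image-level plate (10 worms/well)
for the end-to-end run.  These sizes were chosen so each experiment's
sampling error is small relative to the property it checks.

## Known limitations

- The edge-detection path is validated on synthetic spots only; its
  component-scoring parameters would need re-tuning for real young-worm
  morphology.
- Bleach correction assumes mono-exponential decay per channel; two-phase
  bleaching or light-history effects are out of scope.
- The simulator's dead-worm signature is "no response + metadata flag";
  behavioural death calls (movement, pumping) are not modelled.
- No spectral bleed-through/cross-talk correction is implemented, matching
  the instrument's own processing chain.
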