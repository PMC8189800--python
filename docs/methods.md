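# Methods

This note documents the models, numerical choices and known limitations
of `fixoffset`, stage by stage.

## Geometry

A gaze or target position `(x, y)` in degrees of visual angle maps to
the unit direction vector `(tan x, tan y, 1)/‖·‖` (tangent-plane
convention). The angular offset between two positions is the arc between
their direction vectors, `arccos` of the clamped dot product, reported
in degrees. On any meridian through the primary position the angular
distance equals the coordinate difference exactly; off-meridian, the
plane Euclidean distance `√(Δx²+Δy²)` overestimates the angular distance
by at most ~0.5% out to 10° separations near the primary position, so it
is exposed as a checked fast alternative but the angular form is the
default everywhere. Dot products are clamped into [−1, 1] before
`arccos`; this matters because rounding can push the dot product of
nearly identical unit vectors above 1. The residual `arccos` noise for
identical positions is ~1e-6 degrees, which is why "exact zero" checks
in the tests use that scale.

## Synthetic recordings

The generator emulates a 1000 Hz monocular random-saccade task: 100
targets uniform over ±15° (H) × ±9° (V), consecutive displacements ≥ 2°
(candidates drawn uniformly over the box and rejected while too close,
which keeps marginal coverage uniform to well below what a χ² test at
n = 10,000 can detect), 1 s dwell per target. Per target jump the eye
follows after a truncated-normal latency (mean 237 ms, SD 17 ms, range
192–316 ms — the operating values of the latency-removal stage) with a
minimum-jerk saccade whose duration follows the main-sequence rule
`21 ms + 2.2 ms/°`; its peak radial velocity (1.875·A/D) exceeds 55 °/s
for any amplitude the task can produce, which is all the detectors need.
Zeroing both kinematic parameters produces single-sample saccades, for
which the latency estimator recovers the planted shift exactly; with
realistic kinematics the estimator's optimum is the planted latency plus
roughly half the saccade duration (the shift that best centres the
saccade on the target jump), which is the same bias any real recording
imposes.

Fixation samples sit at the target plus a planted offset: per fixation,
one level is drawn per mixture component (truncated normal, ≥ 0, since
offsets are distances), and the fixation dwells on each level for a
duration proportional to the component weight, interleaved over two
cycles so that any 500-sample sub-window sees every component. Level
changes are instantaneous: kinematically they read as tiny saccade-like
shifts, the cleaning stages remove the single transition sample plus a
small neighbourhood, and the fixation becomes a multi-segment fixation
with a genuinely multimodal offset histogram — the phenomenon the
analysis stack is built to detect. White measurement noise (default
0.05° per channel, an ordinary video-oculography noise floor) and an
optional sinusoidal drift of the offset magnitude complete the fixation
model. Blinks are Poisson-placed NaN blocks of 50–300 ms flanked by
20 ms, 3–10° vertical transients, matching the assumptions of the
blink-saccade removal algorithm. Anticipatory saccades are inserted with
probability `slope × trial index` (a linearly increasing hazard): a
2.5–4° single-axis excursion 100–300 ms before the target jump whose
displaced plateau persists until the next real saccade.

Each recording's pseudo-random stream derives from (scenario seed,
subject id, session), so cohorts are reproducible trial by trial, and a
per-sample ground-truth structure (event codes, currently-fixated target
index, planted levels, latencies, spans) is returned with the recording
and serialisable as a JSON sidecar.

What the generator does **not** emulate: the 1/f within-fixation noise
spectrum of real trackers (noise is white plus an optional drift
sinusoid), pupil dynamics, post-saccadic oscillation waveforms,
microsaccade kinematics, or tracker-specific artefacts. Passing tests
therefore demonstrate that the pipeline's stages do what they claim on
signals satisfying their stated assumptions — not that real recordings
satisfy those assumptions.

## Cleaning

The five stages run in a fixed order (latency, blink saccades, velocity
saccades, quadratic residuals, anticipatory plateaus); each only ever
converts samples to NaN, so every stage is idempotent and retained
values are bit-identical to the raw input. Velocity is the centered
Savitzky–Golay first derivative (order 2, 7 ms window — standard for
1000 Hz saccade work; both configurable), computed by explicit
convolution so NaNs propagate into the surrounding half-window instead
of raising, with the edge half-windows NaN. FixVelT is the
linear-interpolation empirical 90th percentile. In the velocity-based
saccade expansion, a NaN neighbour or the recording boundary counts as a
terminating minimum. The step-2 regressor is the squared within-window
index 1²..27² (with intercept); the threshold applies to |β|×1000
because parabolas open both ways, and the full flagged window is
removed, unioned across overlaps and channels. The anticipatory rule
uses absolute channel offsets. Windows and sample indices are reported
1-based inclusive to match the task's sample numbering; storage is
0-based internally.

On synthetic recordings at generator defaults, ≥ 95% of ground-truth
saccade samples end up NaN and ≤ 2% of pure-fixation samples are lost
(measured in the calibration tests); most of the small fixation loss
sits at saccade borders outside the analysis window.

## Multimodality

The mixture model is the Richardson–Green univariate Gaussian mixture
with unknown k: k uniform on {1..kmax} (kmax = 5), weights ~
Dirichlet(1), means ~ N(midrange, R²) kept in ascending order, component
precisions ~ Gamma(α = 2, β) with the data-scaled hyperprior
β ~ Gamma(g = 0.2, h = 10/R²), R the data range. Each sweep performs
conjugate updates of weights, means (order-constrained), variances, β
and allocations, then one split/combine and one birth/death attempt with
the standard acceptance ratios. 2000 sweeps are retained after a 500
sweep burn-in. Correctness of the trans-dimensional moves is checked by
the prior-recovery identity: with the likelihood disabled the chain
reproduces the uniform prior over k (so posterior odds equal prior odds
and BF = 1).

The Bayes factor is `b/a` with `b` the posterior and `a` the prior odds
of k > 1 (`a` available analytically and by simulation; both agree
within Monte-Carlo error). Sentinels: a chain that never leaves k = 1
reports log(BF) = log 0.003, one that never visits k = 1 reports +∞,
replaced at report time by the batch maximum. Components are treated as
modes for classification (k > 1 ⇒ multimodal), matching how the
segment-stratified report tables count them; a mode-counting sensitivity
variant can be derived from the retained draws, which are exposed on the
posterior object. The point fit averages draws conditional on the modal
k with components sorted by mean; label switching is immaterial for k
counts and handled by the ordering for the point fit.

The ACR-style frequentist check uses the Müller–Sawitzki excess-mass
difference `max_λ (E_n(2,λ) − E_n(1,λ))`, computed exactly for a given λ
by an O(n) dynamic program (verified against brute-force interval
enumeration) and maximised over a 64-point geometric λ grid spanning the
sample's empirical density heights. The null is calibrated by a smoothed
bootstrap from the Gaussian KDE at the critical bandwidth (the smallest
bandwidth with a unimodal KDE, found by bisection), variance-rescaled to
preserve the sample variance; the p-value uses the (1 + #{≥ obs})/(B+1)
convention. Default B = 500 bootstrap replicates. Because the same
statistic and grid score data and bootstrap samples alike, the grid
approximation does not bias the test's level; measured type-I error at
α = 0.05 is below nominal and power on 6-SD-separated bimodal data
exceeds 90% (calibration tests). In the full pipeline the ACR column is
off by default (`run_acr`) because the per-fixation bootstrap dominates
runtime; the Bayes factor is the primary classification.

## Normality screen

10,000 standard-normal samples of n = 500 (the plurality fixation
length; fixations with other valid counts are screened against the same
bands); moment-based sample skewness `g1` and non-excess kurtosis
`m4/m2²` (the small-sample bias correction is negligible at n = 500);
acceptance bands are the 5th/95th empirical percentiles. The percentile
convention is deliberate: the published limits (±0.18 for skewness)
equal ≈ 1.645 asymptotic standard errors (√(6/500) = 0.1095), which are
the 5th/95th percentiles, not the 2.5th/97.5th (± 0.21); the convention
is configurable. Bands are deterministic given (n, reps, seed) and
persisted with that provenance.

## Accuracy metrics and drift

ClassicAccuracy is the NaN-ignoring mean offset of every included
fixation. MaxCompMean is the mean of the maximum-weight component (ties
broken toward the smaller mean). MedianAccuracy is reported only when
the evidence class is unimodal, MeanAccuracy only when the fixation is
unimodal *and* passes the normality screen; absent metrics are NaN, and
the gating is part of the record's invariants.

Drift is defined for fixations that are a single contiguous segment of
exactly 500 valid samples. The DC component is the sample mean, retained
exactly; the demeaned series is zero-padded to 512 samples and Fourier
transformed, bins 1 and 2 (1.953 and 3.906 Hz at 1000 Hz) are retained,
and the inverse transform is fitted to the offsets by OLS jointly with a
linear term and intercept: `offset ≈ a·reconstruction + b·t + c`, with
r² of that three-parameter fit as the drift measure. Treating DC as the
exact mean (rather than bin 0 of the padded transform) makes r²
invariant under constant shifts and keeps a pure in-band sinusoid above
r² = 0.99; padding the raw signal would leak the rectangular DC pulse
into the retained bins and break both properties. The 512-point length
is what makes the two retained bins sit at the stated frequencies; a
500-point variant (2 and 4 Hz bins) is available through the
configuration. Drift is sign-agnostic: drifts toward and away from the
target score alike. The joint OLS (reconstruction and linear term fitted
together) is one of two defensible readings of "fit with a linear
component"; the sequential alternative changes r² only marginally and
was not adopted. Ineligible fixations are skipped and logged, not
errors.

The drift–multimodality relation is an OLS of log(BF) on drift r²
(sentinel-replaced values only), reporting slope, variance explained and
p-value.

## Pipeline, sizes and determinism

All thresholds live in `PipelineConfig` with documented units; a master
seed fans out deterministically (SeedSequence) to the mixture sampler
and bootstrap of every fixation, so identical configs produce identical
output files. The analysis window defaults to the fixed samples 192–691
and can be recomputed from the cohort's mean offset curve (fixations
with any NaN or any sample > 60° are excluded from that curve; ties in
window mean resolve to the earliest start, on sums rounded to 12
decimals to absorb float accumulation noise).

Test and calibration problem sizes were chosen to exercise each property
at meaningful power while keeping the default suite fast: 50 seeded
mixture fits per calibration arm at n = 500, 200 excess-mass test runs
with 200 bootstrap replicates, 100 latency-recovery seeds on 3-trial
recordings, 10⁵ sliding windows for the false-alarm rate, and a
25-fixation end-to-end cohort. These are the package's own validation
sizes; the statistics they estimate (rates against 90%/10% margins) are
insensitive to making them larger.

## Known limitations

- The rjMCMC hyperpriors are the Richardson–Green data-dependent
  defaults; other choices shift posterior k mass for weakly separated
  components (the Bayes-factor classification is robust for the
  separations the calibration targets, but borderline fixations are
  prior-sensitive).
- The excess-mass λ grid is an approximation to the continuum maximum;
  it is shared between data and null calibration, preserving test level,
  but the statistic itself is a lower bound on the exact Δn.
- Convergence diagnostics beyond the retained k-trace are out of scope;
  2000 sweeps with both trans-dimensional move families mix well for
  n ≈ 500 univariate samples but are not verified for much larger n.
- The generator's saccade and blink waveforms are idealisations; the
  cleaning calibration numbers (≥ 95% / ≤ 2%) are statements about those
  waveforms, not about any particular tracker.
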