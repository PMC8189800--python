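# fixoffset

Accuracy analysis of eye-tracker fixations from angular-offset
distributions.

Eye-tracker *accuracy* is conventionally reported as the mean angular
offset — the angular distance, in degrees of visual angle, between
measured gaze direction and target direction — over the samples of a
fixation. That convention quietly assumes the offsets of a fixation are
unimodally (ideally normally) distributed around a single value. In
practice they often are not: small saccade-like shifts, post-saccadic
events and slow drift within a single one-second fixation produce offset
histograms with two or more modes, for which a single mean is a poor
summary. `fixoffset` implements a complete, testable pipeline for
quantifying this on random-saccade-task recordings, together with a
seeded synthetic-recording generator so that every stage can be
validated against known ground truth without any external dataset.

## What the pipeline does

Given per-sample gaze/target traces (1000 Hz, degrees of visual angle,
NaN for missing data), one recording per (subject, session):

1. **Latency removal** — a single temporal shift per recording, the one
   among 1..800 samples minimising the mean angular offset between gaze
   and target; the truncated final fixation is dropped.
2. **Blink-saccade removal** — blinks are NaN blocks; the fast
   transients flanking them are removed by marching away from each block
   until three contiguous samples fall below the per-recording *fixation
   velocity threshold* (FixVelT: the 90th percentile of radial
   Savitzky–Golay velocity over putative fixation samples).
3. **Saccade removal, step 1** — radial-velocity excursions above
   55 °/s, expanded to the flanking sub-30 °/s local minima.
4. **Saccade removal, step 2** — a sliding 27-sample regression of
   position on the squared window index; windows with r² > 0.6 and
   |β|×1000 > 0.55 (parabola-like residual events) are removed.
5. **Anticipatory-saccade removal** — post-AS plateaus, i.e. runs of
   ≥ 100 ms with a channel offset above 2°, overlapping the analysis
   window.

Each trial's offsets inside a 500-sample analysis window (default
samples 192–691, or recomputed as the lowest-mean-offset window of the
cohort) form a fixation; fixations with < 400 valid samples or > 4 NaN
blocks are excluded, as are subjects with any session under 20 good
fixations.

Per included fixation the pipeline then computes:

- a Bayesian Gaussian-mixture fit with unknown number of components
  k ∈ {1..5} by reversible-jump MCMC (Richardson–Green moves: conjugate
  within-model updates plus split/combine and birth/death), summarised
  as a Bayes factor BF = b/a, the posterior odds of k > 1 over the prior
  odds. log(BF) ≤ 1 counts as unimodal; 1–3 positive, 3–5 strong, > 5
  very strong evidence of multimodality;
- the frequentist ACR-style excess-mass test (Müller–Sawitzki statistic,
  critical-bandwidth smoothed-bootstrap calibration), optionally;
- a Monte-Carlo normality screen: sample skewness and kurtosis compared
  to 5th/95th-percentile bands from 10,000 normal resamples at n = 500;
- four accuracy metrics: **ClassicAccuracy** (mean offset),
  **MaxCompMean** (mean of the maximum-weight mixture component),
  **MedianAccuracy** (median; unimodal fixations only), and
  **MeanAccuracy** (mean; unimodal *and* normal fixations only);
- a drift statistic: for single-segment 500-sample fixations, the r² of
  fitting the offsets with their own low-frequency reconstruction
  (DC mean + 1.95 Hz + 3.91 Hz bins of a 512-point FFT) plus a linear
  term.

Reports include a per-fixation CSV and a cohort summary of evidence-class
percentages stratified by number of fixation segments (1–5 plus total),
with report-time replacement of infinite log(BF) values (+∞ → batch
maximum, −∞ → log 0.003).

## Worked example

```python
import numpy as np
from fixoffset import (SyntheticScenario, MixtureSpec, generate_target_sequence,
                       generate_recording, clean_recording, fit_rjmcmc)

# a recording whose fixations alternate between two offset levels
spec = MixtureSpec(means=(0.6, 1.6), sds=(0.02, 0.02), weights=(0.65, 0.35))
scenario = SyntheticScenario(seed=11, offset_components=spec, blink_rate=0.0)
seq = generate_target_sequence(25, seed=11)
rec, truth = generate_recording(seq, scenario)

res = clean_recording(rec)
print(f"latency={res.latency} samples, FixVelT={res.fixvelt:.1f} deg/s")
trial = next(t for t in res.trials if t.included)
post = fit_rjmcmc(trial.offsets, seed=500)
w, mu, sd = post.point_fit
print(f"evidence={post.evidence}, k_modal={post.k_modal}")
print(f"components: means={np.round(mu,3)}, weights={np.round(w,2)}")
```

prints

```
latency=263 samples, FixVelT=20.4 deg/s
evidence=very_strong, k_modal=2
components: means=[0.576 1.573], weights=[0.57 0.43]
```

i.e. the planted two-level offset structure (0.6° for 65% of the
fixation, 1.6° for 35%) is recovered: the estimated latency is the
planted 237 ms reaction time plus about half the saccade duration, the
evidence class is *very strong* multimodality, and the maximum-weight
component recovers the dominant offset level — which is what
`MaxCompMean` reports while the classic mean would land between the two
modes.

The same pipeline is available from the shell:

```bash
fixoffset simulate --out-dir data --n-recordings 2 --seed 1
fixoffset preprocess data/S000_s1.csv --out qc.csv
fixoffset analyze data/*.csv --out-dir results
fixoffset limits --out limits.json
```

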