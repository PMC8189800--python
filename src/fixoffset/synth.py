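"""Synthetic random-saccade-task recordings with known ground truth.

The generator emulates the acquisition conditions of a monocular 1000 Hz
random-saccade task: targets jump at 1 s intervals to uniform random
positions within ±15° (horizontal) × ±9° (vertical) with at least 2°
between consecutive positions; the eye follows each jump after a
truncated-normal saccade latency (mean 237 ms, SD 17 ms, range 192–316 ms)
with a minimum-jerk saccade whose duration follows a main-sequence rule;
fixation samples sit at the target plus a planted angular-offset structure
(a truncated Gaussian mixture over offset magnitude), white measurement
noise, and an optional slow sinusoidal drift.  Blinks appear as NaN blocks
flanked by fast blink-saccade transients, and anticipatory saccades are
inserted with a hazard that grows linearly over the task.

Every inserted event is logged in a ground-truth structure so that the
downstream cleaning and classification stages can be scored sample-by-
sample without any external recording.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .recording import GazeRecording

__all__ = [
    "TargetSequence",
    "MixtureSpec",
    "SyntheticScenario",
    "GroundTruth",
    "generate_target_sequence",
    "generate_recording",
    "generate_offset_sample",
    "EVENT_FIXATION",
    "EVENT_SACCADE",
    "EVENT_BLINK",
    "EVENT_AS_SACCADE",
    "EVENT_AS_PLATEAU",
]

# per-sample event codes in GroundTruth.events
EVENT_FIXATION = 0
EVENT_SACCADE = 1
EVENT_BLINK = 2
EVENT_AS_SACCADE = 3
EVENT_AS_PLATEAU = 4


@dataclass
class TargetSequence:
    """Ordered target positions (degrees) with a fixed dwell per target."""

    positions: np.ndarray  # shape (n_targets, 2)
    dwell_ms: float = 1000.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1 or self.positions.shape[1] != 2:
            raise ValueError("positions must be a non-empty (n, 2) array")

    @property
    def n_targets(self) -> int:
        return self.positions.shape[0]


@dataclass
class MixtureSpec:
    """Gaussian mixture over angular-offset magnitude (degrees, >= 0)."""

    means: tuple = (0.7,)
    sds: tuple = (0.15,)
    weights: tuple = (1.0,)

    def __post_init__(self) -> None:
        self.means = tuple(float(m) for m in self.means)
        self.sds = tuple(float(s) for s in self.sds)
        self.weights = tuple(float(w) for w in self.weights)
        k = len(self.means)
        if not (len(self.sds) == len(self.weights) == k) or k == 0:
            raise ValueError("means, sds and weights must have equal nonzero length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be nonnegative")
        if any(s < 0 for s in self.sds):
            raise ValueError("mixture SDs must be nonnegative")

    @property
    def n_components(self) -> int:
        return len(self.means)


@dataclass
class SyntheticScenario:
    """All tunable generation parameters for one synthetic cohort.

    Defaults reproduce the nominal acquisition conditions of the
    random-saccade task; see the package methods note for the rationale
    behind each value.
    """

    seed: int = 0
    fs: float = 1000.0
    # saccade latency (ms), truncated normal
    latency_mean_ms: float = 237.0
    latency_sd_ms: float = 17.0
    latency_min_ms: float = 192.0
    latency_max_ms: float = 316.0
    # fixation
    fixation_noise_sd: float = 0.05  # deg, white, per channel
    offset_components: MixtureSpec = field(default_factory=MixtureSpec)
    drift_amplitude: float = 0.0  # deg, on offset magnitude
    drift_freq_hz: float = 2.0
    # artefacts
    blink_rate: float = 0.1  # blinks per second
    anticipatory_hazard_slope: float = 0.0  # per-trial increase in AS probability
    # saccade kinematics (main sequence: duration = base + slope * amplitude)
    saccade_ms_per_deg: float = 2.2
    saccade_base_ms: float = 21.0

    def validate(self) -> None:
        if self.latency_sd_ms < 0 or self.latency_min_ms > self.latency_max_ms:
            raise ValueError("invalid latency specification")
        if self.fixation_noise_sd < 0:
            raise ValueError("fixation noise SD must be >= 0")
        if self.blink_rate < 0 or self.anticipatory_hazard_slope < 0:
            raise ValueError("hazards must be >= 0")
        if self.drift_amplitude < 0 or self.drift_freq_hz <= 0:
            raise ValueError("invalid drift specification")
        # triggers MixtureSpec invariant checks
        MixtureSpec(self.offset_components.means,
                    self.offset_components.sds,
                    self.offset_components.weights)


@dataclass
class GroundTruth:
    """Per-sample event labels and inserted-event bookkeeping."""

    events: np.ndarray  # int8 codes, one per sample
    latency_samples: list  # planted latency per target jump (jumps 1..n-1)
    saccade_spans: list  # [start, stop) of main saccades
    blink_spans: list  # [start, stop) including flank transients
    blink_nan_spans: list  # [start, stop) of the NaN block proper
    as_spans: list  # anticipatory saccade movements
    as_plateau_spans: list  # displaced fixation plateaus after an AS
    as_trials: list  # trial index (0-based) of each inserted AS
    component_levels: list  # per trial: list of (component_idx, level_deg)
    fix_trial: np.ndarray = None  # index of the target currently fixated, -1 elsewhere

    def to_dict(self) -> dict:
        return {
            "latency_samples": [int(v) for v in self.latency_samples],
            "saccade_spans": [[int(a), int(b)] for a, b in self.saccade_spans],
            "blink_spans": [[int(a), int(b)] for a, b in self.blink_spans],
            "blink_nan_spans": [[int(a), int(b)] for a, b in self.blink_nan_spans],
            "as_spans": [[int(a), int(b)] for a, b in self.as_spans],
            "as_plateau_spans": [[int(a), int(b)] for a, b in self.as_plateau_spans],
            "as_trials": [int(t) for t in self.as_trials],
            "component_levels": [
                [[int(c), float(v)] for c, v in trial] for trial in self.component_levels
            ],
        }


def generate_target_sequence(
    n_targets: int,
    ranges: tuple[float, float] = (15.0, 9.0),
    min_step: float = 2.0,
    seed: int = 0,
    dwell_ms: float = 1000.0,
) -> TargetSequence:
    """Random target positions, uniform over the range, consecutive jumps >= min_step.

    Candidate positions are drawn uniformly over the full box and rejected
    while closer than ``min_step`` to the previous target, which keeps the
    marginal coverage essentially uniform for small exclusion radii.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    xr, yr = float(ranges[0]), float(ranges[1])
    diagonal = 2.0 * float(np.hypot(xr, yr))
    if min_step >= diagonal:
        raise ValueError(
            f"min_step={min_step} infeasible for range ±{xr} x ±{yr} "
            f"(diagonal {diagonal:.2f})"
        )
    rng = np.random.default_rng(seed)
    pos = np.empty((n_targets, 2))
    pos[0] = rng.uniform([-xr, -yr], [xr, yr])
    for i in range(1, n_targets):
        for _ in range(100_000):
            cand = rng.uniform([-xr, -yr], [xr, yr])
            if np.hypot(*(cand - pos[i - 1])) >= min_step:
                pos[i] = cand
                break
        else:  # pragma: no cover - requires near-degenerate geometry
            raise RuntimeError("rejection sampling failed; min_step too large")
    return TargetSequence(positions=pos, dwell_ms=dwell_ms)


def generate_offset_sample(
    means, sds, weights, n: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. draws from a Gaussian mixture truncated at zero.

    Offsets are angular distances, hence nonnegative: each component is a
    normal truncated to [0, inf).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = MixtureSpec(means, sds, weights)
    rng = np.random.default_rng(seed)
    comp = rng.choice(spec.n_components, size=n, p=spec.weights)
    out = np.empty(n)
    for j in range(spec.n_components):
        idx = np.flatnonzero(comp == j)
        if idx.size == 0:
            continue
        mu, sd = spec.means[j], spec.sds[j]
        if sd == 0:
            out[idx] = max(mu, 0.0)
        else:
            a = (0.0 - mu) / sd
            out[idx] = stats.truncnorm.rvs(
                a, np.inf, loc=mu, scale=sd, size=idx.size, random_state=rng
            )
    return out


def _minjerk(n: int) -> np.ndarray:
    """Minimum-jerk normalized displacement over n samples (ends exactly at 1)."""
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _trunc_level(rng: np.random.Generator, mu: float, sd: float) -> float:
    """One draw from N(mu, sd) truncated to >= 0."""
    if sd == 0:
        return max(mu, 0.0)
    a = (0.0 - mu) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))


def _magnitude_path(
    rng: np.random.Generator,
    n: int,
    spec: MixtureSpec,
    n_cycles: int = 2,
) -> tuple[np.ndarray, list]:
    """Offset-magnitude path for one fixation.

    One level is drawn per mixture component; the fixation dwells at each
    level for a total duration proportional to the component weight,
    interleaved over ``n_cycles`` repetitions so that any sub-window of
    the fixation sees every component.  Level changes are instantaneous
    small shifts — kinematically they read as tiny saccade-like events,
    which is precisely the within-fixation structure that produces
    multimodal offset histograms.
    """
    levels = [
        (j, _trunc_level(rng, spec.means[j], spec.sds[j]))
        for j in range(spec.n_components)
    ]
    if spec.n_components == 1:
        return np.full(n, levels[0][1]), levels
    order = rng.permutation(spec.n_components)
    path = np.empty(n)
    w = np.array(spec.weights, dtype=float)
    bounds = np.round(np.cumsum(np.tile(w[order] / n_cycles, n_cycles)) * n).astype(int)
    pos = 0
    for rank, b in enumerate(bounds):
        j = order[rank % len(order)]
        b = min(max(b, pos), n) if rank < len(bounds) - 1 else n
        path[pos:b] = levels[j][1]
        pos = b
    ordered_levels = [levels[j] for j in order]
    return path, ordered_levels


def generate_recording(
    seq: TargetSequence,
    scenario: SyntheticScenario,
    subject: str = "S000",
    session: int = 1,
) -> tuple[GazeRecording, GroundTruth]:
    """Synthesize one recording following ``seq`` under ``scenario``.

    Returns the recording and the ground truth of every inserted event.
    The pseudo-random stream is derived from (scenario.seed, subject,
    session) so cohorts are reproducible trial-by-trial.
    """
    scenario.validate()
    fs = scenario.fs
    rng = np.random.default_rng(
        [int(scenario.seed), zlib.crc32(str(subject).encode()), int(session)]
    )
    dwell = int(round(seq.dwell_ms * fs / 1000.0))
    n_trials = seq.n_targets
    n = n_trials * dwell

    tx = np.repeat(seq.positions[:, 0], dwell)
    ty = np.repeat(seq.positions[:, 1], dwell)
    gx = np.empty(n)
    gy = np.empty(n)
    events = np.zeros(n, dtype=np.int8)

    spec = scenario.offset_components

    # per-jump latencies (jump i moves the target to position i, i = 1..n-1)
    if scenario.latency_sd_ms > 0:
        a = (scenario.latency_min_ms - scenario.latency_mean_ms) / scenario.latency_sd_ms
        b = (scenario.latency_max_ms - scenario.latency_mean_ms) / scenario.latency_sd_ms
        lat_ms = stats.truncnorm.rvs(
            a, b, loc=scenario.latency_mean_ms, scale=scenario.latency_sd_ms,
            size=max(n_trials - 1, 0), random_state=rng,
        )
    else:
        lat_ms = np.full(max(n_trials - 1, 0), scenario.latency_mean_ms)
    lat = np.round(np.asarray(lat_ms) * fs / 1000.0).astype(int)

    fix_trial = np.full(n, -1, dtype=np.int32)
    gt = GroundTruth(
        events=events, fix_trial=fix_trial, latency_samples=list(lat), saccade_spans=[],
        blink_spans=[], blink_nan_spans=[], as_spans=[], as_plateau_spans=[],
        as_trials=[], component_levels=[],
    )

    def saccade_duration(amplitude: float) -> int:
        ms = scenario.saccade_base_ms + scenario.saccade_ms_per_deg * amplitude
        return max(1, int(round(ms * fs / 1000.0)))

    def fill_fixation(start: int, stop: int, trial: int) -> None:
        """Fixation path on [start, stop): target + offset structure."""
        m = stop - start
        if m <= 0:
            gt.component_levels.append([])
            return
        mag, levels = _magnitude_path(rng, m, spec)
        gt.component_levels.append(levels)
        if scenario.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t_rel = np.arange(m) / fs
            mag = mag + scenario.drift_amplitude * np.sin(
                2 * np.pi * scenario.drift_freq_hz * t_rel + phase
            )
        theta = rng.uniform(0, 2 * np.pi)
        gx[start:stop] = seq.positions[trial, 0] + mag * np.cos(theta)
        gy[start:stop] = seq.positions[trial, 1] + mag * np.sin(theta)
        fix_trial[start:stop] = trial

    # assemble trial by trial: fixation of trial i runs from the arrival of
    # its saccade to the start of the next trial's saccade (latency period)
    cursor = 0
    for i in range(n_trials):
        if i < n_trials - 1:
            sac_start = (i + 1) * dwell + int(lat[i])
        else:
            sac_start = n
        sac_start = min(sac_start, n)
        fill_fixation(cursor, sac_start, i)

        # anticipatory saccade near the end of this fixation
        p_as = min(scenario.anticipatory_hazard_slope * (i + 1), 0.9)
        if i < n_trials - 1 and p_as > 0 and rng.uniform() < p_as:
            lead = int(rng.uniform(0.10, 0.30) * fs)  # 100-300 ms before jump
            as_start = (i + 1) * dwell - lead
            if as_start > cursor + 100:
                amp = rng.uniform(2.5, 4.0)
                axis = rng.integers(2)
                sign = rng.choice([-1.0, 1.0])
                d_as = saccade_duration(amp)
                a_stop = min(as_start + d_as, sac_start)
                prof = amp * _minjerk(a_stop - as_start) * sign
                chan = gx if axis == 0 else gy
                chan[as_start:a_stop] += prof
                chan[a_stop:sac_start] += amp * sign
                gt.as_spans.append((as_start, a_stop))
                gt.as_plateau_spans.append((a_stop, sac_start))
                gt.as_trials.append(i)
                events[as_start:a_stop] = EVENT_AS_SACCADE
                events[a_stop:sac_start] = EVENT_AS_PLATEAU
                fix_trial[as_start:sac_start] = -1

        # main saccade to the next target
        if i < n_trials - 1 and sac_start < n:
            p0 = np.array([gx[sac_start - 1], gy[sac_start - 1]])
            # land at the next fixation's starting position: compute it by
            # peeking at where the next fill will start; we fill the next
            # fixation first then draw the saccade toward its first sample.
            # To keep a single pass, land on the next target and let the
            # next fixation path take over from there (its first sample).
            d = saccade_duration(float(np.hypot(*(seq.positions[i + 1] - p0))))
            sac_stop = min(sac_start + d, n)
            cursor = sac_stop
            # fixation fill for trial i+1 happens on the next loop iteration;
            # draw the saccade as a bridge from p0 toward the next target.
            prof = _minjerk(sac_stop - sac_start)
            gx[sac_start:sac_stop] = p0[0] + (seq.positions[i + 1, 0] - p0[0]) * prof
            gy[sac_start:sac_stop] = p0[1] + (seq.positions[i + 1, 1] - p0[1]) * prof
            events[sac_start:sac_stop] = EVENT_SACCADE
            fix_trial[sac_start:sac_stop] = -1
            gt.saccade_spans.append((sac_start, sac_stop))
        else:
            cursor = n

    # measurement noise on both channels
    if scenario.fixation_noise_sd > 0:
        gx += rng.normal(0, scenario.fixation_noise_sd, n)
        gy += rng.normal(0, scenario.fixation_noise_sd, n)

    # blinks: NaN blocks flanked by fast vertical transients
    if scenario.blink_rate > 0:
        n_blinks = rng.poisson(scenario.blink_rate * n / fs)
        flank = int(0.020 * fs)
        for _ in range(n_blinks):
            blk_len = int(rng.uniform(0.050, 0.300) * fs)
            if n - blk_len - 2 * flank <= 0:
                continue
            start = int(rng.uniform(flank, n - blk_len - flank))
            amp = rng.uniform(3.0, 10.0)
            pre = slice(start - flank, start)
            post = slice(start + blk_len, start + blk_len + flank)
            gy[pre] -= amp * _minjerk(flank)
            gy[post] -= amp * (1.0 - _minjerk(flank))
            gx[start:start + blk_len] = np.nan
            gy[start:start + blk_len] = np.nan
            events[start - flank:start + blk_len + flank] = EVENT_BLINK
            fix_trial[start - flank:start + blk_len + flank] = -1
            gt.blink_spans.append((start - flank, start + blk_len + flank))
            gt.blink_nan_spans.append((start, start + blk_len))

    rec = GazeRecording(
        gaze_x=gx, gaze_y=gy, target_x=tx, target_y=ty, fs=fs,
        subject=subject, session=session,
        meta={"synthetic": True, "seed": scenario.seed},
    )
    return rec, gt
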