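"""Cleaning pipeline that turns a raw recording into per-trial offset series.

The stages, applied in order:

1. remove the average saccade latency (one optimal temporal shift per
   recording, found by minimizing mean angular offset over shifts of
   1..800 samples);
2. remove blink saccades (fast transients flanking NaN blocks), using a
   per-recording fixation velocity threshold (FixVelT, the 90th percentile
   of radial velocity over putative fixation samples);
3. remove saccades by radial-velocity excursion above 55 deg/s, expanded
   to the flanking sub-30 deg/s local minima;
4. remove residual saccade-like events by a sliding 27-sample quadratic
   regression (r^2 > 0.6 and |beta|x1000 > 0.55);
5. remove post-anticipatory-saccade plateaus (channel offset > 2 deg for
   at least 100 ms, overlapping the analysis window).

Cleaning only ever converts samples to NaN; retained values are never
altered, so each removal step is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs
from numpy.lib.stride_tricks import sliding_window_view

from ._runs import bool_runs, nan_runs
from .geometry import angular_distance, to_direction
from .recording import GazeRecording

__all__ = [
    "VelocityProfile",
    "FixationTrial",
    "estimate_latency",
    "apply_latency",
    "trial_offset_matrix",
    "mean_offset_curve",
    "select_analysis_window",
    "compute_velocity",
    "fixation_velocity_threshold",
    "remove_blink_saccades",
    "remove_saccades_velocity",
    "remove_saccades_quadratic",
    "remove_anticipatory",
    "extract_trials",
    "segment_and_include",
    "clean_recording",
    "CleanResult",
]


@dataclass
class VelocityProfile:
    """Per-channel and radial gaze velocity in deg/s."""

    vx: np.ndarray
    vy: np.ndarray

    @property
    def radial(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass
class FixationTrial:
    """One target-dwell's angular offsets inside the analysis window.

    ``window`` is the absolute sample range of the analysis window in
    1-based inclusive convention; ``offsets`` has one entry per window
    sample with NaN marking removed/missing data.
    """

    trial_index: int  # 1-based
    window: tuple[int, int]  # absolute samples, 1-based inclusive
    offsets: np.ndarray
    n_valid: int = 0
    n_nan_blocks: int = 0
    n_segments: int = 0
    included: bool = False

    def recount(self) -> "FixationTrial":
        nan_mask = np.isnan(self.offsets)
        self.n_valid = int((~nan_mask).sum())
        self.n_nan_blocks = len(bool_runs(nan_mask))
        self.n_segments = len(bool_runs(~nan_mask))
        return self


def estimate_latency(rec: GazeRecording, max_shift: int = 800) -> int:
    """Optimal temporal shift (samples) aligning gaze to target.

    Evaluates shifts 1..max_shift of the gaze signal earlier in time,
    choosing the shift with the lowest NaN-ignoring mean angular offset;
    ties resolve to the smallest shift.
    """
    n = rec.n_samples
    if n <= max_shift:
        raise ValueError("recording too short for the requested shift range")
    if np.all(np.isnan(rec.gaze_x)):
        raise ValueError("recording is entirely NaN")
    g = to_direction(rec.gaze_x, rec.gaze_y)
    t = to_direction(rec.target_x, rec.target_y)
    best_shift, best_val = 1, np.inf
    for s in range(1, max_shift + 1):
        dot = np.einsum("ij,ij->i", g[s:], t[: n - s])
        ang = np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))
        with np.errstate(invalid="ignore"):
            m = np.nanmean(ang)
        if np.isfinite(m) and m < best_val - 1e-12:
            best_val, best_shift = m, s
    return best_shift


def apply_latency(rec: GazeRecording, shift: int) -> GazeRecording:
    """Shift gaze earlier by ``shift`` samples and truncate the recording.

    The final, now-incomplete trial is dropped by the caller when cutting
    trials (its tail is truncated here).
    """
    n = rec.n_samples
    out = rec.slice(0, n - shift)
    out.gaze_x = rec.gaze_x[shift:].copy()
    out.gaze_y = rec.gaze_y[shift:].copy()
    out.meta["latency_samples"] = int(shift)
    return out


def trial_offset_matrix(rec: GazeRecording, trial_len: int = 1000) -> np.ndarray:
    """Stack per-sample angular offsets into a (n_trials, trial_len) matrix.

    Only complete trials are kept; a trailing partial trial is dropped.
    """
    n_trials = rec.n_samples // trial_len
    off = angular_distance(
        rec.gaze_x[: n_trials * trial_len],
        rec.gaze_y[: n_trials * trial_len],
        rec.target_x[: n_trials * trial_len],
        rec.target_y[: n_trials * trial_len],
    )
    return off.reshape(n_trials, trial_len)


def mean_offset_curve(
    offset_matrix: np.ndarray, max_offset: float = 60.0
) -> tuple[np.ndarray, int]:
    """Per-sample mean offset across fixations.

    Fixations containing any NaN, or any sample above ``max_offset``
    degrees, are excluded from the average.  Returns (curve, n_used).
    """
    has_nan = np.isnan(offset_matrix).any(axis=1)
    with np.errstate(invalid="ignore"):
        too_big = np.nanmax(np.where(np.isnan(offset_matrix), -np.inf, offset_matrix),
                            axis=1) > max_offset
    keep = ~(has_nan | too_big)
    if not keep.any():
        raise ValueError("no fixation passes the averaging exclusions")
    return offset_matrix[keep].mean(axis=0), int(keep.sum())


def select_analysis_window(curve: np.ndarray, width: int = 500) -> tuple[int, int]:
    """Contiguous window of ``width`` samples with the lowest mean offset.

    Returns (start, end) in 1-based inclusive sample numbering; ties
    resolve to the earliest window.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) < width:
        raise ValueError("curve shorter than the window width")
    c = np.concatenate([[0.0], np.cumsum(curve)])
    sums = c[width:] - c[:-width]
    start0 = int(np.argmin(np.round(sums, 12)))  # earliest among float ties
    return (start0 + 1, start0 + width)


def compute_velocity(
    rec: GazeRecording, window_ms: float = 7.0, polyorder: int = 2
) -> VelocityProfile:
    """Savitzky-Golay first-derivative velocity, centered (delay-free), deg/s."""
    win = int(round(window_ms * rec.fs / 1000.0))
    if win % 2 == 0:
        win += 1
    win = max(win, polyorder + 2 if (polyorder + 2) % 2 == 1 else polyorder + 3)
    if rec.n_samples < win:
        raise ValueError("recording shorter than the filter window")
    # explicit centered convolution: NaNs propagate into the surrounding
    # half-window instead of raising, and the edge half-windows (where no
    # full centered fit exists) are NaN
    c = savgol_coeffs(win, polyorder, deriv=1, delta=1.0 / rec.fs, use="conv")
    half = win // 2
    out = []
    for x in (rec.gaze_x, rec.gaze_y):
        v = np.convolve(x, c, mode="same")
        v[:half] = np.nan
        v[-half:] = np.nan
        out.append(v)
    return VelocityProfile(vx=out[0], vy=out[1])


def fixation_velocity_threshold(
    vel: VelocityProfile,
    fs: float = 1000.0,
    peak_thresh: float = 55.0,
    min_block_ms: float = 40.0,
    edge_skip: int = 4,
    percentile: float = 90.0,
) -> float:
    """FixVelT: 90th percentile of radial velocity over putative fixations.

    Stretches with radial velocity above ``peak_thresh`` are removed; the
    remaining blocks shorter than ``min_block_ms`` are rejected; the first
    and last ``edge_skip`` samples of surviving blocks are skipped; the
    percentile is taken over the pooled remaining samples.
    """
    radial = vel.radial
    fixlike = np.isfinite(radial) & ~(radial > peak_thresh)
    min_len = int(round(min_block_ms * fs / 1000.0))
    pooled = []
    for a, b in bool_runs(fixlike):
        if b - a < min_len:
            continue
        seg = radial[a + edge_skip : b - edge_skip]
        if seg.size:
            pooled.append(seg)
    if not pooled:
        raise ValueError("no fixation-like samples survive; cannot set FixVelT")
    return float(np.percentile(np.concatenate(pooled), percentile))


def _position_nan_mask(rec: GazeRecording) -> np.ndarray:
    return np.isnan(rec.gaze_x) | np.isnan(rec.gaze_y)


def remove_blink_saccades(
    rec: GazeRecording, vel: VelocityProfile, fixvelt: float
) -> GazeRecording:
    """NaN the fast blink-saccade transients flanking every NaN block.

    From the last good sample before each NaN block, march backward until
    three contiguous samples all have radial velocity below FixVelT; the
    one of the three closest to the block marks the blink-saccade start
    (it remains valid — it is the end of the prior fixation).  Mirror
    forward after the block.  NaN radial samples never count as below
    threshold.
    """
    out = rec.copy()
    radial = vel.radial
    n = out.n_samples
    below = np.isfinite(radial) & (radial < fixvelt)
    for b0, b1 in nan_runs(np.where(_position_nan_mask(rec), np.nan, 0.0)):
        # backward: find j with below[j-2:j+1] all True, j as close to b0 as possible
        mark = None
        for j in range(b0 - 1, 1, -1):
            if below[j] and below[j - 1] and below[j - 2]:
                mark = j
                break
        lo = 0 if mark is None else mark + 1
        out.gaze_x[lo:b0] = np.nan
        out.gaze_y[lo:b0] = np.nan
        # forward
        mark = None
        for j in range(b1, n - 2):
            if below[j] and below[j + 1] and below[j + 2]:
                mark = j
                break
        hi = n if mark is None else mark
        out.gaze_x[b1:hi] = np.nan
        out.gaze_y[b1:hi] = np.nan
    return out


def remove_saccades_velocity(
    rec: GazeRecording,
    vel: VelocityProfile,
    peak_thresh: float = 55.0,
    min_thresh: float = 30.0,
) -> GazeRecording:
    """NaN every saccade: supra-55 deg/s blocks expanded to sub-30 local minima."""
    out = rec.copy()
    radial = vel.radial
    n = out.n_samples
    supra = np.isfinite(radial) & (radial > peak_thresh)

    def is_local_min(j: int) -> bool:
        left = radial[j - 1] if j > 0 else np.inf
        right = radial[j + 1] if j < n - 1 else np.inf
        if not np.isfinite(radial[j]):
            return False
        left = np.inf if not np.isfinite(left) else left
        right = np.inf if not np.isfinite(right) else right
        return radial[j] <= left and radial[j] <= right

    for s0, s1 in bool_runs(supra):
        start = s0
        for j in range(s0 - 1, -1, -1):
            if not np.isfinite(radial[j]):
                start = j + 1
                break
            if radial[j] < min_thresh and is_local_min(j):
                start = j
                break
        else:
            start = 0
        end = s1 - 1
        for j in range(s1, n):
            if not np.isfinite(radial[j]):
                end = j - 1
                break
            if radial[j] < min_thresh and is_local_min(j):
                end = j
                break
        else:
            end = n - 1
        out.gaze_x[start : end + 1] = np.nan
        out.gaze_y[start : end + 1] = np.nan
    return out


def remove_saccades_quadratic(
    rec: GazeRecording,
    window: int = 27,
    r2_min: float = 0.6,
    beta_min: float = 0.55,
) -> GazeRecording:
    """NaN windows where a pure-quadratic regression fits position well.

    Position in each sliding ``window``-sample stretch is regressed (with
    intercept) on the squared within-window sample index 1^2..window^2,
    channel by channel.  Windows with r^2 > ``r2_min`` and |beta| x 1000 >
    ``beta_min`` are flagged; the union of flagged windows is set to NaN.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = rec.n_samples
    if n < window:
        raise ValueError("recording shorter than the regression window")
    out = rec.copy()
    x = (np.arange(1, window + 1, dtype=float)) ** 2
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    flag_any = np.zeros(n - window + 1, dtype=bool)
    for pos in (rec.gaze_x, rec.gaze_y):
        w = sliding_window_view(pos, window)
        valid = ~np.isnan(w).any(axis=1)
        wc = w - w.mean(axis=1, keepdims=True)
        beta = (wc @ xc) / sxx
        syy = np.einsum("ij,ij->i", wc, wc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(syy > 0, beta**2 * sxx / syy, 0.0)
        flag_any |= valid & (r2 > r2_min) & (np.abs(beta) * 1000.0 > beta_min)
    # union of flagged windows via a difference array
    bump = np.zeros(n + 1, dtype=int)
    idx = np.flatnonzero(flag_any)
    np.add.at(bump, idx, 1)
    np.add.at(bump, idx + window, -1)
    mask = np.cumsum(bump[:-1]) > 0
    out.gaze_x[mask] = np.nan
    out.gaze_y[mask] = np.nan
    return out


def remove_anticipatory(
    rec: GazeRecording,
    window: tuple[int, int] = (192, 691),
    trial_len: int = 1000,
    offset_thresh: float = 2.0,
    min_dur_ms: float = 100.0,
) -> tuple[GazeRecording, list[tuple[int, int]]]:
    """NaN post-anticipatory-saccade plateaus within each trial.

    A plateau is a contiguous run of samples whose horizontal or vertical
    offset magnitude exceeds ``offset_thresh`` degrees.  Runs shorter than
    ``min_dur_ms`` are ignored; runs overlapping the analysis window (even
    partially) are NaN'd.  Returns the cleaned recording and a log of
    (trial_index_1based, run_start_within_trial_1based) for the
    AS-frequency report.
    """
    out = rec.copy()
    n_trials = rec.n_samples // trial_len
    min_len = int(round(min_dur_ms * rec.fs / 1000.0))
    w0, w1 = window[0] - 1, window[1]  # 0-based [w0, w1)
    as_log: list[tuple[int, int]] = []
    for i in range(n_trials):
        a = i * trial_len
        dx = np.abs(rec.gaze_x[a : a + trial_len] - rec.target_x[a : a + trial_len])
        dy = np.abs(rec.gaze_y[a : a + trial_len] - rec.target_y[a : a + trial_len])
        over = np.where(np.isnan(dx) | np.isnan(dy), False,
                        (dx > offset_thresh) | (dy > offset_thresh))
        for r0, r1 in bool_runs(over):
            if r1 - r0 < min_len:
                continue
            if r1 <= w0 or r0 >= w1:
                continue
            out.gaze_x[a + r0 : a + r1] = np.nan
            out.gaze_y[a + r0 : a + r1] = np.nan
            as_log.append((i + 1, r0 + 1))
    return out, as_log


def extract_trials(
    rec: GazeRecording,
    window: tuple[int, int] = (192, 691),
    trial_len: int = 1000,
) -> list[FixationTrial]:
    """Cut the cleaned recording into per-trial analysis-window offsets."""
    n_trials = rec.n_samples // trial_len
    off = trial_offset_matrix(rec, trial_len)
    w0, w1 = window[0] - 1, window[1]
    trials = []
    for i in range(n_trials):
        t = FixationTrial(
            trial_index=i + 1,
            window=(i * trial_len + window[0], i * trial_len + window[1]),
            offsets=off[i, w0:w1].copy(),
        )
        trials.append(segment_and_include(t))
    return trials


def segment_and_include(
    trial: FixationTrial, min_valid: int = 400, max_nan_blocks: int = 4
) -> FixationTrial:
    """Count segments/NaN blocks and set the inclusion flag for one trial."""
    trial.recount()
    trial.included = (
        trial.n_valid >= min_valid and trial.n_nan_blocks <= max_nan_blocks
    )
    return trial


@dataclass
class CleanResult:
    """Outcome of the full cleaning pipeline for one recording."""

    recording: GazeRecording
    trials: list
    latency: int
    fixvelt: float
    window: tuple[int, int]
    as_log: list = field(default_factory=list)


def clean_recording(
    rec: GazeRecording,
    window: tuple[int, int] = (192, 691),
    max_shift: int = 800,
    trial_len: int = 1000,
    sg_window_ms: float = 7.0,
    sg_polyorder: int = 2,
    latency: int | None = None,
) -> CleanResult:
    """Run every cleaning stage in order and cut per-trial offsets.

    ``latency`` overrides the estimated shift when given (useful for
    already-aligned synthetic data).
    """
    shift = estimate_latency(rec, max_shift) if latency is None else int(latency)
    aligned = apply_latency(rec, shift)
    vel = compute_velocity(aligned, sg_window_ms, sg_polyorder)
    fixvelt = fixation_velocity_threshold(vel, fs=aligned.fs)
    step2 = remove_blink_saccades(aligned, vel, fixvelt)
    step3 = remove_saccades_velocity(step2, vel)
    step4 = remove_saccades_quadratic(step3)
    step5, as_log = remove_anticipatory(step4, window=window, trial_len=trial_len)
    trials = extract_trials(step5, window=window, trial_len=trial_len)
    return CleanResult(
        recording=step5, trials=trials, latency=shift, fixvelt=fixvelt,
        window=window, as_log=as_log,
    )
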