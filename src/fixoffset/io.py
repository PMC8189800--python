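"""Readers, writers and configuration for the analysis pipeline.

The on-disk recording dialect is a long CSV, one file per (subject,
session), with per-sample columns ``time_ms, gaze_x, gaze_y, target_x,
target_y`` in degrees of visual angle and missing samples left empty.
A ``column_map`` lets files with other header names (e.g. a public
database's native columns) be read without rewriting them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import GazeRecording
from .synth import GroundTruth

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "write_ground_truth",
    "read_ground_truth",
]

_CANONICAL = ("time_ms", "gaze_x", "gaze_y", "target_x", "target_y")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, in documented units.

    Defaults are the published operating points of the cleaning and
    classification stages; the analysis window may either be fixed or
    recomputed from the cohort's mean offset curve.
    """

    # latency search
    max_shift: int = 800  # samples
    trial_len: int = 1000  # samples per target dwell (1 s at 1000 Hz)
    # velocity / saccade removal
    sg_window_ms: float = 7.0
    sg_polyorder: int = 2
    saccade_peak_thresh: float = 55.0  # deg/s
    saccade_min_thresh: float = 30.0  # deg/s
    fixvelt_percentile: float = 90.0
    fixvelt_min_block_ms: float = 40.0
    fixvelt_edge_skip: int = 4  # samples
    # quadratic (step-2) detector
    quad_window: int = 27  # samples
    quad_r2_min: float = 0.6
    quad_beta_min: float = 0.55  # on |beta| x 1000
    # anticipatory saccades
    as_offset_thresh: float = 2.0  # deg
    as_min_dur_ms: float = 100.0
    # analysis window / inclusion
    window: tuple = (192, 691)  # 1-based inclusive samples within a trial
    recompute_window: bool = False
    window_width: int = 500
    min_valid: int = 400
    max_nan_blocks: int = 4
    min_good_fixations: int = 20  # per session, else the subject is excluded
    # multimodality
    kmax: int = 5
    n_iter: int = 2000
    burn_in: int = 500
    run_acr: bool = False
    acr_n_boot: int = 500
    # normality
    normality_n: int = 500
    normality_reps: int = 10_000
    # drift
    fft_length: int = 512
    # randomness
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["window"] = list(d["window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(**d)


def write_recording(rec: GazeRecording, path) -> None:
    """Write a recording in the pipeline's CSV dialect (NaN as empty)."""
    t_ms = np.arange(rec.n_samples) * 1000.0 / rec.fs
    df = pd.DataFrame({
        "time_ms": t_ms,
        "gaze_x": rec.gaze_x,
        "gaze_y": rec.gaze_y,
        "target_x": rec.target_x,
        "target_y": rec.target_y,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(
    path,
    column_map: dict | None = None,
    fs: float = 1000.0,
    subject: str | None = None,
    session: int = 1,
) -> GazeRecording:
    """Read a recording CSV, validating time monotonicity and units.

    ``column_map`` maps canonical names (``time_ms``, ``gaze_x``, ...)
    to the file's actual column names.
    """
    df = pd.read_csv(path)
    cmap = {name: name for name in _CANONICAL}
    if column_map:
        cmap.update(column_map)
    missing = [cmap[c] for c in _CANONICAL if cmap[c] not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    t = df[cmap["time_ms"]].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
        raise ValueError("sampling must be uniform")
    channels = {}
    for c in _CANONICAL[1:]:
        v = df[cmap[c]].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and np.any(np.abs(finite) > 90):
            raise ValueError(
                f"column {cmap[c]} has |value| > 90; expected degrees of visual angle"
            )
        channels[c] = v
    if subject is None:
        subject = Path(path).stem
    return GazeRecording(
        gaze_x=channels["gaze_x"], gaze_y=channels["gaze_y"],
        target_x=channels["target_x"], target_y=channels["target_y"],
        fs=fs, subject=subject, session=session,
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Sidecar ground-truth file (JSON) with event indices and true parameters."""
    Path(path).write_text(json.dumps(gt.to_dict(), indent=1))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
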