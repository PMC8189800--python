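"""In-memory container for one random-saccade-task recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class GazeRecording:
    """Per-sample gaze and target time series for one session.

    All position channels are in degrees of visual angle; missing samples
    (blinks, removed artefacts) are NaN.  Sampling is uniform at ``fs`` Hz
    (1000 Hz nominal for the random-saccade task).
    """

    gaze_x: np.ndarray
    gaze_y: np.ndarray
    target_x: np.ndarray
    target_y: np.ndarray
    fs: float = 1000.0
    subject: str = "S000"
    session: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.target_x = np.asarray(self.target_x, dtype=float)
        self.target_y = np.asarray(self.target_y, dtype=float)
        n = len(self.gaze_x)
        if not all(len(a) == n for a in (self.gaze_y, self.target_x, self.target_y)):
            raise ValueError("all channels must have the same length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.gaze_x)

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "GazeRecording":
        return replace(
            self,
            gaze_x=self.gaze_x.copy(),
            gaze_y=self.gaze_y.copy(),
            target_x=self.target_x.copy(),
            target_y=self.target_y.copy(),
            meta=dict(self.meta),
        )

    def slice(self, start: int, stop: int) -> "GazeRecording":
        """Sub-recording over sample range [start, stop)."""
        return replace(
            self,
            gaze_x=self.gaze_x[start:stop].copy(),
            gaze_y=self.gaze_y[start:stop].copy(),
            target_x=self.target_x[start:stop].copy(),
            target_y=self.target_y[start:stop].copy(),
            meta=dict(self.meta),
        )
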