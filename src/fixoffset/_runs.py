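"""Run-length helpers for NaN bookkeeping."""

from __future__ import annotations

import numpy as np


def bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True runs of a boolean mask as [start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def nan_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous NaN runs as [start, stop) pairs."""
    return bool_runs(np.isnan(np.asarray(x, dtype=float)))


def valid_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous non-NaN runs as [start, stop) pairs."""
    return bool_runs(~np.isnan(np.asarray(x, dtype=float)))
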