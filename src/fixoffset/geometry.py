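"""Angular geometry of gaze and target positions.

Positions are expressed in degrees of visual angle ``(x, y)`` relative to
primary position.  A position maps to a 3-D direction vector via the
tangent-plane convention ``(tan x, tan y, 1)``, normalised to unit length,
and the angular separation of two positions is the arc between their
direction vectors.  For small separations near primary position this is
numerically very close to the plane Euclidean distance (within about 0.5%
at 10 degrees), which is why the Euclidean form is offered as a checked
shortcut.

All functions are NaN-preserving and vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "to_direction",
    "angular_distance",
    "euclidean_distance",
    "offset_series",
]

_MAX_ANGLE = 90.0  # tangent undefined at/beyond 90 degrees


def _check_angles(x: np.ndarray, y: np.ndarray) -> None:
    # NaN samples are allowed (missing data); only finite values are checked.
    for arr in (x, y):
        finite = arr[np.isfinite(arr)]
        if finite.size and np.any(np.abs(finite) >= _MAX_ANGLE):
            raise ValueError(
                "gaze/target angles must satisfy |angle| < 90 degrees; "
                f"got extreme value {finite[np.argmax(np.abs(finite))]:.3f}"
            )


def to_direction(x, y):
    """Map position(s) in degrees to unit direction vector(s).

    Parameters
    ----------
    x, y : float or array-like
        Horizontal and vertical position in degrees of visual angle,
        ``|x|, |y| < 90``.

    Returns
    -------
    ndarray
        Unit vectors with shape ``(..., 3)``; the unnormalised vector is
        ``(tan x, tan y, 1)``.  NaN inputs yield NaN vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_angles(x, y)
    tx = np.tan(np.radians(x))
    ty = np.tan(np.radians(y))
    v = np.stack([tx, ty, np.ones_like(tx)], axis=-1)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / norm


def angular_distance(x1, y1, x2, y2):
    """Angular distance in degrees between two positions.

    Computed as ``arccos`` of the dot product of the two unit direction
    vectors; the dot product is clamped into [-1, 1] so that rounding can
    never produce NaN for valid input.  Result lies in [0, 180].
    """
    v1 = to_direction(x1, y1)
    v2 = to_direction(x2, y2)
    dot = np.sum(v1 * v2, axis=-1)
    dot = np.clip(dot, -1.0, 1.0)
    return np.degrees(np.arccos(dot))


def euclidean_distance(x1, y1, x2, y2):
    """Plane Euclidean distance in degrees between two positions."""
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    return np.hypot(x1 - x2, y1 - y2)


def offset_series(rec, *, method: str = "angular") -> np.ndarray:
    """Per-sample angular offset of gaze from target for a recording.

    Parameters
    ----------
    rec : GazeRecording
        Recording with aligned gaze and target channels (latency already
        removed).
    method : {"angular", "euclidean"}
        Distance convention; "angular" is the default and the reference.

    Returns
    -------
    ndarray
        Offset in degrees per sample; NaN wherever any input channel is NaN.
    """
    gx, gy = rec.gaze_x, rec.gaze_y
    tx, ty = rec.target_x, rec.target_y
    if not (len(gx) == len(gy) == len(tx) == len(ty)):
        raise ValueError("gaze and target channels must have equal length")
    if method == "angular":
        return angular_distance(gx, gy, tx, ty)
    if method == "euclidean":
        return euclidean_distance(gx, gy, tx, ty)
    raise ValueError(f"unknown method {method!r}")
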