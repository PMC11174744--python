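"""Joint-angle computation from landmarks and signal conditioning.

Angles are interior joint angles measured in the image plane (sagittal-plane
assumption): 180° is full extension, and values live in [0, 180].  The knee
angle is taken at the knee between the thigh (knee→hip) and the shank
(knee→ankle); the ankle angle at the ankle between the shank (ankle→knee)
and the instep (ankle→toe).  Depth, when present, is deliberately ignored.

Missing-data policy: a frame lacking any required landmark yields a missing
(NaN) angle; no imputation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import pandas as pd

from .errors import (
    EmptySeriesError,
    ExtrapolationError,
    ParameterError,
    UndefinedAngleError,
)
from .landmark_io import LandmarkSequence, ReferenceAngleSeries


@dataclass
class JointAngleSeries:
    """Per-frame interior joint angles in degrees; NaN marks missing frames."""

    timestamps: np.ndarray
    angles: np.ndarray
    joint: str
    side: str
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.timestamps.shape != self.angles.shape:
            raise ParameterError("timestamps and angles must have equal length")
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 180 + 1e-9):
            raise ParameterError("angles must lie in [0, 180] or be missing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps,
                "joint": self.joint,
                "side": self.side,
                "angle_deg": self.angles,
                "smoothed": self.smoothed,
            }
        )


def interior_angle(a, b, c) -> float:
    """Interior angle at vertex ``b`` between rays b→a and b→c, in degrees.

    The result lies in [0, 180] and is invariant under translation, rotation,
    reflection and uniform scaling of the three points, so it is the same in
    image pixels and in metric world coordinates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.hypot(u[0], u[1])
    nv = np.hypot(v[0], v[1])
    if nu == 0.0 or nv == 0.0:
        raise UndefinedAngleError("angle undefined: vertex coincides with an endpoint")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _angle_arrays(ax, ay, bx, by, cx, cy) -> np.ndarray:
    """Vectorized interior angle at (bx, by); NaN where any point is missing."""
    ux, uy = ax - bx, ay - by
    vx, vy = cx - bx, cy - by
    nu = np.hypot(ux, uy)
    nv = np.hypot(vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (ux * vx + uy * vy) / (nu * nv)
        cos = np.clip(cos, -1.0, 1.0)
        ang = np.degrees(np.arccos(cos))
    ang = np.where((nu == 0) | (nv == 0), np.nan, ang)
    return ang


def _joint_series(
    seq: LandmarkSequence, side: str, names: tuple[str, str, str], joint: str
) -> JointAngleSeries:
    t, ax, ay = seq.track(names[0], side)
    _, bx, by = seq.track(names[1], side)
    _, cx, cy = seq.track(names[2], side)
    angles = _angle_arrays(ax, ay, bx, by, cx, cy)
    if not np.isfinite(angles).any():
        raise EmptySeriesError(
            f"{joint} angle undefined on side {side!r}: required landmarks never co-observed"
        )
    return JointAngleSeries(timestamps=t, angles=angles, joint=joint, side=side)


def knee_angle_series(seq: LandmarkSequence, side: str) -> JointAngleSeries:
    """Knee interior angle (hip–knee–ankle) per frame, degrees."""
    return _joint_series(seq, side, ("hip", "knee", "ankle"), "knee")


def ankle_angle_series(seq: LandmarkSequence, side: str) -> JointAngleSeries:
    """Ankle interior angle (knee–ankle–toe) per frame, degrees."""
    return _joint_series(seq, side, ("knee", "ankle", "toe"), "ankle")


#: Default smoothing window: 5 frames = 0.2 s at the nominal 25 fps rate.
DEFAULT_SMOOTHING_WINDOW = 5


def moving_average(
    series: JointAngleSeries, window: int = DEFAULT_SMOOTHING_WINDOW
) -> JointAngleSeries:
    """Centered moving mean with edge truncation.

    The window must be odd so the filter is symmetric.  Missing entries are
    excluded from each window's mean but remain missing in the output, and
    the window shrinks at the series edges, so output length equals input
    length and a constant series is returned unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd count >= 1, got {window}")
    s = pd.Series(series.angles)
    smoothed = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    smoothed[~np.isfinite(series.angles)] = np.nan
    return replace(series, angles=smoothed, smoothed=True)


AnySeries = Union[JointAngleSeries, ReferenceAngleSeries]


def resample_to(series: AnySeries, timebase) -> AnySeries:
    """Linearly interpolate a series onto ``timebase``.

    The target timebase must lie within the series' time span.  Target points
    whose bracketing source interval touches a missing value are missing in
    the output (missing spans propagate; they are never bridged).
    """
    timebase = np.asarray(timebase, dtype=float)
    t = series.timestamps
    if len(t) == 0:
        raise ExtrapolationError("cannot resample an empty series")
    if timebase.size and (timebase.min() < t[0] - 1e-12 or timebase.max() > t[-1] + 1e-12):
        raise ExtrapolationError(
            f"timebase [{timebase.min():g}, {timebase.max():g}] outside series span "
            f"[{t[0]:g}, {t[-1]:g}]"
        )
    angles = series.angles
    valid = np.isfinite(angles)
    if valid.any():
        out = np.interp(timebase, t[valid], angles[valid])
    else:
        out = np.full(timebase.shape, np.nan)
    # propagate missing: a target point bracketed by a missing source sample
    # (on either side in the *full* grid) is itself missing
    right = np.searchsorted(t, timebase, side="left")
    left = np.clip(np.searchsorted(t, timebase, side="right") - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    bad = ~valid[left] | ~valid[right]
    out = np.where(bad, np.nan, out)
    if isinstance(series, ReferenceAngleSeries):
        return ReferenceAngleSeries(
            timestamps=timebase,
            angles=out,
            joint=series.joint,
            source_label=series.source_label,
        )
    return replace(series, timestamps=timebase, angles=out)
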