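"""Data model and CSV persistence for pose-landmark and reference-angle streams.

The pipeline consumes whole-body pose-estimator output reduced to a fixed
sagittal-plane vocabulary: ``head_top`` and ``nose`` (unsided) plus ``hip``,
``knee``, ``ankle``, ``heel`` and ``toe`` on each side.  Coordinates follow
the image convention — pixels, origin top-left, x rightward, y downward —
with 0-based frame indices.

CSV schema (comma separated, dot decimal, UTF-8, header required)::

    frame_index, timestamp_s, landmark, side, x_px, y_px, depth_m, visibility

``side`` is empty for unsided landmarks and ``depth_m`` is empty when the
capture had no depth stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, ValidationError

UNSIDED_LANDMARKS = ("head_top", "nose")
SIDED_LANDMARKS = ("hip", "knee", "ankle", "heel", "toe")
SIDES = ("left", "right")

#: Default confidence floor below which a detection is treated as missing.
DEFAULT_VISIBILITY_FLOOR = 0.5

LANDMARK_COLUMNS = [
    "frame_index",
    "timestamp_s",
    "landmark",
    "side",
    "x_px",
    "y_px",
    "depth_m",
    "visibility",
]

REFERENCE_COLUMNS = ["timestamp_s", "angle_deg", "joint", "source"]


def _check_name_side(name: str, side: Optional[str]) -> None:
    if name in UNSIDED_LANDMARKS:
        if side is not None:
            raise ValidationError(f"landmark {name!r} is unsided, got side={side!r}")
    elif name in SIDED_LANDMARKS:
        if side not in SIDES:
            raise ValidationError(f"landmark {name!r} requires side in {SIDES}, got {side!r}")
    else:
        raise ValidationError(f"unknown landmark name {name!r}")


@dataclass(frozen=True)
class Landmark:
    """A single named 2D keypoint in one frame.

    ``imputed`` marks landmarks filled in by :func:`interpolate_gaps`; it is
    an in-memory annotation and is not persisted to CSV.
    """

    name: str
    side: Optional[str]
    x: float
    y: float
    visibility: float = 1.0
    depth: Optional[float] = None
    imputed: bool = False

    def __post_init__(self) -> None:
        _check_name_side(self.name, self.side)
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates for {self.key}")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValidationError(f"visibility {self.visibility} outside [0, 1] for {self.key}")
        if self.depth is not None and not self.depth > 0:
            raise ValidationError(f"depth must be absent or > 0, got {self.depth}")

    @property
    def key(self) -> tuple[str, Optional[str]]:
        return (self.name, self.side)

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class LandmarkFrame:
    """All landmarks observed in one video frame."""

    frame_index: int
    timestamp: float
    landmarks: dict[tuple[str, Optional[str]], Landmark] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame_index {self.frame_index}")
        for key, lm in self.landmarks.items():
            if key != lm.key:
                raise ValidationError(f"landmark stored under wrong key {key} != {lm.key}")

    def add(self, lm: Landmark) -> None:
        if lm.key in self.landmarks:
            raise ValidationError(
                f"duplicate landmark {lm.key} in frame {self.frame_index}"
            )
        self.landmarks[lm.key] = lm

    def get(self, name: str, side: Optional[str] = None) -> Optional[Landmark]:
        return self.landmarks.get((name, side))


@dataclass
class LandmarkSequence:
    """Time-ordered landmark frames with a nominal capture rate."""

    frames: list[LandmarkFrame]
    nominal_rate: float = 25.0
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR

    def __post_init__(self) -> None:
        if not self.nominal_rate > 0:
            raise ValidationError(f"nominal_rate must be > 0, got {self.nominal_rate}")
        self.validate()

    def validate(self) -> None:
        for i in range(1, len(self.frames)):
            a, b = self.frames[i - 1], self.frames[i]
            if b.timestamp <= a.timestamp:
                raise ValidationError(
                    "timestamps not strictly increasing at frame "
                    f"{b.frame_index} (row {i}): {b.timestamp} <= {a.timestamp}"
                )
            if b.frame_index <= a.frame_index:
                raise ValidationError(
                    f"frame_index not strictly increasing at row {i}: "
                    f"{b.frame_index} <= {a.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        return iter(self.frames)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSequence):
            return NotImplemented
        if len(self.frames) != len(other.frames) or self.nominal_rate != other.nominal_rate:
            return False
        for fa, fb in zip(self.frames, other.frames):
            if (fa.frame_index, fa.timestamp) != (fb.frame_index, fb.timestamp):
                return False
            if set(fa.landmarks) != set(fb.landmarks):
                return False
            for key, la in fa.landmarks.items():
                lb = fb.landmarks[key]
                if (la.x, la.y, la.visibility, la.depth) != (lb.x, lb.y, lb.visibility, lb.depth):
                    return False
        return True

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def track(
        self,
        name: str,
        side: Optional[str] = None,
        respect_floor: bool = True,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame (t, x, y) arrays for one landmark; NaN where missing.

        A detection below the sequence's visibility floor counts as missing
        unless ``respect_floor`` is False.
        """
        _check_name_side(name, side)
        n = len(self.frames)
        t = self.timestamps
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        for i, frame in enumerate(self.frames):
            lm = frame.get(name, side)
            if lm is None:
                continue
            if respect_floor and not lm.imputed and lm.visibility < self.visibility_floor:
                continue
            x[i], y[i] = lm.x, lm.y
        return t, x, y

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for frame in self.frames:
            for lm in frame.landmarks.values():
                rows.append(
                    {
                        "frame_index": frame.frame_index,
                        "timestamp_s": frame.timestamp,
                        "landmark": lm.name,
                        "side": "" if lm.side is None else lm.side,
                        "x_px": lm.x,
                        "y_px": lm.y,
                        "depth_m": np.nan if lm.depth is None else lm.depth,
                        "visibility": lm.visibility,
                    }
                )
        return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


@dataclass
class ReferenceAngleSeries:
    """A reference joint-angle stream, e.g. from a MEMS-IMU system."""

    timestamps: np.ndarray
    angles: np.ndarray
    joint: str
    source_label: str = "MEMS"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.timestamps.shape != self.angles.shape:
            raise ValidationError("timestamps and angles must have the same length")
        if self.joint not in ("knee", "ankle"):
            raise ValidationError(f"joint must be 'knee' or 'ankle', got {self.joint!r}")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("reference timestamps must be strictly increasing")


def _sequence_from_dataframe(
    df: pd.DataFrame, nominal_rate: float, visibility_floor: float
) -> LandmarkSequence:
    frames: list[LandmarkFrame] = []
    for (idx, ts), group in df.groupby(["frame_index", "timestamp_s"], sort=False):
        frame = LandmarkFrame(frame_index=int(idx), timestamp=float(ts))
        for row in group.itertuples(index=False):
            side = None if (pd.isna(row.side) or row.side == "") else str(row.side)
            depth = None if pd.isna(row.depth_m) else float(row.depth_m)
            frame.add(
                Landmark(
                    name=str(row.landmark),
                    side=side,
                    x=float(row.x_px),
                    y=float(row.y_px),
                    visibility=float(row.visibility),
                    depth=depth,
                )
            )
        frames.append(frame)
    return LandmarkSequence(
        frames=frames, nominal_rate=nominal_rate, visibility_floor=visibility_floor
    )


def read_landmark_csv(
    path,
    nominal_rate: float = 25.0,
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR,
) -> LandmarkSequence:
    """Load a landmark CSV into a validated :class:`LandmarkSequence`.

    Rows with visibility below ``visibility_floor`` are loaded but treated as
    missing by downstream consumers of :meth:`LandmarkSequence.track`.
    """
    df = pd.read_csv(path, dtype={"side": "string"}, float_precision="round_trip")
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return _sequence_from_dataframe(df, nominal_rate, visibility_floor)


def write_landmark_csv(seq: LandmarkSequence, path) -> None:
    """Write a sequence to CSV at full float precision (repr round-trip)."""
    # pandas' default float writer keeps only 16 significant digits; shortest
    # repr is required for read(write(x)) == x at the binary-float level
    seq.to_dataframe().to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_reference_csv(path) -> list[ReferenceAngleSeries]:
    """Load reference angle streams, one series per (joint, source) pair."""
    df = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out = []
    for (joint, source), group in df.groupby(["joint", "source"], sort=False):
        out.append(
            ReferenceAngleSeries(
                timestamps=group["timestamp_s"].to_numpy(float),
                angles=group["angle_deg"].to_numpy(float),
                joint=str(joint),
                source_label=str(source),
            )
        )
    return out


def write_reference_csv(series: ReferenceAngleSeries, path) -> None:
    pd.DataFrame(
        {
            "timestamp_s": series.timestamps,
            "angle_deg": series.angles,
            "joint": series.joint,
            "source": series.source_label,
        }
    ).to_csv(path, index=False)


def interpolate_gaps(seq: LandmarkSequence, max_gap: int) -> LandmarkSequence:
    """Fill short detection dropouts by linear interpolation.

    For every landmark track, runs of frames where the landmark is absent or
    below the visibility floor are filled linearly (against timestamps) from
    the flanking observed frames, provided the run is at most ``max_gap``
    frames long.  Filled landmarks are flagged ``imputed``; longer runs and
    runs touching the sequence boundary are left missing.  The operation is
    idempotent.
    """
    if max_gap < 0:
        raise ParameterError(f"max_gap must be >= 0, got {max_gap}")
    n = len(seq.frames)
    new_frames = [
        LandmarkFrame(f.frame_index, f.timestamp, dict(f.landmarks)) for f in seq.frames
    ]
    if n == 0 or max_gap == 0:
        return LandmarkSequence(new_frames, seq.nominal_rate, seq.visibility_floor)
    t = seq.timestamps
    keys = [(name, None) for name in UNSIDED_LANDMARKS] + [
        (name, side) for name in SIDED_LANDMARKS for side in SIDES
    ]
    for name, side in keys:
        present = np.zeros(n, dtype=bool)
        for i, frame in enumerate(seq.frames):
            lm = frame.get(name, side)
            present[i] = lm is not None and (
                lm.imputed or lm.visibility >= seq.visibility_floor
            )
        if present.all() or not present.any():
            continue
        obs = np.flatnonzero(present)
        for a, b in zip(obs[:-1], obs[1:]):
            gap = b - a - 1
            if gap == 0 or gap > max_gap:
                continue
            la = seq.frames[a].get(name, side)
            lb = seq.frames[b].get(name, side)
            for i in range(a + 1, b):
                w = (t[i] - t[a]) / (t[b] - t[a])
                depth = None
                if la.depth is not None and lb.depth is not None:
                    depth = (1 - w) * la.depth + w * lb.depth
                filled = Landmark(
                    name=name,
                    side=side,
                    x=(1 - w) * la.x + w * lb.x,
                    y=(1 - w) * la.y + w * lb.y,
                    visibility=min(la.visibility, lb.visibility),
                    depth=depth,
                    imputed=True,
                )
                new_frames[i].landmarks[(name, side)] = filled
    return LandmarkSequence(new_frames, seq.nominal_rate, seq.visibility_floor)
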