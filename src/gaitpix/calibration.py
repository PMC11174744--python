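"""Metric scale from a fiducial marker, and anthropometry from landmarks.

A square fiducial (ArUco-style) marker of known physical side length is
detected elsewhere; here its four pixel corners are consumed as data.  The
marker's pixel side — the mean of its four edge lengths, which is robust to
mild perspective — gives a cm-per-pixel ratio, and the median across
observations is robust to isolated detection glitches.

Anthropometric lengths (knee–heel, hip–ankle, ankle–toe, stature) are mean
per-frame Euclidean pixel distances scaled by that ratio, taken from a
static capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, MeasurementError, NonStaticCaptureError, ParameterError
from .landmark_io import SIDES, LandmarkSequence

MARKER_COLUMNS = [
    "frame_index",
    "c1x", "c1y", "c2x", "c2y", "c3x", "c3y", "c4x", "c4y",
    "side_cm",
]


@dataclass(frozen=True)
class MarkerObservation:
    """Four pixel corners of a square marker, in consistent winding order."""

    corners: np.ndarray  # shape (4, 2), pixels
    side_cm: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        corners = np.asarray(self.corners, dtype=float).reshape(4, 2)
        object.__setattr__(self, "corners", corners)
        if not self.side_cm > 0:
            raise CalibrationError(f"marker side_cm must be > 0, got {self.side_cm}")
        if len({tuple(c) for c in corners.tolist()}) != 4:
            raise CalibrationError("marker corners must be 4 distinct points")

    @property
    def edge_lengths_px(self) -> np.ndarray:
        rolled = np.roll(self.corners, -1, axis=0)
        return np.hypot(*(rolled - self.corners).T)

    @property
    def side_px(self) -> float:
        return float(self.edge_lengths_px.mean())


@dataclass(frozen=True)
class ScaleCalibration:
    """cm-per-pixel ratio with the spread of the observations behind it."""

    cm_per_px: float
    n_observations: int = 1
    dispersion: float = 0.0  # coefficient of variation of per-observation scales

    def __post_init__(self) -> None:
        if not self.cm_per_px > 0:
            raise CalibrationError(f"cm_per_px must be > 0, got {self.cm_per_px}")
        if self.dispersion < 0:
            raise CalibrationError("dispersion must be >= 0")


@dataclass(frozen=True)
class SegmentMeasurement:
    """Mean segment length with per-frame samples retained for resampling."""

    mean_cm: float
    samples_cm: np.ndarray


@dataclass(frozen=True)
class AnthropometricProfile:
    knee_to_heel_cm: float
    hip_to_ankle_cm: float
    ankle_to_toe_cm: float
    height_cm: float
    n_frames_used: int

    def __post_init__(self) -> None:
        for name in ("knee_to_heel_cm", "hip_to_ankle_cm", "ankle_to_toe_cm", "height_cm"):
            if not getattr(self, name) > 0:
                raise MeasurementError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.height_cm > self.hip_to_ankle_cm:
            raise MeasurementError("height must exceed hip-to-ankle length")

    def as_dict(self) -> dict[str, float]:
        return {
            "knee_to_heel_cm": self.knee_to_heel_cm,
            "hip_to_ankle_cm": self.hip_to_ankle_cm,
            "ankle_to_toe_cm": self.ankle_to_toe_cm,
            "height_cm": self.height_cm,
        }


def scale_from_marker(
    obs: MarkerObservation | Sequence[MarkerObservation],
) -> ScaleCalibration:
    """Median cm-per-pixel scale over one or more marker observations."""
    observations = [obs] if isinstance(obs, MarkerObservation) else list(obs)
    if not observations:
        raise CalibrationError("at least one marker observation required")
    scales = []
    for o in observations:
        if np.any(o.edge_lengths_px < 1.0):
            raise CalibrationError(
                f"degenerate marker at frame {o.frame_index}: edge shorter than 1 px"
            )
        scales.append(o.side_cm / o.side_px)
    scales = np.asarray(scales)
    cm_per_px = float(np.median(scales))
    dispersion = float(scales.std() / scales.mean()) if len(scales) > 1 else 0.0
    return ScaleCalibration(
        cm_per_px=cm_per_px, n_observations=len(scales), dispersion=dispersion
    )


def read_marker_csv(path) -> list[MarkerObservation]:
    df = pd.read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise CalibrationError(f"{path}: missing required columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        corners = np.array(
            [[row.c1x, row.c1y], [row.c2x, row.c2y], [row.c3x, row.c3y], [row.c4x, row.c4y]]
        )
        out.append(
            MarkerObservation(
                corners=corners, side_cm=float(row.side_cm), frame_index=int(row.frame_index)
            )
        )
    return out


def write_marker_csv(observations: Sequence[MarkerObservation], path) -> None:
    rows = []
    for o in observations:
        c = o.corners
        rows.append(
            {
                "frame_index": o.frame_index,
                "c1x": c[0, 0], "c1y": c[0, 1],
                "c2x": c[1, 0], "c2y": c[1, 1],
                "c3x": c[2, 0], "c3y": c[2, 1],
                "c4x": c[3, 0], "c4y": c[3, 1],
                "side_cm": o.side_cm,
            }
        )
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, index=False)


def segment_length(
    seq: LandmarkSequence,
    from_landmark: tuple[str, Optional[str]],
    to_landmark: tuple[str, Optional[str]],
    scale: ScaleCalibration,
) -> SegmentMeasurement:
    """Mean metric distance between two landmarks over co-observed frames."""
    _, x1, y1 = seq.track(*from_landmark)
    _, x2, y2 = seq.track(*to_landmark)
    d = np.hypot(x2 - x1, y2 - y1) * scale.cm_per_px
    samples = d[np.isfinite(d)]
    if samples.size == 0:
        raise MeasurementError(
            f"landmarks {from_landmark} and {to_landmark} never co-observed"
        )
    return SegmentMeasurement(mean_cm=float(samples.mean()), samples_cm=samples)


#: Static-capture gate: median per-frame landmark displacement (px/frame).
DEFAULT_STATIC_THRESHOLD_PX = 2.0


def median_displacement_px(seq: LandmarkSequence) -> float:
    """Median per-frame displacement across all landmark tracks, pixels."""
    disps = []
    from .landmark_io import SIDED_LANDMARKS, UNSIDED_LANDMARKS

    keys = [(n, None) for n in UNSIDED_LANDMARKS] + [
        (n, s) for n in SIDED_LANDMARKS for s in SIDES
    ]
    for name, side in keys:
        _, x, y = seq.track(name, side)
        dx, dy = np.diff(x), np.diff(y)
        step = np.hypot(dx, dy)
        disps.append(step[np.isfinite(step)])
    all_steps = np.concatenate(disps) if disps else np.array([])
    if all_steps.size == 0:
        return 0.0
    return float(np.median(all_steps))


def anthropometric_profile(
    seq: LandmarkSequence,
    scale: ScaleCalibration,
    side: str = "left",
    static_threshold_px: float = DEFAULT_STATIC_THRESHOLD_PX,
    crown_correction: float = 1.0,
) -> AnthropometricProfile:
    """The four anthropometric measurements from a static capture.

    Height is the pixel distance from the highest head landmark to the lowest
    foot landmark (heel or toe, either side) times the scale, optionally
    times a crown correction factor for skeletons whose top landmark is not
    the crown of the head (default 1.0, i.e. no correction).
    """
    motion = median_displacement_px(seq)
    if motion > static_threshold_px:
        raise NonStaticCaptureError(
            f"median landmark displacement {motion:.2f} px/frame exceeds the "
            f"static-capture threshold {static_threshold_px} px/frame"
        )
    knee_heel = segment_length(seq, ("knee", side), ("heel", side), scale)
    hip_ankle = segment_length(seq, ("hip", side), ("ankle", side), scale)
    ankle_toe = segment_length(seq, ("ankle", side), ("toe", side), scale)

    head_ys = []
    for name in ("head_top", "nose"):
        _, _, y = seq.track(name, None)
        head_ys.append(y)
    foot_ys = []
    for name in ("heel", "toe"):
        for s in SIDES:
            _, _, y = seq.track(name, s)
            foot_ys.append(y)
    head_y = np.nanmin(np.vstack(head_ys), axis=0)  # y-down: min y = highest
    foot_y = np.nanmax(np.vstack(foot_ys), axis=0)
    heights = (foot_y - head_y) * scale.cm_per_px * crown_correction
    heights = heights[np.isfinite(heights)]
    if heights.size == 0:
        raise MeasurementError("head and foot landmarks never co-observed")
    n_used = int(
        min(
            knee_heel.samples_cm.size,
            hip_ankle.samples_cm.size,
            ankle_toe.samples_cm.size,
            heights.size,
        )
    )
    return AnthropometricProfile(
        knee_to_heel_cm=knee_heel.mean_cm,
        hip_to_ankle_cm=hip_ankle.mean_cm,
        ankle_to_toe_cm=ankle_toe.mean_cm,
        height_cm=float(heights.mean()),
        n_frames_used=n_used,
    )


def average_samples(samples: Sequence[float]) -> float:
    """Arithmetic mean of repeated measurements at full precision.

    Samples are decimal-printed measurements, so the mean is accumulated in
    decimal on their shortest decimal representations: a mean that is
    exactly a reporting tie (e.g. 25.815) then reaches the rounding layer
    as a tie instead of drifting an ulp under binary accumulation.
    """
    samples = [float(s) for s in samples]
    if not samples:
        raise ParameterError("average_samples requires at least one sample")
    total = sum(Decimal(repr(s)) for s in samples)
    return float(total / len(samples))


def round_report(x: float, decimals: int = 2, mode: str = "round") -> float:
    """Round a value for table reporting.

    ``mode='round'`` applies decimal round-half-even on the value's shortest
    decimal representation (so 91.025 → 91.02, 25.815 → 25.82, immune to
    binary-float tie artifacts); ``mode='truncate'`` drops excess digits.
    """
    if mode not in ("round", "truncate"):
        raise ParameterError(f"unknown rounding mode {mode!r}")
    q = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_EVEN if mode == "round" else ROUND_DOWN
    return float(Decimal(repr(float(x))).quantize(q, rounding=rounding))
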