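"""Gait-phase segmentation, pedometry, step length and traveled distance.

The gait cycle is segmented into the six canonical sub-phases — heel strike,
foot flat, midstance, heel off, initial swing, mid swing — with a
sequential-flag state machine: a phase event is emitted only if the previous
phase of the cycle was the last one emitted for that side, which prevents
step skipping and double counting.

Ground contact is decided per landmark (heel, toe) with hysteresis
thresholds normalized by the leg length in pixels, so behavior does not
depend on camera distance: a landmark engages contact when it comes within
``contact_epsilon`` leg lengths of the ground line and releases only beyond
``release_epsilon`` leg lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import ScaleCalibration
from .errors import EstimationError, ParameterError
from .landmark_io import SIDES, LandmarkSequence

#: Canonical cyclic order of gait phases.
PHASES = (
    "heel_strike",
    "foot_flat",
    "midstance",
    "heel_off",
    "initial_swing",
    "mid_swing",
)

_PREV = {PHASES[i]: PHASES[i - 1] for i in range(len(PHASES))}


@dataclass(frozen=True)
class GaitEvent:
    phase: str
    side: str
    frame_index: int
    timestamp: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ParameterError(f"unknown gait phase {self.phase!r}")
        if self.side not in SIDES:
            raise ParameterError(f"unknown side {self.side!r}")


@dataclass(frozen=True)
class GaitParams:
    """Thresholds for contact detection and event debouncing.

    contact_epsilon / release_epsilon are fractions of the leg length in
    pixels (hip-to-ankle); min_event_gap debounces repeats of the same phase
    on the same side; ground_quantile sets the heel-height quantile used for
    the ground line.
    """

    contact_epsilon: float = 0.05
    release_epsilon: float = 0.10
    min_event_gap: float = 0.2
    ground_quantile: float = 0.95

    def __post_init__(self) -> None:
        if not (self.release_epsilon > self.contact_epsilon > 0):
            raise ParameterError(
                "need release_epsilon > contact_epsilon > 0, got "
                f"{self.release_epsilon} / {self.contact_epsilon}"
            )
        if self.min_event_gap < 0:
            raise ParameterError("min_event_gap must be >= 0")
        if not 0 < self.ground_quantile <= 1:
            raise ParameterError("ground_quantile must be in (0, 1]")


@dataclass
class GaitSummary:
    step_count: int
    step_lengths_cm: list[float]
    mean_step_length_cm: float
    traveled_distance_m: float
    events: list[GaitEvent] = field(default_factory=list)
    cycles: list[list[GaitEvent]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.step_count < 0 or self.traveled_distance_m < 0:
            raise ParameterError("step_count and traveled distance must be >= 0")


def estimate_ground_line(
    seq: LandmarkSequence, quantile: float = 0.95, min_frames: int = 10
) -> float:
    """Ground y level (pixels) as a high quantile of observed heel heights.

    With y increasing downward, larger y is closer to the floor, so the
    chosen quantile of heel y values tracks the ground plane while staying
    robust to swing-phase excursions.
    """
    ys = []
    for side in SIDES:
        _, _, y = seq.track("heel", side)
        ys.append(y[np.isfinite(y)])
    heel_y = np.concatenate(ys) if ys else np.array([])
    if heel_y.size < min_frames:
        raise EstimationError(
            f"need heel observations on >= {min_frames} frames, got {heel_y.size}"
        )
    return float(np.quantile(heel_y, quantile))


def _leg_length_px(seq: LandmarkSequence, side: str) -> float:
    _, hx, hy = seq.track("hip", side)
    _, ax, ay = seq.track("ankle", side)
    d = np.hypot(ax - hx, ay - hy)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise EstimationError(f"hip and ankle never co-observed on side {side!r}")
    return float(np.median(d))


class _ContactState:
    """Hysteresis contact detector for one landmark."""

    def __init__(self, contact_px: float, release_px: float):
        self.contact_px = contact_px
        self.release_px = release_px
        self.down: Optional[bool] = None

    def update(self, height_px: float) -> Optional[str]:
        """Feed the landmark's height above ground; report a transition."""
        if not np.isfinite(height_px):
            return None
        if self.down is None:
            self.down = height_px <= 0.5 * (self.contact_px + self.release_px)
            return None
        if self.down and height_px >= self.release_px:
            self.down = False
            return "up"
        if not self.down and height_px <= self.contact_px:
            self.down = True
            return "down"
        return None


def detect_gait_phases(
    seq: LandmarkSequence, params: GaitParams = GaitParams()
) -> list[GaitEvent]:
    """Run the sequential-flag gait-phase state machine over a sequence.

    Per side, heel/toe contact transitions and ankle-crossing geometry drive
    the six phase events; each event requires the preceding phase in the
    cycle to have been the last one emitted for that side (the first event
    of a side is exempt, since a capture can start anywhere in the cycle).
    """
    n = len(seq)
    t = seq.timestamps
    ground_y = estimate_ground_line(seq, params.ground_quantile)

    tracks: dict[str, dict[str, np.ndarray]] = {}
    detectors: dict[str, dict[str, _ContactState]] = {}
    for side in SIDES:
        leg_px = _leg_length_px(seq, side)
        d = {}
        for name in ("heel", "toe", "ankle"):
            _, x, y = seq.track(name, side)
            d[f"{name}_x"], d[f"{name}_y"] = x, y
        tracks[side] = d
        detectors[side] = {
            name: _ContactState(
                params.contact_epsilon * leg_px, params.release_epsilon * leg_px
            )
            for name in ("heel", "toe")
        }

    events: list[GaitEvent] = []
    last_phase: dict[str, Optional[str]] = {s: None for s in SIDES}
    last_time: dict[tuple[str, str], float] = {}

    def emit(phase: str, side: str, i: int) -> None:
        if last_phase[side] is not None and last_phase[side] != _PREV[phase]:
            return
        key = (side, phase)
        if key in last_time and t[i] - last_time[key] < params.min_event_gap:
            return
        events.append(
            GaitEvent(
                phase=phase, side=side, frame_index=seq.frames[i].frame_index, timestamp=t[i]
            )
        )
        last_phase[side] = phase
        last_time[key] = t[i]

    other = {"left": "right", "right": "left"}
    dx_prev: dict[str, float] = {}
    for i in range(n):
        transitions = {}
        for side in SIDES:
            tr = tracks[side]
            transitions[side] = {
                name: detectors[side][name].update(ground_y - tr[f"{name}_y"][i])
                for name in ("heel", "toe")
            }
        for side in SIDES:
            tr, det = tracks[side], detectors[side]
            heel_tr, toe_tr = transitions[side]["heel"], transitions[side]["toe"]
            heel_down = bool(det["heel"].down)
            toe_down = bool(det["toe"].down)

            # ankle crossing relative to the contralateral ankle
            dx = tr["ankle_x"][i] - tracks[other[side]]["ankle_x"][i]
            crossed = False
            if np.isfinite(dx):
                prev = dx_prev.get(side)
                if prev is not None and np.sign(dx) != np.sign(prev) and dx != 0:
                    crossed = True
                dx_prev[side] = dx

            if heel_tr == "down" and not toe_down:
                emit("heel_strike", side, i)
            if toe_tr == "down" and heel_down:
                emit("foot_flat", side, i)
            if crossed and heel_down and toe_down:
                emit("midstance", side, i)
            if heel_tr == "up" and toe_down:
                emit("heel_off", side, i)
            if toe_tr == "up" and not heel_down:
                emit("initial_swing", side, i)
            if crossed and not heel_down and not toe_down:
                emit("mid_swing", side, i)
    return events


def count_steps(events: Sequence[GaitEvent]) -> int:
    """Validated heel strikes across both sides."""
    return sum(1 for e in events if e.phase == "heel_strike")


def step_lengths(
    seq: LandmarkSequence,
    events: Sequence[GaitEvent],
    scale: ScaleCalibration,
) -> list[float]:
    """Mid-foot-to-mid-foot horizontal distance at every foot-flat event, cm.

    The mid-foot is the midpoint of heel and toe.  Events at which either
    foot is not fully observed are skipped with a warning.
    """
    mids = {}
    for side in SIDES:
        _, hx, _ = seq.track("heel", side)
        _, tx, _ = seq.track("toe", side)
        mids[side] = 0.5 * (hx + tx)
    index_of = {f.frame_index: i for i, f in enumerate(seq.frames)}
    out = []
    for e in events:
        if e.phase != "foot_flat":
            continue
        i = index_of.get(e.frame_index)
        if i is None:
            continue
        sep = abs(mids["right"][i] - mids["left"][i])
        if not np.isfinite(sep):
            warnings.warn(
                f"foot-flat event at frame {e.frame_index}: contralateral foot "
                "not observed, step skipped",
                stacklevel=2,
            )
            continue
        out.append(float(sep * scale.cm_per_px))
    return out


def traveled_distance(
    step_lengths_cm: Sequence[float],
    step_count: int,
    mode: str = "count_times_mean",
) -> float:
    """Distance in meters from step lengths and the pedometer count.

    ``count_times_mean`` (treadmill: the subject stays in frame and steps are
    multiplied by the mean stride) or ``cumulative`` (overground: per-step
    lengths are summed).
    """
    lengths = [float(v) for v in step_lengths_cm]
    if mode == "cumulative":
        return float(sum(lengths)) / 100.0
    if mode == "count_times_mean":
        if not lengths:
            raise ParameterError("count_times_mean requires at least one step length")
        return step_count * float(np.mean(lengths)) / 100.0
    raise ParameterError(f"unknown distance mode {mode!r}")


def extract_cycles(events: Sequence[GaitEvent], side: str) -> list[list[GaitEvent]]:
    """Complete six-phase cycles (heel strike → mid swing) for one side."""
    seq = [e for e in events if e.side == side]
    cycles, current = [], []
    for e in seq:
        if e.phase == "heel_strike":
            current = [e]
        elif current and e.phase == PHASES[len(current)]:
            current.append(e)
            if len(current) == len(PHASES):
                cycles.append(current)
                current = []
        else:
            current = []
    return cycles


def summarize_gait(
    seq: LandmarkSequence,
    scale: ScaleCalibration,
    params: GaitParams = GaitParams(),
    distance_mode: str = "count_times_mean",
) -> GaitSummary:
    """End-to-end gait summary: events, pedometry, step length, distance."""
    events = detect_gait_phases(seq, params)
    n_steps = count_steps(events)
    lengths = step_lengths(seq, events, scale)
    mean_len = float(np.mean(lengths)) if lengths else float("nan")
    if lengths:
        distance = traveled_distance(lengths, n_steps, mode=distance_mode)
    else:
        distance = 0.0
    cycles = [c for side in SIDES for c in extract_cycles(events, side)]
    return GaitSummary(
        step_count=n_steps,
        step_lengths_cm=lengths,
        mean_step_length_cm=mean_len,
        traveled_distance_m=distance,
        events=events,
        cycles=cycles,
    )


def events_to_dataframe(events: Sequence[GaitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "timestamp_s": e.timestamp,
                "frame_index": e.frame_index,
                "side": e.side,
                "phase": e.phase,
            }
            for e in events
        ],
        columns=["timestamp_s", "frame_index", "side", "phase"],
    )
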