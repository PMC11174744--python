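"""Planar sagittal-plane gait simulator with full ground truth.

The simulator stands in for the camera + pose-estimator stack: it emits the
same landmark streams, fiducial-marker corner observations and reference
angle streams the live pipeline consumes, together with the ground truth
(angles, events, step lengths, segment lengths) needed to score every other
module without hardware.

Model
-----
Each leg follows a periodic cycle of period ``T`` (two steps): stance on the
treadmill belt (heel rocker → flat foot → toe rocker) followed by a swing
that returns the foot to a fixed strike position.  Foot trajectories are
constructed directly — heel and toe anchored to the belt during their
respective rockers, smoothstep-interpolated lift during swing — and the knee
is placed by two-link inverse kinematics (thigh, shank) from the hip, which
keeps the planted step length and the ground-contact constraint exact by
construction.  The legs are phase-shifted by half a cycle.

In treadmill mode the pelvis is horizontally fixed and the belt carries the
stance foot backwards; in overground mode the whole construction is
translated forward at the belt speed, which leaves the stance foot
stationary on the floor.

World coordinates are centimeters (x forward, y up, ground at y = 0) and are
projected to image pixels (origin top-left, y down) with a uniform
cm-per-pixel scale; noise is isotropic per-landmark Gaussian in pixels plus
Bernoulli dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import kinematics
from .calibration import MarkerObservation
from .errors import ConfigurationError
from .gait_events import GaitEvent
from .landmark_io import (
    Landmark,
    LandmarkFrame,
    LandmarkSequence,
    ReferenceAngleSeries,
    SIDES,
)

# cycle sub-phase boundaries, as fractions of the per-leg cycle
_R1 = 0.10  # heel rocker: landing rotation ends, foot fully flat
_R2 = 0.62  # toe rocker begins: heel starts to rise (> 0.5 + _R1, so the
# two feet are simultaneously flat for a nonzero double-support window)
_D_STANCE = 0.70  # toe-off: swing begins
_ALPHA0_DEG = 20.0  # foot dorsiflexion at heel strike
_BETA1_DEG = 35.0  # foot plantarflexion at toe-off
_LIFT_CM = 10.0  # additional heel lift at mid swing
_U0 = 0.30  # right-leg cycle phase at t = 0 (left is offset by 0.5)
_EXTENSION_RATIO = 0.999  # max leg extension as a fraction of thigh+shank

# pixel-frame layout (480p-style view)
_PX_CENTER_X = 320.0
_PX_GROUND_Y = 440.0

# ankle position in the foot frame (heel at origin, toe on +x when flat), cm
_ANKLE_OFFSET = (4.0, 7.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic capture.

    Defaults emulate the validation protocol: 25 fps capture of a subject
    walking on a treadmill at ~1.0 km/h (cadence 38 steps/min with 44 cm
    steps), segment lengths of a ~1.70 m adult, and a 10 cm square fiducial
    marker.
    """

    fps: float = 25.0
    n_steps: int = 30
    step_length_cm: float = 44.0
    cadence_spm: float = 38.0
    thigh_cm: float = 45.0
    shank_cm: float = 46.0
    foot_cm: float = 25.0
    subject_height_cm: float = 170.0
    cm_per_px_true: float = 0.4
    marker_side_cm: float = 10.0
    noise_sigma_px: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    treadmill: bool = True
    static_duration_s: float = 10.0

    def __post_init__(self) -> None:
        positive = (
            "fps", "step_length_cm", "cadence_spm", "thigh_cm", "shank_cm",
            "foot_cm", "subject_height_cm", "cm_per_px_true", "marker_side_cm",
            "static_duration_s",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.noise_sigma_px < 0:
            raise ConfigurationError("noise_sigma_px must be >= 0")
        if not self.subject_height_cm > self.thigh_cm + self.shank_cm:
            raise ConfigurationError("subject height must exceed leg length")

    @property
    def step_period_s(self) -> float:
        return 60.0 / self.cadence_spm

    @property
    def cycle_period_s(self) -> float:
        return 2.0 * self.step_period_s


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    config: SimulationConfig
    angle_series: dict  # (joint, side) -> kinematics.JointAngleSeries
    events: list[GaitEvent]
    step_count: int
    step_lengths_cm: list[float]
    segment_lengths_cm: dict  # knee_to_heel_cm, hip_to_ankle_cm, ankle_to_toe_cm, height_cm
    ground_y_px: float
    noiseless: LandmarkSequence = field(repr=False, default=None)


def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _foot_pose(u: np.ndarray, L: float, f: float):
    """Heel position (cm) and foot pitch (rad) for cycle fractions ``u``.

    The foot pitch is the angle of the heel→toe vector above horizontal:
    positive at heel strike (toe up), zero when flat, negative during the
    toe rocker (heel up).
    """
    a0 = math.radians(_ALPHA0_DEG)
    b1 = math.radians(_BETA1_DEG)
    # strike position sits forward of the stance midpoint so the leg is
    # most extended exactly at touchdown (heel strike), as in upright gait
    a = _R2 * L
    target_x = a + (f / 2.0) * (1.0 - math.cos(a0))

    heel_x = np.empty_like(u)
    heel_y = np.empty_like(u)
    phi = np.empty_like(u)

    m1 = u < _R1
    m2 = (u >= _R1) & (u < _R2)
    m3 = (u >= _R2) & (u < _D_STANCE)
    m4 = u >= _D_STANCE

    # heel rocker: heel rolls on the belt while the foot rotates flat; the
    # small forward slide keeps the foot *midpoint* belt-anchored, which is
    # what plants the mid-foot step length exactly
    s = u[m1] / _R1
    p = a0 * (1.0 - _smoothstep(s))
    phi[m1] = p
    heel_x[m1] = a - 2.0 * L * u[m1] + (f / 2.0) * (1.0 - np.cos(p))
    heel_y[m1] = 0.0

    # flat foot on the belt
    phi[m2] = 0.0
    heel_x[m2] = a - 2.0 * L * u[m2]
    heel_y[m2] = 0.0

    # toe rocker: toe anchored to the belt, heel pivots up
    s = (u[m3] - _R2) / (_D_STANCE - _R2)
    p = -b1 * _smoothstep(s)
    phi[m3] = p
    toe_x = a - 2.0 * L * u[m3] + f
    heel_x[m3] = toe_x - f * np.cos(p)
    heel_y[m3] = -f * np.sin(p)

    # swing: smoothstep return to the strike position with a lift bump
    s = (u[m4] - _D_STANCE) / (1.0 - _D_STANCE)
    S = _smoothstep(s)
    x0 = a - 2.0 * L * _D_STANCE + f - f * math.cos(b1)
    y0 = f * math.sin(b1)
    phi[m4] = -b1 + (a0 + b1) * S
    heel_x[m4] = x0 + (target_x - x0) * S
    heel_y[m4] = y0 * (1.0 - S) + _LIFT_CM * np.sin(np.pi * s) ** 2

    return heel_x, heel_y, phi


def _leg_world(u: np.ndarray, cfg: SimulationConfig):
    """heel, toe, ankle world positions (cm) for one leg."""
    heel_x, heel_y, phi = _foot_pose(u, cfg.step_length_cm, cfg.foot_cm)
    ex, ez = _ANKLE_OFFSET
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    toe_x = heel_x + cfg.foot_cm * cos_p
    toe_y = heel_y + cfg.foot_cm * sin_p
    ankle_x = heel_x + ex * cos_p - ez * sin_p
    ankle_y = heel_y + ex * sin_p + ez * cos_p
    return (heel_x, heel_y), (toe_x, toe_y), (ankle_x, ankle_y)


def _solve_hip_height(ankle_sets, cfg: SimulationConfig) -> float:
    """Largest hip height keeping both legs within the extension budget."""
    reach = _EXTENSION_RATIO * (cfg.thigh_cm + cfg.shank_cm)
    best = np.inf
    for ankle_x, ankle_y in ankle_sets:
        slack = reach**2 - ankle_x**2
        if np.any(slack < 0):
            raise ConfigurationError(
                f"step length {cfg.step_length_cm} cm is kinematically infeasible "
                f"for thigh {cfg.thigh_cm} + shank {cfg.shank_cm} cm"
            )
        best = min(best, float(np.min(ankle_y + np.sqrt(slack))))
    return best


def _knee_positions(hip_x, hip_y, ankle_x, ankle_y, cfg: SimulationConfig):
    """Two-link IK: knee on the anterior side of the hip-ankle chord."""
    th, sh = cfg.thigh_cm, cfg.shank_cm
    dx = ankle_x - hip_x
    dy = ankle_y - hip_y
    d = np.hypot(dx, dy)
    along = (th**2 - sh**2 + d**2) / (2.0 * d)
    perp = np.sqrt(np.maximum(th**2 - along**2, 0.0))
    # unit normal chosen so the knee falls forward (+x) of the chord
    nx, ny = -dy / d, dx / d
    knee_x = hip_x + along * dx / d + perp * nx
    knee_y = hip_y + along * dy / d + perp * ny
    return knee_x, knee_y


def _to_px(x_cm, y_cm, cfg: SimulationConfig):
    s = cfg.cm_per_px_true
    return _PX_CENTER_X + np.asarray(x_cm) / s, _PX_GROUND_Y - np.asarray(y_cm) / s


def _build_sequence(t, world, cfg: SimulationConfig) -> LandmarkSequence:
    """Assemble a noiseless LandmarkSequence from world-cm landmark arrays."""
    frames = []
    px = {key: _to_px(x, y, cfg) for key, (x, y) in world.items()}
    for i, ti in enumerate(t):
        frame = LandmarkFrame(frame_index=i, timestamp=float(ti))
        for (name, side), (xs, ys) in px.items():
            frame.add(
                Landmark(name=name, side=side, x=float(xs[i]), y=float(ys[i]), visibility=1.0)
            )
        frames.append(frame)
    return LandmarkSequence(frames=frames, nominal_rate=cfg.fps)


def _apply_noise(
    seq: LandmarkSequence, cfg: SimulationConfig, rng: np.random.Generator
) -> LandmarkSequence:
    if cfg.noise_sigma_px == 0 and cfg.dropout_rate == 0:
        return seq
    frames = []
    for f in seq.frames:
        frame = LandmarkFrame(frame_index=f.frame_index, timestamp=f.timestamp)
        for lm in f.landmarks.values():
            if cfg.dropout_rate > 0 and rng.random() < cfg.dropout_rate:
                continue
            x, y = lm.x, lm.y
            if cfg.noise_sigma_px > 0:
                x += rng.normal(0.0, cfg.noise_sigma_px)
                y += rng.normal(0.0, cfg.noise_sigma_px)
            frame.add(replace(lm, x=x, y=y))
        frames.append(frame)
    return LandmarkSequence(frames=frames, nominal_rate=cfg.fps)


def _marker_observations(
    t, cfg: SimulationConfig, rng: np.random.Generator, pelvis_x
) -> list[MarkerObservation]:
    """Square marker on the subject's arm, corners consistent with the scale."""
    hs = cfg.marker_side_cm / 2.0
    out = []
    for i, _ in enumerate(t):
        cx, cy = pelvis_x[i] + 5.0, 120.0
        corners_cm = [
            (cx - hs, cy + hs), (cx + hs, cy + hs), (cx + hs, cy - hs), (cx - hs, cy - hs)
        ]
        corners_px = np.array([_to_px(x, y, cfg) for x, y in corners_cm], dtype=float)
        if cfg.noise_sigma_px > 0:
            corners_px = corners_px + rng.normal(0.0, cfg.noise_sigma_px, corners_px.shape)
        out.append(
            MarkerObservation(corners=corners_px, side_cm=cfg.marker_side_cm, frame_index=i)
        )
    return out


def _static_segment_truth(cfg: SimulationConfig) -> dict:
    ex, ez = _ANKLE_OFFSET
    return {
        "knee_to_heel_cm": math.hypot(ex, ez + cfg.shank_cm),
        "hip_to_ankle_cm": cfg.thigh_cm + cfg.shank_cm,
        "ankle_to_toe_cm": math.hypot(cfg.foot_cm - ex, ez),
        "height_cm": cfg.subject_height_cm,
    }


def _truth_angles(noiseless: LandmarkSequence) -> dict:
    out = {}
    for side in SIDES:
        out[("knee", side)] = kinematics.knee_angle_series(noiseless, side)
        out[("ankle", side)] = kinematics.ankle_angle_series(noiseless, side)
    return out


def _truth_events(t, u_by_side, ankle_x_by_side, cfg: SimulationConfig) -> list[GaitEvent]:
    """Analytic phase-boundary times, reported at the nearest frame."""
    T = cfg.cycle_period_s
    t_end = float(t[-1])
    events = []

    def add(phase: str, side: str, time: float) -> None:
        if not 0.0 <= time <= t_end:
            return
        idx = int(np.clip(round(time * cfg.fps), 0, len(t) - 1))
        events.append(GaitEvent(phase=phase, side=side, frame_index=idx, timestamp=float(t[idx])))

    phase_u = {
        "heel_strike": 1.0,
        "foot_flat": _R1,
        "heel_off": _R2,
        "initial_swing": _D_STANCE,
    }
    offsets = {"right": _U0, "left": _U0 + 0.5}
    for side, u0 in offsets.items():
        for phase, u_star in phase_u.items():
            k = math.floor(u0 - u_star)
            while True:
                time = (u_star - u0 + k) * T
                if time > t_end:
                    break
                add(phase, side, time)
                k += 1

    # crossings of the two ankles give midstance (stance leg) / mid swing
    # (swing leg); locate them on the sampled noiseless trajectories
    dx = ankle_x_by_side["right"] - ankle_x_by_side["left"]
    sign = np.sign(dx)
    crossings = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    for i in crossings:
        for side in SIDES:
            u = u_by_side[side][i]
            phase = "midstance" if u < _D_STANCE else "mid_swing"
            add(phase, side, float(t[i]))
    events.sort(key=lambda e: (e.timestamp, e.phase))
    return events


def simulate_gait(config: SimulationConfig = SimulationConfig()):
    """Simulate a walk; returns (sequence, marker observations, ground truth).

    The capture window is sized so that exactly ``config.n_steps`` heel
    strikes (both feet pooled) fall inside it, with margins to the window
    edges.  Identical config + seed yields bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tau = cfg.step_period_s
    T = cfg.cycle_period_s
    t_end = (cfg.n_steps + 0.2) * tau
    n_frames = int(math.floor(t_end * cfg.fps)) + 1
    t = np.arange(n_frames) / cfg.fps

    u = {"right": (t / T + _U0) % 1.0, "left": (t / T + _U0 + 0.5) % 1.0}
    legs = {side: _leg_world(u[side], cfg) for side in SIDES}

    hip_y = _solve_hip_height([legs[s][2] for s in SIDES], cfg)
    if cfg.treadmill:
        pelvis_x = np.zeros_like(t)
    else:
        belt_speed = 2.0 * cfg.step_length_cm / T
        pelvis_x = belt_speed * t

    world = {}
    ankle_x_by_side = {}
    for side in SIDES:
        (hx, hy), (tx, ty), (ax, ay) = legs[side]
        hx, tx, ax = hx + pelvis_x, tx + pelvis_x, ax + pelvis_x
        kx, ky = _knee_positions(pelvis_x, hip_y, ax, ay, cfg)
        world[("heel", side)] = (hx, hy)
        world[("toe", side)] = (tx, ty)
        world[("ankle", side)] = (ax, ay)
        world[("knee", side)] = (kx, ky)
        world[("hip", side)] = (pelvis_x, np.full_like(t, hip_y))
        ankle_x_by_side[side] = ax - pelvis_x
    world[("head_top", None)] = (pelvis_x, np.full_like(t, cfg.subject_height_cm))
    world[("nose", None)] = (pelvis_x + 8.0, np.full_like(t, cfg.subject_height_cm - 10.0))

    noiseless = _build_sequence(t, world, cfg)
    observed = _apply_noise(noiseless, cfg, rng)
    markers = _marker_observations(t, cfg, rng, pelvis_x)

    truth = GroundTruth(
        config=cfg,
        angle_series=_truth_angles(noiseless),
        events=_truth_events(t, u, ankle_x_by_side, cfg),
        step_count=cfg.n_steps,
        step_lengths_cm=[cfg.step_length_cm] * cfg.n_steps,
        segment_lengths_cm=_static_segment_truth(cfg),
        ground_y_px=_PX_GROUND_Y,
        noiseless=noiseless,
    )
    return observed, markers, truth


def simulate_static_pose(config: SimulationConfig = SimulationConfig()):
    """Standing subject in the sagittal plane (anthropometry capture).

    Legs are straight and the feet flat, so the true segment lengths follow
    directly from the configured geometry; only jitter noise and dropouts
    perturb the landmarks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.static_duration_s * cfg.fps))
    t = np.arange(n_frames) / cfg.fps
    ex, ez = _ANKLE_OFFSET
    const = lambda v: np.full_like(t, float(v))

    world = {}
    for side in SIDES:
        world[("heel", side)] = (const(0.0), const(0.0))
        world[("toe", side)] = (const(cfg.foot_cm), const(0.0))
        world[("ankle", side)] = (const(ex), const(ez))
        world[("knee", side)] = (const(ex), const(ez + cfg.shank_cm))
        world[("hip", side)] = (const(ex), const(ez + cfg.shank_cm + cfg.thigh_cm))
    world[("head_top", None)] = (const(ex), const(cfg.subject_height_cm))
    world[("nose", None)] = (const(ex + 8.0), const(cfg.subject_height_cm - 10.0))

    noiseless = _build_sequence(t, world, cfg)
    observed = _apply_noise(noiseless, cfg, rng)
    markers = _marker_observations(t, cfg, rng, np.zeros_like(t))

    truth = GroundTruth(
        config=cfg,
        angle_series=_truth_angles(noiseless),
        events=[],
        step_count=0,
        step_lengths_cm=[],
        segment_lengths_cm=_static_segment_truth(cfg),
        ground_y_px=_PX_GROUND_Y,
        noiseless=noiseless,
    )
    return observed, markers, truth


def simulate_reference_stream(
    truth: GroundTruth,
    rate: float = 60.0,
    noise_deg: float = 0.0,
    joint: str = "knee",
    side: str = "right",
    seed: Optional[int] = None,
) -> ReferenceAngleSeries:
    """Emulated MEMS-IMU angle stream: resampled truth plus Gaussian noise."""
    if rate <= 0:
        raise ConfigurationError("rate must be > 0")
    series = truth.angle_series[(joint, side)]
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    n = int(math.floor((t1 - t0) * rate)) + 1
    tb = t0 + np.arange(n) / rate
    resampled = kinematics.resample_to(series, tb)
    angles = resampled.angles.copy()
    if noise_deg > 0:
        rng = np.random.default_rng(truth.config.seed if seed is None else seed)
        angles = angles + rng.normal(0.0, noise_deg, angles.shape)
    angles = np.clip(angles, 0.0, 180.0)
    return ReferenceAngleSeries(
        timestamps=tb, angles=angles, joint=joint, source_label="MEMS"
    )
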