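"""Gait-phase state machine, pedometry, step length and traveled distance."""

import numpy as np
import pytest

from gaitpix.calibration import ScaleCalibration
from gaitpix.errors import EstimationError, ParameterError
from gaitpix.gait_events import (
    PHASES,
    GaitEvent,
    GaitParams,
    count_steps,
    detect_gait_phases,
    estimate_ground_line,
    extract_cycles,
    step_lengths,
    summarize_gait,
    traveled_distance,
)
from gaitpix.landmark_io import Landmark, LandmarkFrame, LandmarkSequence
from gaitpix.synthetic_gait import SimulationConfig, simulate_gait, simulate_static_pose

from conftest import make_track_sequence


def assert_canonical_order(events, side):
    """The per-side phase sequence must be a contiguous walk around the cycle."""
    phases = [e.phase for e in events if e.side == side]
    assert phases, f"no events for side {side}"
    for prev, cur in zip(phases, phases[1:]):
        assert PHASES[(PHASES.index(prev) + 1) % 6] == cur, (
            f"phase {cur} does not follow {prev} on side {side}"
        )


class TestGroundLine:
    def test_constant_heels(self):
        seq = make_track_sequence([(100, 400)] * 12, name="heel", side="left")
        assert estimate_ground_line(seq) == pytest.approx(400.0)

    def test_quantile_one_is_max(self):
        ys = [400, 402, 450] * 4
        seq = make_track_sequence([(0, y) for y in ys], name="heel", side="left")
        assert estimate_ground_line(seq, quantile=1.0) == pytest.approx(450.0)

    def test_insufficient_frames(self):
        seq = make_track_sequence([(0, 400)] * 5, name="heel", side="left")
        with pytest.raises(EstimationError):
            estimate_ground_line(seq)

    def test_simulated_ground_plane_recovered(self, short_walk):
        seq, _, truth = short_walk
        assert abs(estimate_ground_line(seq) - truth.ground_y_px) <= 2.0


class TestGaitParams:
    def test_hysteresis_ordering_enforced(self):
        with pytest.raises(ParameterError):
            GaitParams(contact_epsilon=0.1, release_epsilon=0.05)
        with pytest.raises(ParameterError):
            GaitParams(min_event_gap=-1)


class TestPhaseDetection:
    def test_static_standing_emits_no_events(self, static_capture):
        seq, _, _ = static_capture
        assert detect_gait_phases(seq) == []

    def test_two_full_cycles_each_leg_all_six_phases(self, short_walk):
        """Noiseless walk: each leg shows the six phases in canonical order,
        at least twice (the phase-identification grid on synthetic data)."""
        seq, _, _ = short_walk
        events = detect_gait_phases(seq)
        for side in ("left", "right"):
            assert_canonical_order(events, side)
            cycles = extract_cycles(events, side)
            assert len(cycles) >= 2
            for cycle in cycles:
                assert [e.phase for e in cycle] == list(PHASES)

    def test_heel_bounce_debounced(self, short_walk):
        """A spurious 1-frame heel re-contact must not add a heel strike."""
        seq, _, truth = short_walk
        base_events = detect_gait_phases(seq)
        base_count = count_steps(base_events)
        # lift the right heel clear of the ground for one frame shortly after
        # a detected heel strike, producing an up-down contact flicker
        strike = next(
            e for e in base_events if e.phase == "heel_strike" and e.side == "right"
        )
        i = strike.frame_index + 2
        lm = seq.frames[i].get("heel", "right")
        bounced_frames = [
            LandmarkFrame(f.frame_index, f.timestamp, dict(f.landmarks)) for f in seq.frames
        ]
        bounced_frames[i].landmarks[("heel", "right")] = Landmark(
            name="heel", side="right", x=lm.x, y=lm.y - 60.0, visibility=lm.visibility
        )
        bounced = LandmarkSequence(bounced_frames, seq.nominal_rate)
        assert count_steps(detect_gait_phases(bounced)) == base_count

    def test_sequential_flags_only_suppress(self, short_walk):
        """Validated heel strikes never exceed raw heel down-transitions."""
        seq, _, _ = short_walk
        params = GaitParams()
        events = detect_gait_phases(seq, params)
        ground = estimate_ground_line(seq, params.ground_quantile)
        raw_down = 0
        for side in ("left", "right"):
            from gaitpix.gait_events import _ContactState, _leg_length_px

            leg = _leg_length_px(seq, side)
            det = _ContactState(params.contact_epsilon * leg, params.release_epsilon * leg)
            _, _, y = seq.track("heel", side)
            raw_down += sum(det.update(ground - yi) == "down" for yi in y)
        assert count_steps(events) <= raw_down

    @pytest.mark.parametrize("n_steps", [10, 30])
    def test_noiseless_step_count_exact(self, n_steps):
        seq, _, truth = simulate_gait(SimulationConfig(n_steps=n_steps, seed=1))
        assert count_steps(detect_gait_phases(seq)) == truth.step_count == n_steps

    def test_noisy_step_count_median_error_zero(self):
        """Pedometer protocol with 2 px noise: median count error of 0 steps."""
        errors = []
        for seed in range(10):
            cfg = SimulationConfig(n_steps=10, noise_sigma_px=2.0, seed=seed)
            seq, _, truth = simulate_gait(cfg)
            errors.append(count_steps(detect_gait_phases(seq)) - truth.step_count)
        assert np.median(np.abs(errors)) == 0

    def test_phase_order_property_across_conditions(self):
        """Every simulated walk yields per-side phase sequences that walk the
        canonical cycle, regardless of speed, mode or moderate noise."""
        conditions = [
            dict(n_steps=5, cadence_spm=38),
            dict(n_steps=5, cadence_spm=52),  # ~1.5 km/h at 44 cm steps
            dict(n_steps=5, treadmill=False),
            dict(n_steps=5, noise_sigma_px=1.0, seed=4),
        ]
        for kw in conditions:
            seq, _, _ = simulate_gait(SimulationConfig(**kw))
            events = detect_gait_phases(seq)
            for side in ("left", "right"):
                assert_canonical_order(events, side)


class TestStepLengthAndDistance:
    def test_direct_product_oracle(self):
        frames = []
        for i in range(2):
            f = LandmarkFrame(frame_index=i, timestamp=i / 25)
            for side, x in (("left", 100.0), ("right", 400.0)):
                f.add(Landmark(name="heel", side=side, x=x - 50, y=400.0))
                f.add(Landmark(name="toe", side=side, x=x + 50, y=400.0))
            frames.append(f)
        seq = LandmarkSequence(frames=frames)
        events = [GaitEvent(phase="foot_flat", side="left", frame_index=0, timestamp=0.0)]
        lengths = step_lengths(seq, events, ScaleCalibration(0.1))
        assert lengths == [pytest.approx(30.0)]  # 300 px x 0.1 cm/px

    def test_noiseless_simulated_steps_all_within_tenth_cm(self, walk_30):
        seq, markers, truth = walk_30
        from gaitpix.calibration import scale_from_marker

        events = detect_gait_phases(seq)
        lengths = step_lengths(seq, events, scale_from_marker(markers))
        assert lengths
        assert np.max(np.abs(np.array(lengths) - truth.config.step_length_cm)) < 0.1

    def test_missing_contralateral_foot_skipped_with_warning(self):
        seq = make_track_sequence([(100, 400)] * 3, name="heel", side="left")
        for f in seq.frames:
            f.add(Landmark(name="toe", side="left", x=150.0, y=400.0))
        events = [GaitEvent(phase="foot_flat", side="left", frame_index=1, timestamp=0.04)]
        with pytest.warns(UserWarning, match="contralateral"):
            lengths = step_lengths(seq, events, ScaleCalibration(0.1))
        assert lengths == []

    @pytest.mark.parametrize(
        "lengths,count,mode,expected",
        [
            ([44.0] * 3, 90, "count_times_mean", 39.60),  # treadmill reference distance
            ([], 0, "cumulative", 0.0),
            ([50, 50, 40], 3, "cumulative", 1.40),
        ],
    )
    def test_traveled_distance(self, lengths, count, mode, expected):
        assert traveled_distance(lengths, count, mode) == pytest.approx(expected)

    def test_count_times_mean_requires_lengths(self):
        with pytest.raises(ParameterError):
            traveled_distance([], 10, "count_times_mean")

    def test_summary_consistency(self, walk_30):
        seq, markers, truth = walk_30
        from gaitpix.calibration import scale_from_marker

        summary = summarize_gait(seq, scale_from_marker(markers))
        assert summary.step_count == truth.step_count
        assert summary.step_count == count_steps(summary.events)
        assert summary.mean_step_length_cm == pytest.approx(44.0, abs=0.01)
        assert summary.traveled_distance_m == pytest.approx(30 * 0.44, abs=0.01)
        assert len(summary.cycles) >= 2
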