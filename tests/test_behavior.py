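"""Behavioral metrics: zones, preference, eye use, activity, symmetry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintkit import (
    ArenaGeometry,
    GazeClass,
    GazeThresholds,
    KeypointTable,
    activity,
    analyze_sessions,
    assign_zone,
    assign_zones,
    classify_gaze,
    classify_gaze_frames,
    compile_schedule,
    first_choice,
    preference_index,
    summarize_occupancy,
)
from imprintkit.config import ExperimentConfig


class TestZones:
    @pytest.mark.parametrize(
        "x, zone", [(10.0, "left"), (45.0, "middle"), (80.0, "right"),
                    (0.0, "left"), (29.9, "left"), (30.0, "middle"),
                    (60.0, "middle"), (60.1, "right"), (90.0, "right")],
    )
    def test_thirds_of_the_default_arena(self, x, zone, geometry):
        assert assign_zone(x, geometry) == zone

    def test_out_of_arena_position_clamped_with_warning(self, geometry):
        with pytest.warns(UserWarning, match="clamped"):
            assert assign_zone(-0.5, geometry) == "left"

    def test_vectorized_matches_scalar(self, geometry):
        xs = np.linspace(0, 90, 91)
        vec = assign_zones(xs, geometry)
        assert all(vec[i] == assign_zone(float(x), geometry) for i, x in enumerate(xs))

    def test_masked_frames_labelled(self, geometry):
        zones = assign_zones(np.array([10.0, np.nan, 80.0]), geometry)
        assert list(zones) == ["left", "masked", "right"]


def track_from_x(xs, fps=30.0, like=None):
    xs = np.asarray(xs, float)
    like = np.ones_like(xs) if like is None else np.asarray(like, float)
    arr = np.column_stack([xs, np.full_like(xs, 30.0), like])
    return KeypointTable.from_arrays({"head_center": arr}, fps=fps, units="cm")


class TestOccupancy:
    def test_constant_left_zone_time(self, geometry):
        table = track_from_x(np.full(120, 10.0), fps=30.0)
        occ = summarize_occupancy(table, geometry)
        assert occ["time_left_zone_s"] == pytest.approx(4.0)
        assert occ["time_middle_s"] == occ["time_right_zone_s"] == 0.0

    def test_times_match_per_frame_oracle(self, geometry):
        rng = np.random.default_rng(7)
        xs = rng.uniform(0, 90, size=500)
        table = track_from_x(xs, fps=25.0)
        occ = summarize_occupancy(table, geometry)
        # brute-force frame count per zone
        expected = {"left": 0, "middle": 0, "right": 0}
        for x in xs:
            if x < 30:
                expected["left"] += 1
            elif x > 60:
                expected["right"] += 1
            else:
                expected["middle"] += 1
        assert occ["time_left_zone_s"] == pytest.approx(expected["left"] / 25.0)
        assert occ["time_middle_s"] == pytest.approx(expected["middle"] / 25.0)
        assert occ["time_right_zone_s"] == pytest.approx(expected["right"] / 25.0)

    def test_zone_times_partition_the_window(self, geometry):
        rng = np.random.default_rng(11)
        like = (rng.uniform(0, 1, 300) > 0.2).astype(float)
        xs = rng.uniform(0, 90, 300)
        table = track_from_x(xs, fps=30.0, like=like)
        from imprintkit import clean_track

        occ = summarize_occupancy(clean_track(table, max_gap_frames=0), geometry)
        total = (occ["time_left_zone_s"] + occ["time_middle_s"]
                 + occ["time_right_zone_s"] + occ["time_masked_s"])
        assert total == pytest.approx(300 / 30.0, abs=1 / 30.0)

    def test_middle_dweller_makes_no_choice(self, geometry):
        table = track_from_x(np.full(100, 45.0))
        occ = summarize_occupancy(table, geometry)
        assert occ["first_choice"] == "none"
        pi = preference_index(occ["time_left_zone_s"], occ["time_right_zone_s"])
        assert math.isnan(pi)

    def test_first_choice_requires_entry(self):
        # starting inside a zone is not a choice; the first *transition*
        # into a stimulus zone is
        assert first_choice(np.array(["left", "left", "left"])) == "none"
        assert first_choice(np.array(["middle", "middle", "right"])) == "right"
        assert first_choice(np.array(["left", "middle", "right"])) == "right"
        assert first_choice(np.array(["middle", "masked", "left"])) == "left"

    def test_empty_window_rejected(self, geometry):
        table = track_from_x(np.full(10, 45.0))
        with pytest.raises(ValueError, match="overlap"):
            summarize_occupancy(table, geometry, start_s=100.0, end_s=200.0)


class TestPreferenceIndex:
    @pytest.mark.parametrize(
        "target, other, expected", [(60.0, 60.0, 0.5), (90.0, 30.0, 0.75),
                                    (30.0, 90.0, 0.25), (10.0, 0.0, 1.0)],
    )
    def test_reference_values(self, target, other, expected):
        assert preference_index(target, other) == pytest.approx(expected)

    def test_undefined_when_neither_zone_visited(self):
        assert math.isnan(preference_index(0.0, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(min_value=0.0, max_value=1e4),
        st.floats(min_value=0.0, max_value=1e4),
    )
    def test_bounds_and_complementarity(self, a, b):
        if a + b == 0:
            return
        p = preference_index(a, b)
        assert 0.0 <= p <= 1.0
        assert p + preference_index(b, a) == pytest.approx(1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            preference_index(-1.0, 5.0)


# head facing +x (toward the right screen); image coords, y down
BEAK = (2.0, 0.0)
LEFT_EYE = (0.0, -0.75)
RIGHT_EYE = (0.0, 0.75)


class TestGaze:
    def test_straight_ahead_is_binocular(self):
        assert classify_gaze(BEAK, LEFT_EYE, RIGHT_EYE, (10.0, 0.0)) == GazeClass.BINOCULAR

    def test_stimulus_90_degrees_left_is_left_monocular(self):
        # 90 deg to the animal's left = toward its left eye side
        stim = (0.0, -10.0)
        assert classify_gaze(BEAK, LEFT_EYE, RIGHT_EYE, stim) == GazeClass.LEFT_MONOCULAR

    def test_stimulus_90_degrees_right_is_right_monocular(self):
        stim = (0.0, 10.0)
        assert classify_gaze(BEAK, LEFT_EYE, RIGHT_EYE, stim) == GazeClass.RIGHT_MONOCULAR

    def test_behind_the_head_is_blind(self):
        thresholds = GazeThresholds(binocular_half_angle_deg=15, lateral_limit_deg=150)
        assert classify_gaze(BEAK, LEFT_EYE, RIGHT_EYE, (-10.0, 0.01),
                             thresholds) == GazeClass.NONE

    def test_degenerate_geometry_yields_none(self):
        assert classify_gaze((0.0, 0.0), (0.0, 0.0), (0.0, 0.0),
                             (10.0, 0.0)) == GazeClass.NONE

    def test_masked_keypoint_yields_none(self):
        assert classify_gaze((np.nan, np.nan), LEFT_EYE, RIGHT_EYE,
                             (10.0, 0.0)) == GazeClass.NONE

    def test_mirror_reflection_swaps_left_right_labels(self):
        # reflecting the whole scene about y=0 must swap the monocular
        # labels and preserve binocular/none, for any configuration
        rng = np.random.default_rng(42)
        n = 1000
        beak = rng.uniform(-10, 10, (n, 2))
        le = rng.uniform(-10, 10, (n, 2))
        re = rng.uniform(-10, 10, (n, 2))
        stim = rng.uniform(-50, 50, (n, 2))

        def mirror(a):
            out = a.copy()
            out[:, 1] = -out[:, 1]
            return out

        orig = classify_gaze_frames(beak, le, re, stim)
        # mirroring swaps the anatomical eyes too
        refl = classify_gaze_frames(mirror(beak), mirror(re), mirror(le), mirror(stim))
        swap = {
            GazeClass.LEFT_MONOCULAR: GazeClass.RIGHT_MONOCULAR,
            GazeClass.RIGHT_MONOCULAR: GazeClass.LEFT_MONOCULAR,
            GazeClass.BINOCULAR: GazeClass.BINOCULAR,
            GazeClass.NONE: GazeClass.NONE,
        }
        assert all(swap[o] == r for o, r in zip(orig, refl))


class TestGazeDurations:
    def test_classes_partition_the_session(self, geometry):
        from imprintkit import SimParams, clean_track, gaze_durations, px_to_cm
        from imprintkit import simulate_trajectory

        track = simulate_trajectory(
            SimParams(duration_s=20.0, dropout_rate=0.1, seed=6), geometry
        )
        table = px_to_cm(clean_track(table=track.keypoints, max_gap_frames=0),
                         geometry)
        gaze = gaze_durations(table, geometry, "left")
        beak = table.xy("beak")
        masked_s = np.isnan(beak[:, 0]).sum() / table.fps
        total = sum(gaze.values()) + masked_s
        assert total == pytest.approx(20.0, abs=1 / table.fps)

    def test_frontal_chick_views_facing_screen_binocularly(
        self, geometry, head_track_cm
    ):
        from imprintkit import gaze_durations

        # the fixture chick always heads straight toward the right screen
        gaze = gaze_durations(head_track_cm, geometry, "right")
        assert gaze[GazeClass.BINOCULAR] == pytest.approx(12 / 30.0)
        gaze_away = gaze_durations(head_track_cm, geometry, "left")
        assert gaze_away[GazeClass.BINOCULAR] == 0.0


class TestActivity:
    def test_stationary_head(self):
        table = track_from_x(np.full(50, 45.0))
        assert activity(table) == (0.0, 0.0)

    def test_constant_speed_path(self):
        xs = 10.0 + 2.0 * np.arange(11)  # 2 cm per frame, 10 steps
        table = track_from_x(xs, fps=30.0)
        path, speed = activity(table)
        assert path == pytest.approx(20.0)
        assert speed == pytest.approx(20.0 / (10 / 30.0))

    def test_random_walk_matches_step_sum_oracle(self):
        rng = np.random.default_rng(3)
        xy = np.cumsum(rng.normal(0, 0.5, (200, 2)), axis=0) + 45.0
        like = np.ones(200)
        like[50:60] = 0.0  # a masked stretch
        arr = np.column_stack([xy, like])
        table = KeypointTable.from_arrays({"head_center": arr}, fps=30.0, units="cm")
        from imprintkit import clean_track

        cleaned = clean_track(table, max_gap_frames=0)
        path, _ = activity(cleaned)
        head = cleaned.xy("head_center")
        expected = 0.0
        for a, b in zip(head[:-1], head[1:]):
            if not (np.isnan(a).any() or np.isnan(b).any()):
                expected += float(np.hypot(*(b - a)))
        assert path == pytest.approx(expected)

    def test_too_few_frames(self):
        table = track_from_x(np.array([45.0]))
        assert activity(table) == (0.0, 0.0)


class TestAnalyzeSessions:
    def make_timeline(self):
        cfg = ExperimentConfig(
            days=1, sessions_per_day=1, test_session_s=10.0,
            test_set_a=("imp",), test_set_b=("nov",),
            phase_order=("test",), seed=1,
        )
        return compile_schedule(cfg)

    def test_preference_toward_target_stimulus(self, geometry, head_track_cm):
        timeline = self.make_timeline()
        (summary,) = analyze_sessions(
            head_track_cm, geometry, timeline, target_stimuli={"imp"}
        )
        event = timeline.events[0]
        target_side = "left" if event.left_stimulus == "imp" else "right"
        assert summary.target_side == target_side
        t = {"left": summary.time_left_zone_s, "right": summary.time_right_zone_s}
        other = "right" if target_side == "left" else "left"
        assert summary.preference_index == pytest.approx(
            t[target_side] / (t[target_side] + t[other])
        )
        assert summary.preference_defined

    def test_metadata_echoed(self, geometry, head_track_cm):
        (summary,) = analyze_sessions(
            head_track_cm, geometry, self.make_timeline(), target_stimuli={"imp"}
        )
        assert summary.zone_depth_cm == geometry.zone_depth_cm
        assert summary.binocular_half_angle_deg == 15.0

    def test_disjoint_schedule_rejected(self, geometry, head_track_cm):
        cfg = ExperimentConfig(
            days=1, sessions_per_day=1, imprint_session_s=10.0,
            imprint_set=("hen",), seed=0,
        )
        timeline = compile_schedule(cfg)
        shifted = [e for e in timeline.events]
        from imprintkit.schedule import PresentationEvent, Timeline

        late = Timeline(
            events=tuple(
                PresentationEvent(e.day, e.session, e.phase, e.start_s + 1000,
                                  e.end_s + 1000, e.left_stimulus,
                                  e.right_stimulus, e.imprint_side)
                for e in shifted
            ),
            seed=0,
        )
        with pytest.raises(ValueError, match="overlap"):
            analyze_sessions(head_track_cm, geometry, late)
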