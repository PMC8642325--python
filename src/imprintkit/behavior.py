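"""Behavioral quantification of dual-choice sessions from pose tracks.

Given a cleaned keypoint track in arena centimetres and the compiled
schedule (which says what was on each screen when), this module computes
the standard read-outs of the imprinting / free-choice paradigm:

* **zone occupancy** — seconds spent in the left stimulus zone, the middle,
  and the right stimulus zone (each stimulus zone extends
  ``zone_depth_cm`` from its screen);
* **first choice** — which stimulus zone the chick *entered* first (a zone
  transition; starting inside a zone does not count as a choice);
* **preference index** — time near the target stimulus over time near both
  stimuli, 0.5 meaning no preference;
* **eye use (visual-field) classification** — whether the chick views a
  stimulus binocularly or with its left/right monocular field, from the
  head axis (eye midpoint -> beak) versus the bearing to the stimulus;
* **head motoric activity** — path length and mean speed of the head point.

Masked (low-confidence) frames are excluded from every duration, never
imputed. The angular thresholds of the eye-use classifier are calibration
parameters, not measured constants; every summary row records the values
used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .config import DARK
from .schedule import Timeline
from .tracking import KeypointTable

__all__ = [
    "GazeClass",
    "GazeThresholds",
    "BehaviorSummary",
    "assign_zone",
    "assign_zones",
    "summarize_occupancy",
    "first_choice",
    "preference_index",
    "classify_gaze",
    "classify_gaze_frames",
    "gaze_durations",
    "activity",
    "analyze_sessions",
    "write_metrics_csv",
]


class GazeClass(str, Enum):
    """Which part of the visual field a stimulus falls in.

    Chicks have laterally placed eyes: a frontal stimulus is seen with the
    (small) binocular field, a lateral one with a single monocular field.
    """

    BINOCULAR = "binocular"
    LEFT_MONOCULAR = "left_monocular"
    RIGHT_MONOCULAR = "right_monocular"
    NONE = "none"


@dataclass(frozen=True)
class GazeThresholds:
    """Angular limits of the visual-field classifier (degrees).

    ``binocular_half_angle_deg``: half-width of the frontal binocular
    sector; ``lateral_limit_deg``: largest absolute bearing still inside a
    monocular field. Both are calibration parameters exposed in config and
    echoed into every output row.
    """

    binocular_half_angle_deg: float = 15.0
    lateral_limit_deg: float = 150.0

    def __post_init__(self) -> None:
        if not 0 < self.binocular_half_angle_deg < self.lateral_limit_deg <= 180:
            raise ValueError(
                "need 0 < binocular_half_angle_deg < lateral_limit_deg <= 180"
            )


@dataclass
class BehaviorSummary:
    """Per-session behavioural metrics."""

    day: int
    session: int
    phase: str
    start_s: float
    end_s: float
    left_stimulus: str
    right_stimulus: str
    time_left_zone_s: float
    time_middle_s: float
    time_right_zone_s: float
    time_masked_s: float
    first_choice: str  # "left" | "right" | "none"
    target_side: str  # "left" | "right" | "n/a"
    preference_index: float  # nan when undefined
    preference_defined: bool
    gaze_left_stimulus_s: dict = field(default_factory=dict)
    gaze_right_stimulus_s: dict = field(default_factory=dict)
    activity_cm: float = 0.0
    mean_speed_cm_s: float = 0.0
    binocular_half_angle_deg: float = 15.0
    lateral_limit_deg: float = 150.0
    zone_depth_cm: float = 30.0

    def to_row(self) -> dict:
        row = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("gaze_left_stimulus_s", "gaze_right_stimulus_s")
        }
        for side, gd in (
            ("left", self.gaze_left_stimulus_s),
            ("right", self.gaze_right_stimulus_s),
        ):
            for cls in GazeClass:
                row[f"gaze_{side}_{cls.value}_s"] = gd.get(cls, 0.0)
        return row


# ---------------------------------------------------------------- zones


def assign_zone(x_cm: float, geometry: ArenaGeometry) -> str:
    """Zone of a single x position: 'left', 'middle' or 'right'.

    The left zone is x < zone_depth_cm, the right zone
    x > length_cm - zone_depth_cm. Positions outside [0, length] are
    clamped with a warning (tracking jitter can place a point a hair
    outside the wall).
    """
    if math.isnan(x_cm):
        raise ValueError("cannot assign a zone to a masked (NaN) position")
    if x_cm < 0 or x_cm > geometry.length_cm:
        warnings.warn(
            f"x={x_cm:.2f} cm outside arena [0, {geometry.length_cm:g}]; clamped",
            stacklevel=2,
        )
        x_cm = min(max(x_cm, 0.0), geometry.length_cm)
    if x_cm < geometry.zone_depth_cm:
        return "left"
    if x_cm > geometry.length_cm - geometry.zone_depth_cm:
        return "right"
    return "middle"


def assign_zones(x_cm: np.ndarray, geometry: ArenaGeometry) -> np.ndarray:
    """Vectorized :func:`assign_zone`; masked (NaN) frames map to 'masked'."""
    x = np.asarray(x_cm, float)
    x_cl = np.clip(x, 0.0, geometry.length_cm)
    zones = np.full(x.shape, "middle", dtype=object)
    zones[x_cl < geometry.zone_depth_cm] = "left"
    zones[x_cl > geometry.length_cm - geometry.zone_depth_cm] = "right"
    zones[np.isnan(x)] = "masked"
    return zones


def _window_slice(n_frames: int, fps: float, start_s: float, end_s: float) -> slice:
    lo = max(0, math.ceil(start_s * fps - 1e-9))
    hi = min(n_frames, math.ceil(end_s * fps - 1e-9))
    return slice(lo, hi)


def first_choice(zones: np.ndarray) -> str:
    """First stimulus zone *entered* in a zone sequence.

    A choice requires a transition: the first unmasked zone observed sets
    the baseline, and the first subsequent change of zone into 'left' or
    'right' is the choice. A chick that starts in a stimulus zone and
    never moves, or never leaves the middle, has made none.
    """
    prev = None
    for z in zones:
        if z == "masked":
            continue
        if prev is not None and z != prev and z in ("left", "right"):
            return str(z)
        prev = z
    return "none"


def summarize_occupancy(
    track: KeypointTable,
    geometry: ArenaGeometry,
    start_s: float = 0.0,
    end_s: float | None = None,
) -> dict:
    """Zone occupancy of the head point over a time window.

    Frame counts per zone are converted to seconds at the track's fps;
    masked frames are tallied separately, so
    ``left + middle + right + masked`` equals the window duration to within
    one frame. Returns a dict with the times, the first choice and the
    per-frame zone labels (for downstream reuse).
    """
    if track.units != "cm":
        raise ValueError("summarize_occupancy expects a track in cm units")
    if end_s is None:
        end_s = track.n_frames / track.fps
    sl = _window_slice(track.n_frames, track.fps, start_s, end_s)
    if sl.stop <= sl.start:
        raise ValueError(
            f"window [{start_s:g}, {end_s:g}) s does not overlap the track "
            f"({track.n_frames} frames at {track.fps:g} fps)"
        )
    x = track.head_center()[sl, 0]
    zones = assign_zones(x, geometry)
    dt = 1.0 / track.fps
    return {
        "time_left_zone_s": float((zones == "left").sum() * dt),
        "time_middle_s": float((zones == "middle").sum() * dt),
        "time_right_zone_s": float((zones == "right").sum() * dt),
        "time_masked_s": float((zones == "masked").sum() * dt),
        "first_choice": first_choice(zones),
        "zones": zones,
    }


# ----------------------------------------------------------- preference


def preference_index(t_target_s: float, t_other_s: float) -> float:
    """Preference for the target stimulus: t_target / (t_target + t_other).

    0.5 means no preference; swapping the arguments maps p to 1 - p. When
    the chick visited neither stimulus zone the index is undefined and NaN
    is returned — never a silent 0.5.
    """
    if t_target_s < 0 or t_other_s < 0:
        raise ValueError("zone times must be >= 0")
    total = t_target_s + t_other_s
    if total == 0:
        return float("nan")
    return t_target_s / total


# ------------------------------------------------------------- eye use


def _signed_angle(ux, uy, vx, vy):
    """Signed angle (rad) from vector u to vector v in image coordinates."""
    return np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy)


def classify_gaze(
    beak: tuple[float, float],
    left_eye: tuple[float, float],
    right_eye: tuple[float, float],
    stimulus_pos: tuple[float, float],
    thresholds: GazeThresholds = GazeThresholds(),
) -> GazeClass:
    """Visual-field class of a stimulus given the head keypoints.

    The head axis runs from the eye midpoint to the beak; the bearing is
    the signed angle from that axis to the stimulus. Within the binocular
    half-angle the view is binocular; out to the lateral limit it is
    monocular with whichever eye lies on the stimulus side; beyond it the
    stimulus is in the blind sector (``NONE``). Degenerate head geometry
    (coincident keypoints) also yields ``NONE``.
    """
    cls = classify_gaze_frames(
        np.asarray([beak], float),
        np.asarray([left_eye], float),
        np.asarray([right_eye], float),
        np.asarray([stimulus_pos], float),
        thresholds,
    )[0]
    return GazeClass(cls)


def classify_gaze_frames(
    beak: np.ndarray,
    left_eye: np.ndarray,
    right_eye: np.ndarray,
    stimulus_pos: np.ndarray,
    thresholds: GazeThresholds = GazeThresholds(),
) -> np.ndarray:
    """Vectorized gaze classification over (n, 2) keypoint arrays.

    Returns an object array of :class:`GazeClass` values; frames with any
    masked keypoint or degenerate geometry are ``NONE``.
    """
    beak = np.atleast_2d(np.asarray(beak, float))
    le = np.atleast_2d(np.asarray(left_eye, float))
    re = np.atleast_2d(np.asarray(right_eye, float))
    stim = np.broadcast_to(
        np.atleast_2d(np.asarray(stimulus_pos, float)), beak.shape
    )
    mid = (le + re) / 2.0
    axis = beak - mid
    bearing = stim - mid
    eye_vec = le - mid

    with np.errstate(invalid="ignore"):
        theta = _signed_angle(axis[:, 0], axis[:, 1], bearing[:, 0], bearing[:, 1])
        eye_angle = _signed_angle(axis[:, 0], axis[:, 1], eye_vec[:, 0], eye_vec[:, 1])
    left_sign = np.sign(eye_angle)

    abs_deg = np.degrees(np.abs(theta))
    degenerate = (
        np.isnan(beak).any(1)
        | np.isnan(le).any(1)
        | np.isnan(re).any(1)
        | np.isnan(stim).any(1)
        | (np.hypot(axis[:, 0], axis[:, 1]) == 0)
        | (np.hypot(bearing[:, 0], bearing[:, 1]) == 0)
        | (left_sign == 0)
        | np.isnan(abs_deg)
    )

    with np.errstate(invalid="ignore"):
        binoc = abs_deg <= thresholds.binocular_half_angle_deg
        lateral = (~binoc) & (abs_deg <= thresholds.lateral_limit_deg)
        same_side_as_left_eye = np.sign(theta) == left_sign
    code = np.zeros(len(beak), dtype=int)  # 0=none
    code[binoc] = 1
    code[lateral & same_side_as_left_eye] = 2
    code[lateral & ~same_side_as_left_eye] = 3
    code[degenerate] = 0
    lut = np.array(
        [GazeClass.NONE, GazeClass.BINOCULAR,
         GazeClass.LEFT_MONOCULAR, GazeClass.RIGHT_MONOCULAR],
        dtype=object,
    )
    return lut[code]


def gaze_durations(
    track: KeypointTable,
    geometry: ArenaGeometry,
    stimulus_side: str,
    thresholds: GazeThresholds = GazeThresholds(),
    start_s: float = 0.0,
    end_s: float | None = None,
) -> dict:
    """Seconds spent viewing a screen with each visual field.

    The gaze target is the point of the ``stimulus_side`` screen at the
    chick's own y (the screen spans the short wall), evaluated per frame.
    Frames with any masked head keypoint count toward no class.
    """
    if track.units != "cm":
        raise ValueError("gaze_durations expects a track in cm units")
    if end_s is None:
        end_s = track.n_frames / track.fps
    sl = _window_slice(track.n_frames, track.fps, start_s, end_s)
    beak = track.xy("beak")[sl]
    le = track.xy("left_eye")[sl]
    re = track.xy("right_eye")[sl]
    stim_x = geometry.screen_x_cm(stimulus_side)
    mid_y = (le[:, 1] + re[:, 1]) / 2.0
    stim = np.column_stack([np.full(len(beak), stim_x), mid_y])
    classes = classify_gaze_frames(beak, le, re, stim, thresholds)
    dt = 1.0 / track.fps
    masked = (
        np.isnan(beak).any(1) | np.isnan(le).any(1) | np.isnan(re).any(1)
    )
    out = {cls: 0.0 for cls in GazeClass}
    for cls in GazeClass:
        # compare by value: numpy stringifies an enum scalar via str(), so
        # `classes == cls` would silently match nothing
        n = int(((classes == cls.value) & ~masked).sum())
        out[cls] = n * dt
    return out


# ------------------------------------------------------------- activity


def activity(
    track: KeypointTable, start_s: float = 0.0, end_s: float | None = None
) -> tuple[float, float]:
    """Head path length (cm) and mean speed (cm/s) over unmasked steps.

    A step counts only when both of its endpoint frames are unmasked; the
    mean speed divides the path by the summed duration of counted steps.
    Fewer than two unmasked frames yields (0, 0).
    """
    if track.units != "cm":
        raise ValueError("activity expects a track in cm units")
    if end_s is None:
        end_s = track.n_frames / track.fps
    sl = _window_slice(track.n_frames, track.fps, start_s, end_s)
    head = track.head_center()[sl]
    ok = ~np.isnan(head).any(axis=1)
    step_ok = ok[:-1] & ok[1:]
    if step_ok.sum() == 0:
        return 0.0, 0.0
    deltas = np.diff(head, axis=0)
    lengths = np.hypot(deltas[:, 0], deltas[:, 1])[step_ok]
    path = float(lengths.sum())
    duration = step_ok.sum() / track.fps
    return path, path / duration


# ----------------------------------------------------------- pipeline


def analyze_sessions(
    track: KeypointTable,
    geometry: ArenaGeometry,
    timeline: Timeline,
    target_stimuli: set[str] | None = None,
    thresholds: GazeThresholds = GazeThresholds(),
) -> list[BehaviorSummary]:
    """Join a track against the schedule and summarize every active session.

    The track's frame 0 is taken to be timeline t = 0. For test events the
    target side is the screen showing a stimulus from ``target_stimuli``
    (e.g. the imprinting set); for imprinting events it is the lit screen.
    Raises ``ValueError`` when the schedule and the track do not overlap.
    """
    if track.units != "cm":
        raise ValueError("analyze_sessions expects a track in cm units")
    track_end = track.n_frames / track.fps
    summaries = []
    for event in timeline.active_events():
        if event.start_s >= track_end or event.end_s <= 0:
            continue
        occ = summarize_occupancy(track, geometry, event.start_s, event.end_s)
        if event.phase == "imprinting":
            target_side = event.imprint_side
        elif target_stimuli:
            if event.left_stimulus in target_stimuli:
                target_side = "left"
            elif event.right_stimulus in target_stimuli:
                target_side = "right"
            else:
                target_side = "n/a"
        else:
            target_side = "n/a"

        if target_side == "left":
            pi = preference_index(occ["time_left_zone_s"], occ["time_right_zone_s"])
        elif target_side == "right":
            pi = preference_index(occ["time_right_zone_s"], occ["time_left_zone_s"])
        else:
            pi = float("nan")

        gaze_left = (
            gaze_durations(track, geometry, "left", thresholds,
                           event.start_s, event.end_s)
            if event.left_stimulus != DARK
            else {cls: 0.0 for cls in GazeClass}
        )
        gaze_right = (
            gaze_durations(track, geometry, "right", thresholds,
                           event.start_s, event.end_s)
            if event.right_stimulus != DARK
            else {cls: 0.0 for cls in GazeClass}
        )
        path, speed = activity(track, event.start_s, event.end_s)
        summaries.append(
            BehaviorSummary(
                day=event.day,
                session=event.session,
                phase=event.phase,
                start_s=event.start_s,
                end_s=event.end_s,
                left_stimulus=event.left_stimulus,
                right_stimulus=event.right_stimulus,
                time_left_zone_s=occ["time_left_zone_s"],
                time_middle_s=occ["time_middle_s"],
                time_right_zone_s=occ["time_right_zone_s"],
                time_masked_s=occ["time_masked_s"],
                first_choice=occ["first_choice"],
                target_side=target_side,
                preference_index=pi,
                preference_defined=not math.isnan(pi),
                gaze_left_stimulus_s=gaze_left,
                gaze_right_stimulus_s=gaze_right,
                activity_cm=path,
                mean_speed_cm_s=speed,
                binocular_half_angle_deg=thresholds.binocular_half_angle_deg,
                lateral_limit_deg=thresholds.lateral_limit_deg,
                zone_depth_cm=geometry.zone_depth_cm,
            )
        )
    if not summaries:
        raise ValueError("schedule and track do not overlap in time")
    return summaries


def write_metrics_csv(summaries: list[BehaviorSummary], path: str | Path) -> None:
    """One row per session, metrics plus the thresholds that produced them."""
    pd.DataFrame([s.to_row() for s in summaries]).to_csv(path, index=False)
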