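"""Synthetic chick trajectories with a controllable side preference.

Every downstream stage (cleaning, calibration, occupancy, eye use,
activity) is testable without animals or cameras: the simulator emits
keypoint tables in the same DeepLabCut CSV dialect a real tracking network
would, plus a per-frame ground-truth sidecar.

The model is a bout-structured biased walk. The chick alternates between
*travelling* toward a goal anchor (a point well inside one stimulus zone)
and *dwelling* there under an attractive pull with small positional noise.
At the end of each dwell bout a new goal is drawn: the target screen with
probability ``preference_p``, the other screen otherwise. Because dwell
bouts have the same expected length on both sides and entries into the two
zones are equally frequent (an entry requires a side switch, and switches
target->other and other->target are equally common), the expected fraction
of stimulus-zone time spent at the target equals ``preference_p`` by
construction — no pilot calibration is needed.

Head keypoints (beak, both eyes) ride on a rigid triangle around the body
point, oriented along the smoothed direction of motion plus heading noise;
the dimensions (eyes 1.5 cm apart, beak 2 cm ahead) are plausible
chick-scale fixture constants, not biological claims. A seeded fraction of
frames is emitted with low likelihood to mimic tracking dropout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .arena import ArenaGeometry
from .behavior import assign_zones
from .tracking import KeypointTable

__all__ = ["SimParams", "SimulatedTrack", "simulate_trajectory", "write_ground_truth"]

#: rigid head-triangle dimensions (cm)
EYE_SEPARATION_CM = 1.5
BEAK_AHEAD_CM = 2.0

#: likelihood emitted on dropout frames (well below any sensible threshold)
DROPOUT_LIKELIHOOD = 0.1


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic chick.

    ``preference_p`` is the long-run fraction of stimulus-zone time spent
    at the ``target_side`` screen. ``step_cm_sd`` scales per-frame
    positional noise, ``turn_sd_deg`` the per-frame heading noise, and
    ``dropout_rate`` the fraction of frames emitted with low likelihood.
    """

    preference_p: float = 0.5
    duration_s: float = 600.0
    fps: float = 30.0
    step_cm_sd: float = 0.2
    turn_sd_deg: float = 15.0
    dropout_rate: float = 0.05
    seed: int = 0
    target_side: str = "left"
    travel_speed_cm_s: float = 12.0
    dwell_s: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preference_p <= 1.0:
            raise ValueError("preference_p must be in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.target_side not in ("left", "right"):
            raise ValueError("target_side must be 'left' or 'right'")


@dataclass(frozen=True)
class SimulatedTrack:
    """A simulated session: keypoints (px) plus per-frame ground truth."""

    keypoints: KeypointTable
    true_zone: np.ndarray  # per-frame zone of the body point
    params: SimParams
    geometry: ArenaGeometry


def simulate_trajectory(
    params: SimParams, geometry: ArenaGeometry | None = None
) -> SimulatedTrack:
    """Run the bout-structured walk and emit a pixel-space keypoint table.

    Fully reproducible: the same (params, geometry) always yields the same
    table, down to the CSV bytes written from it. Positions stay inside
    the arena (reflecting walls).
    """
    geometry = geometry or ArenaGeometry()
    rng = np.random.default_rng(params.seed)
    n = round(params.duration_s * params.fps)
    dt = 1.0 / params.fps

    depth = geometry.zone_depth_cm
    anchors = {
        "left": (depth / 2.0, geometry.width_cm / 2.0),
        "right": (geometry.length_cm - depth / 2.0, geometry.width_cm / 2.0),
    }
    other = {"left": "right", "right": "left"}

    # pre-drawn per-frame noise keeps the sequential loop cheap
    noise = rng.normal(0.0, params.step_cm_sd, size=(n, 2))
    goal_draws = rng.random(n)  # at most one goal switch per frame
    jitter_draws = rng.random(n)  # dwell-length jitter, independent of goals

    step_travel = params.travel_speed_cm_s * dt
    arrive_r = 4.0
    pull = 0.1  # dwell attraction per frame; keeps excursions ~0.5 cm
    margin = 1.0
    lo = np.array([margin, margin])
    hi = np.array([geometry.length_cm - margin, geometry.width_cm - margin])

    def draw_goal(k: int) -> str:
        return params.target_side if goal_draws[k] < params.preference_p else other[params.target_side]

    pos = np.array([geometry.length_cm / 2.0, geometry.width_cm / 2.0])
    goal_side = draw_goal(0)
    goal = np.asarray(anchors[goal_side])
    dwelling = False
    dwell_left = 0
    body = np.empty((n, 2))

    for k in range(n):
        if dwelling:
            pos = pos + pull * (goal - pos) + 0.5 * noise[k]
            dwell_left -= 1
            if dwell_left <= 0:
                new_side = draw_goal(k)
                if new_side == goal_side:
                    dwell_left = _dwell_frames(params, jitter_draws[k])
                else:
                    goal_side = new_side
                    goal = np.asarray(anchors[goal_side])
                    dwelling = False
        else:
            d = goal - pos
            dist = float(np.hypot(d[0], d[1]))
            if dist < arrive_r:
                dwelling = True
                dwell_left = _dwell_frames(params, jitter_draws[k])
            else:
                pos = pos + d * (step_travel / dist) + 0.3 * noise[k]
        # reflect at the walls
        pos = np.where(pos < lo, 2 * lo - pos, pos)
        pos = np.where(pos > hi, 2 * hi - pos, pos)
        pos = np.clip(pos, lo, hi)
        body[k] = pos

    # heading: exponentially smoothed velocity plus per-frame noise
    vel = np.vstack([[0.0, 0.0], np.diff(body, axis=0)])
    alpha = 0.2
    smooth = lfilter([alpha], [1.0, -(1.0 - alpha)], vel, axis=0)
    heading = np.arctan2(smooth[:, 1], smooth[:, 0])
    heading += np.radians(params.turn_sd_deg) * rng.normal(size=n)

    h = np.column_stack([np.cos(heading), np.sin(heading)])
    # left side of the animal in image (y-down) coordinates
    n_left = np.column_stack([h[:, 1], -h[:, 0]])
    beak = body + BEAK_AHEAD_CM * h
    left_eye = body + (EYE_SEPARATION_CM / 2.0) * n_left
    right_eye = body - (EYE_SEPARATION_CM / 2.0) * n_left

    base_like = rng.uniform(0.95, 1.0, size=n)
    dropout = rng.random(n) < params.dropout_rate
    like = np.where(dropout, DROPOUT_LIKELIHOOD, base_like)

    s = geometry.px_per_cm
    ox, oy = geometry.origin_px

    def to_px(xy: np.ndarray) -> np.ndarray:
        return np.column_stack([xy[:, 0] * s + ox, xy[:, 1] * s + oy, like])

    table = KeypointTable.from_arrays(
        {
            "beak": to_px(beak),
            "left_eye": to_px(left_eye),
            "right_eye": to_px(right_eye),
            "head_center": to_px(body),
        },
        fps=params.fps,
        scorer="imprintkit-sim",
        units="px",
    )
    true_zone = assign_zones(body[:, 0], geometry)
    return SimulatedTrack(
        keypoints=table, true_zone=true_zone, params=params, geometry=geometry
    )


def _dwell_frames(params: SimParams, jitter_u: float) -> int:
    # dwell bouts of dwell_s +/- 20%, jittered by the same pre-drawn uniforms
    jitter = 0.8 + 0.4 * jitter_u
    return max(1, round(params.dwell_s * jitter * params.fps))


def write_ground_truth(track: SimulatedTrack, path: str | Path) -> None:
    """Per-frame true zone plus the true preference, for validation."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "true_zone", "true_p", "target_side"])
        for k, z in enumerate(track.true_zone):
            w.writerow([k, z, track.params.preference_p, track.params.target_side])
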