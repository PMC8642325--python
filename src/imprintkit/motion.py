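"""Headless per-frame stimulus state for translatory and flicker presentation.

Instead of driving a monitor, the engine emits ideal :class:`FrameState`
records sampled at the configured refresh rate (>= 115 Hz, the chick
flicker-fusion threshold; 120 Hz in the reference setup). A frame log is
the ground truth of what an on-screen player should have shown.

Conventions (fixed for reproducibility, since either choice is defensible):

* translatory motion is ``x(t) = center_x + A * sin(2*pi*t / T)`` — the
  image starts at the centre moving in +x, position and speed are both
  sinusoidal, and ``A`` is the maximum displacement from centre
  (peak-to-peak excursion is ``2A``);
* flicker is a square wave that starts visible: on for ``on_s``, off for
  ``off_s``, repeating;
* events are sampled on the half-open interval [start, end), start
  inclusive, so contiguous events never double-emit a boundary frame.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .config import MIN_REFRESH_HZ, MotionParams
from .schedule import PresentationEvent, Timeline

__all__ = [
    "FrameState",
    "position_at",
    "visibility_at",
    "frames_for_event",
    "iter_timeline_frames",
    "write_frame_log",
    "FRAME_COLUMNS",
]

FRAME_COLUMNS = ("frame", "t_s", "side", "visible", "x_px", "y_px")


@dataclass(frozen=True, slots=True)
class FrameState:
    """Stimulus state of a single display frame.

    ``t_s`` is ``frame_index / refresh_hz`` on the clock of whatever the
    frame sequence spans (a single event, or the whole timeline for
    :func:`iter_timeline_frames`). ``side`` is where a stimulus is shown:
    one screen for imprinting, ``both`` for test, ``dark`` for pauses.
    """

    frame_index: int
    t_s: float
    side: str  # "left" | "right" | "both" | "dark"
    visible: bool
    x_px: float
    y_px: float


def position_at(params: MotionParams, t: float) -> float:
    """Horizontal position (px) of a translatory stimulus at time ``t``.

    x(t) = center_x + amplitude * sin(2*pi*t / period); periodic with the
    configured period, bounded by +/- amplitude around the centre.
    """
    if params.mode != "translatory":
        return params.center_x_px
    if params.period_s <= 0:
        raise ValueError("translatory motion requires period_s > 0")
    return params.center_x_px + params.amplitude_px * math.sin(
        2.0 * math.pi * t / params.period_s
    )


def visibility_at(params: MotionParams, t: float) -> bool:
    """Square-wave visibility of a flickering stimulus at time ``t``.

    Visible on [k*(on+off), k*(on+off) + on) for every integer k >= 0; the
    duty fraction over whole cycles is on / (on + off).
    """
    if params.mode != "flicker":
        return True
    cycle = params.on_s + params.off_s
    if cycle <= 0:
        raise ValueError("flicker requires on_s + off_s > 0")
    phase = t % cycle
    # snap phases within float rounding of a boundary onto it, so frame
    # times like 1.4 (stored as 1.4 - 2^-53) land in the right half-cycle
    eps = 1e-9 * max(1.0, abs(t))
    if cycle - phase <= eps:
        phase = 0.0
    return phase < params.on_s and (params.on_s - phase) > eps


def frames_for_event(
    event: PresentationEvent,
    params: MotionParams,
    refresh_hz: float,
) -> list[FrameState]:
    """Sample an event into per-frame states at ``refresh_hz``.

    Emits exactly ``round(duration * refresh_hz)`` frames; frame k is at
    t = k / refresh_hz after event start (half-open sampling). Pause/dark
    events emit invisible frames so the log covers every instant.
    """
    if refresh_hz < MIN_REFRESH_HZ:
        raise ValueError(
            f"refresh_hz {refresh_hz:g} below the {MIN_REFRESH_HZ:g} Hz minimum"
        )
    n_frames = round(event.duration_s * refresh_hz)
    dark = event.phase == "pause"
    if event.phase == "imprinting":
        side = event.imprint_side
    elif event.phase == "test":
        side = "both"
    else:
        side = "dark"
    frames = []
    for k in range(n_frames):
        t = k / refresh_hz
        visible = (not dark) and visibility_at(params, t)
        x = position_at(params, t) if params.mode == "translatory" else params.center_x_px
        frames.append(
            FrameState(
                frame_index=k,
                t_s=t,
                side=side,
                visible=visible,
                x_px=x,
                y_px=params.y_offset_px,
            )
        )
    return frames


def iter_timeline_frames(
    timeline: Timeline, params: MotionParams, refresh_hz: float
) -> Iterator[FrameState]:
    """Stream frames for a whole timeline with a global frame counter.

    Each event restarts its motion phase at its own start (an image begins
    a session centred and visible); frame indices and times are global so
    ``t_s = frame / refresh_hz`` holds across the run.
    """
    offset = 0
    for event in timeline.events:
        for f in frames_for_event(event, params, refresh_hz):
            yield FrameState(
                frame_index=offset + f.frame_index,
                t_s=(offset + f.frame_index) / refresh_hz,
                side=f.side,
                visible=f.visible,
                x_px=f.x_px,
                y_px=f.y_px,
            )
        offset += round(event.duration_s * refresh_hz)


def write_frame_log(frames, path: str | Path) -> None:
    """Write frames as CSV ``frame,t_s,side,visible,x_px,y_px``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FRAME_COLUMNS)
        for f in frames:
            w.writerow(
                [f.frame_index, repr(float(f.t_s)), f.side,
                 int(f.visible), repr(float(f.x_px)), repr(float(f.y_px))]
            )
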