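"""Compile an experiment configuration into a deterministic presentation timeline.

The compiler turns the days/sessions grid of an :class:`ExperimentConfig`
into an ordered list of :class:`PresentationEvent`: imprinting events (one
image on one screen, the other dark), test events (one image per screen),
and explicit dark pause events between sessions. Which side the imprinting
image (or test set A) appears on is assigned pseudo-randomly but balanced —
over the whole experiment each side hosts the same set of stimuli for the
same number of sessions, up to one session when the count is odd.

Everything is seeded: the same (config, seed) pair always compiles to the
same timeline, and the schedule log written from it is byte-identical, so a
run can be audited or replayed exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import (
    DARK,
    ExperimentConfig,
    config_fingerprint,
    validate_config,
)

__all__ = [
    "PresentationEvent",
    "Timeline",
    "balance_sides",
    "compile_schedule",
    "write_schedule_log",
    "read_schedule_log",
    "write_schedule_xlsx",
    "SCHEDULE_COLUMNS",
]

SCHEDULE_COLUMNS = (
    "day",
    "session",
    "phase",
    "start_s",
    "end_s",
    "left_stimulus",
    "right_stimulus",
    "imprint_side",
    "seed",
)


@dataclass(frozen=True)
class PresentationEvent:
    """One contiguous stretch of screen state.

    ``imprint_side`` is the screen showing the single image during an
    imprinting event and ``"n/a"`` otherwise. Times are absolute seconds
    from experiment start; ``day`` and ``session`` are 1-based indices.
    """

    day: int
    session: int
    phase: str  # "imprinting" | "test" | "pause"
    start_s: float
    end_s: float
    left_stimulus: str = DARK
    right_stimulus: str = DARK
    imprint_side: str = "n/a"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Timeline:
    """Compiled schedule: ordered events plus provenance."""

    events: tuple[PresentationEvent, ...]
    config_fingerprint: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def total_span_s(self) -> float:
        return self.events[-1].end_s if self.events else 0.0

    def active_events(self) -> tuple[PresentationEvent, ...]:
        return tuple(e for e in self.events if e.phase != "pause")


def balance_sides(
    n_sessions: int, seed: int, max_run: int | None = None
) -> list[str]:
    """Balanced pseudo-random left/right assignment for ``n_sessions`` sessions.

    Returns a seeded shuffle of a maximally balanced multiset: exactly
    floor(n/2) of one side and ceil(n/2) of the other, with the surplus
    side (for odd n) itself chosen by the seeded generator. The counts
    therefore never differ by more than one, which balances the exposure
    time of each side when session durations are equal.

    ``max_run`` optionally caps consecutive same-side assignments by
    re-shuffling (off by default; the balancing itself already bounds runs
    at n/2 + 1).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    half = n_sessions // 2
    sides = ["left"] * half + ["right"] * half
    if n_sessions % 2:
        sides.append("left" if rng.random() < 0.5 else "right")
    sides = np.asarray(sides)
    for _ in range(10_000):
        rng.shuffle(sides)
        if max_run is None or _longest_run(sides) <= max_run:
            return [str(s) for s in sides]
    raise ValueError(
        f"could not satisfy max_run={max_run} for n_sessions={n_sessions}"
    )


def _longest_run(sides: np.ndarray) -> int:
    best = run = 1
    for a, b in zip(sides[:-1], sides[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


class _StimulusPicker:
    """Seeded per-session stimulus choice from a set.

    "replace": uniform with replacement (a fresh random image each
    session). "cycle": seeded permutations without replacement, reshuffled
    each time the set is exhausted.
    """

    def __init__(self, ids: tuple[str, ...], seed, mode: str) -> None:
        self.ids = list(ids)
        self.rng = np.random.default_rng(seed)
        self.mode = mode
        self._queue: list[str] = []

    def pick(self) -> str:
        if self.mode == "replace":
            return self.ids[int(self.rng.integers(len(self.ids)))]
        if not self._queue:
            order = self.rng.permutation(len(self.ids))
            self._queue = [self.ids[i] for i in order]
        return self._queue.pop(0)


def compile_schedule(config: ExperimentConfig) -> Timeline:
    """Compile a validated configuration into a :class:`Timeline`.

    Per day, each session runs the phases of ``config.phase_order`` in
    order; consecutive active events are separated by explicit dark pause
    events of ``inter_session_pause_s``. Events are contiguous within the
    experiment (no gaps), and days are logical blocks of absolute time, not
    wall-clock dates. Phases with zero duration are skipped.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError(
            "invalid ExperimentConfig:\n  " + "\n  ".join(violations)
        )

    ss = np.random.SeedSequence(config.seed)
    s_side_imp, s_side_test, s_stim_imp, s_stim_a, s_stim_b = ss.spawn(5)

    active_phases = [
        p for p in config.phase_order if config.phase_duration_s(p) > 0
    ]
    n_sessions = config.days * config.sessions_per_day
    sides: dict[str, list[str]] = {}
    if "imprinting" in active_phases:
        sides["imprinting"] = balance_sides(
            n_sessions, int(s_side_imp.generate_state(1)[0]), config.max_side_run
        )
    if "test" in active_phases:
        sides["test"] = balance_sides(
            n_sessions, int(s_side_test.generate_state(1)[0]), config.max_side_run
        )

    pick_imp = _StimulusPicker(config.imprint_set, s_stim_imp, config.stimulus_sampling) \
        if config.imprint_set else None
    pick_a = _StimulusPicker(config.test_set_a, s_stim_a, config.stimulus_sampling) \
        if config.test_set_a else None
    pick_b = _StimulusPicker(config.test_set_b, s_stim_b, config.stimulus_sampling) \
        if config.test_set_b else None

    events: list[PresentationEvent] = []
    t = 0.0
    session_idx = 0  # experiment-wide session counter for side lists
    for day in range(1, config.days + 1):
        day_events: list[tuple[int, str, float, str, str, str]] = []
        for session in range(1, config.sessions_per_day + 1):
            for phase in active_phases:
                dur = config.phase_duration_s(phase)
                if phase == "imprinting":
                    side = sides["imprinting"][session_idx]
                    stim = pick_imp.pick()
                    left = stim if side == "left" else DARK
                    right = stim if side == "right" else DARK
                    day_events.append((session, phase, dur, left, right, side))
                else:  # test
                    side_a = sides["test"][session_idx]
                    stim_a, stim_b = pick_a.pick(), pick_b.pick()
                    if side_a == "left":
                        left, right = stim_a, stim_b
                    else:
                        left, right = stim_b, stim_a
                    day_events.append((session, phase, dur, left, right, "n/a"))
            session_idx += 1
        for i, (session, phase, dur, left, right, side) in enumerate(day_events):
            events.append(
                PresentationEvent(day, session, phase, t, t + dur, left, right, side)
            )
            t += dur
            last_of_day = i == len(day_events) - 1
            if not last_of_day and config.inter_session_pause_s > 0:
                events.append(
                    PresentationEvent(
                        day, session, "pause", t, t + config.inter_session_pause_s
                    )
                )
                t += config.inter_session_pause_s

    return Timeline(
        events=tuple(events),
        config_fingerprint=config_fingerprint(config),
        seed=config.seed,
    )


def _fmt(x: float) -> str:
    # repr round-trips floats exactly through the CSV
    return repr(float(x))


def write_schedule_log(timeline: Timeline, path: str | Path) -> None:
    """Write the audit log: one CSV row per event (pauses included).

    The log fully reconstructs screen state at any instant of the
    experiment and round-trips losslessly through
    :func:`read_schedule_log`.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCHEDULE_COLUMNS)
        for e in timeline.events:
            w.writerow(
                [
                    e.day,
                    e.session,
                    e.phase,
                    _fmt(e.start_s),
                    _fmt(e.end_s),
                    e.left_stimulus,
                    e.right_stimulus,
                    e.imprint_side,
                    timeline.seed,
                ]
            )


def read_schedule_log(path: str | Path) -> Timeline:
    """Read a schedule log back into a :class:`Timeline` (event-wise inverse
    of :func:`write_schedule_log`; the config fingerprint is not stored in
    the log and comes back empty)."""
    events: list[PresentationEvent] = []
    seed = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != SCHEDULE_COLUMNS:
            raise ValueError(
                f"not a schedule log: expected header {','.join(SCHEDULE_COLUMNS)}"
            )
        for row in reader:
            day, session, phase, start_s, end_s, left, right, side, seed_s = row
            events.append(
                PresentationEvent(
                    int(day), int(session), phase,
                    float(start_s), float(end_s), left, right, side,
                )
            )
            seed = int(seed_s)
    return Timeline(events=tuple(events), seed=seed)


def write_schedule_xlsx(timeline: Timeline, path: str | Path) -> None:
    """Excel export of the schedule log (same columns as the CSV)."""
    import pandas as pd

    rows = [
        {
            "day": e.day, "session": e.session, "phase": e.phase,
            "start_s": e.start_s, "end_s": e.end_s,
            "left_stimulus": e.left_stimulus, "right_stimulus": e.right_stimulus,
            "imprint_side": e.imprint_side, "seed": timeline.seed,
        }
        for e in timeline.events
    ]
    pd.DataFrame(rows, columns=list(SCHEDULE_COLUMNS)).to_excel(path, index=False)
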