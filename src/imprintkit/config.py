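"""Experiment configuration: declarative description of an imprinting run.

An experiment is a grid of days x sessions. Within each session one or more
presentation phases run in ``phase_order``: an *imprinting* phase shows a
single image on one screen while the other screen stays dark, a *test*
phase shows one image from each of two test sets simultaneously (the dual
free-choice task). Sessions are separated by dark inter-session pauses.

Because the chick flicker-fusion threshold is about 115 Hz, configurations
with a display refresh below 115 Hz are rejected by :func:`validate_config`
— below that rate the screens themselves flicker visibly to the animal.
The reference display runs at 120 Hz.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "MIN_REFRESH_HZ",
    "DARK",
    "MotionParams",
    "ExperimentConfig",
    "validate_config",
    "config_fingerprint",
    "load_config",
    "save_config",
]

#: Chick flicker-fusion frequency: displays slower than this are perceived
#: as flickering light rather than a constant stream.
MIN_REFRESH_HZ = 115.0

#: Sentinel stimulus id for a dark (switched-off) screen.
DARK = "dark"

PHASES = ("imprinting", "test")


@dataclass(frozen=True)
class MotionParams:
    """How a stimulus image moves on screen.

    mode
        ``static`` — image fixed at ``center_x_px``;
        ``translatory`` — horizontal sinusoidal oscillation,
        x(t) = center + amplitude * sin(2*pi*t / period);
        ``flicker`` — square-wave appearance/disappearance, visible for
        ``on_s`` then hidden for ``off_s``, repeating.

    ``amplitude_px`` is the maximum displacement from the centre, so the
    peak-to-peak excursion is twice the amplitude. ``y_offset_px`` shifts
    the image vertically (positive = downward, image convention).
    """

    mode: str = "static"
    amplitude_px: float = 0.0
    period_s: float = 0.0
    on_s: float = 0.0
    off_s: float = 0.0
    y_offset_px: float = 0.0
    center_x_px: float = 0.0

    def violations(self) -> list[str]:
        out = []
        if self.mode not in ("static", "translatory", "flicker"):
            out.append(f"motion.mode: unknown mode {self.mode!r}")
        if self.amplitude_px < 0:
            out.append("motion.amplitude_px: must be >= 0")
        if self.mode == "translatory" and self.period_s <= 0:
            out.append("motion.period_s: must be > 0 for translatory motion")
        if self.mode == "flicker":
            if self.on_s < 0 or self.off_s < 0:
                out.append("motion.on_s/off_s: must be >= 0")
            elif self.on_s + self.off_s <= 0:
                out.append("motion.on_s+off_s: flicker cycle must be > 0")
        return out


@dataclass(frozen=True)
class ExperimentConfig:
    """Full declarative description of an imprinting / dual-choice run."""

    refresh_hz: float = 120.0
    days: int = 1
    sessions_per_day: int = 1
    imprint_session_s: float = 0.0
    test_session_s: float = 0.0
    inter_session_pause_s: float = 0.0
    imprint_set: tuple[str, ...] = ()
    test_set_a: tuple[str, ...] = ()
    test_set_b: tuple[str, ...] = ()
    motion: MotionParams = field(default_factory=MotionParams)
    seed: int = 0
    phase_order: tuple[str, ...] = ("imprinting",)
    #: sample stimuli with replacement ("replace") or cycle a seeded
    #: permutation without replacement ("cycle")
    stimulus_sampling: str = "replace"
    #: optional cap on consecutive same-side assignments (None = no cap)
    max_side_run: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "imprint_set", tuple(self.imprint_set))
        object.__setattr__(self, "test_set_a", tuple(self.test_set_a))
        object.__setattr__(self, "test_set_b", tuple(self.test_set_b))
        object.__setattr__(self, "phase_order", tuple(self.phase_order))

    def phase_duration_s(self, phase: str) -> float:
        if phase == "imprinting":
            return self.imprint_session_s
        if phase == "test":
            return self.test_session_s
        raise ValueError(f"unknown phase {phase!r}")


def validate_config(config: ExperimentConfig) -> list[str]:
    """Check a configuration; return a list of violations (empty = valid).

    Violations are returned as data rather than raised, so a caller (CLI or
    GUI replacement) can report all problems at once.
    """
    v: list[str] = []
    if config.refresh_hz < MIN_REFRESH_HZ:
        v.append(
            f"refresh_hz: {config.refresh_hz:g} Hz is below the {MIN_REFRESH_HZ:g} Hz "
            "chick flicker-fusion threshold"
        )
    if config.days < 1:
        v.append("days: must be >= 1")
    if config.sessions_per_day < 1:
        v.append("sessions_per_day: must be >= 1")
    for name in ("imprint_session_s", "test_session_s", "inter_session_pause_s"):
        if getattr(config, name) < 0:
            v.append(f"{name}: must be >= 0")
    for phase in config.phase_order:
        if phase not in PHASES:
            v.append(f"phase_order: unknown phase {phase!r}")
    if "imprinting" in config.phase_order and not config.imprint_set:
        v.append("imprint_set: imprinting phase requires a non-empty imprint set")
    if "test" in config.phase_order and (not config.test_set_a or not config.test_set_b):
        v.append("test_set_a/test_set_b: test phase requires both test sets non-empty")
    if config.stimulus_sampling not in ("replace", "cycle"):
        v.append("stimulus_sampling: must be 'replace' or 'cycle'")
    if config.max_side_run is not None and config.max_side_run < 1:
        v.append("max_side_run: must be >= 1 or None")
    v.extend(config.motion.violations())
    return v


def config_fingerprint(config: ExperimentConfig) -> str:
    """Stable hash of a configuration, recorded in compiled timelines."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    motion = MotionParams(**raw.pop("motion", {}))
    return ExperimentConfig(motion=motion, **raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    data = asdict(config)
    data["imprint_set"] = list(config.imprint_set)
    data["test_set_a"] = list(config.test_set_a)
    data["test_set_b"] = list(config.test_set_b)
    data["phase_order"] = list(config.phase_order)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
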