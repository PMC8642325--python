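"""Pose-track I/O in the DeepLabCut CSV dialect, cleaning, and calibration.

DeepLabCut exports one CSV per video with three header rows — scorer,
bodyparts, coords — and x, y, likelihood columns per bodypart per frame.
This module reads and writes that dialect, masks low-confidence points,
bridges short tracking gaps by linear interpolation, and converts pixel
coordinates to arena centimetres with a single isotropic scale (the
overhead camera sits ~105 cm above a 90 cm arena, so perspective error is
negligible at behavioural precision and a full homography is unnecessary).

A masked point is represented by NaN coordinates; downstream metrics skip
masked frames instead of guessing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaGeometry

__all__ = [
    "KeypointTable",
    "ParseError",
    "read_keypoints",
    "write_keypoints",
    "clean_track",
    "px_to_cm",
    "cm_to_px",
    "fit_px_per_cm",
    "GAZE_PARTS",
]

#: bodyparts required for visual-field (eye-use) analysis
GAZE_PARTS = ("beak", "left_eye", "right_eye")

COORDS = ("x", "y", "likelihood")


class ParseError(ValueError):
    """Malformed keypoint CSV (bad header, ragged row, non-numeric cell)."""


@dataclass(frozen=True)
class KeypointTable:
    """Time-indexed bodypart coordinates with per-point confidence.

    ``data`` has a two-level column index (bodypart, coord) with coords
    x, y, likelihood; rows are frames 0..n-1 (frame k is at time k/fps).
    ``units`` is "px" for raw tracks and "cm" after calibration.
    """

    data: pd.DataFrame
    fps: float
    scorer: str = "imprintkit"
    units: str = "px"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        lk = self.data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        if np.nanmin(lk, initial=1.0) < 0 or np.nanmax(lk, initial=0.0) > 1:
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def bodyparts(self) -> tuple[str, ...]:
        return tuple(self.data.columns.get_level_values(0).unique())

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) float array of a bodypart's coordinates (NaN = masked)."""
        return self.data[part][["x", "y"]].to_numpy(float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.data[(part, "likelihood")].to_numpy(float)

    def head_center(self) -> np.ndarray:
        """Head reference point: the ``head_center`` part when tracked,
        otherwise the midpoint of the two eyes."""
        if "head_center" in self.bodyparts:
            return self.xy("head_center")
        return (self.xy("left_eye") + self.xy("right_eye")) / 2.0

    @staticmethod
    def from_arrays(
        parts: dict[str, np.ndarray], fps: float, scorer: str = "imprintkit",
        units: str = "px",
    ) -> "KeypointTable":
        """Build a table from a {bodypart: (n, 3) array of x, y, likelihood}."""
        cols = {}
        for name, arr in parts.items():
            arr = np.asarray(arr, float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"part {name!r}: expected shape (n, 3)")
            for j, coord in enumerate(COORDS):
                cols[(name, coord)] = arr[:, j]
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
        return KeypointTable(data=df, fps=fps, scorer=scorer, units=units)


def read_keypoints(path: str | Path, fps: float) -> KeypointTable:
    """Parse a DeepLabCut-dialect CSV into a :class:`KeypointTable`.

    Expects the three header rows (scorer / bodyparts / coords) and an
    x, y, likelihood triplet per bodypart. Raises :class:`ParseError`
    naming the offending row/column on malformed input.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise ParseError(f"{path.name}: fewer than 3 header rows")
    labels = [r[0] if r else "" for r in rows[:3]]
    for i, expected in enumerate(("scorer", "bodyparts", "coords")):
        if labels[i] != expected:
            raise ParseError(
                f"{path.name}: header row {i + 1} should start with "
                f"{expected!r}, found {labels[i]!r}"
            )
    scorer_row, parts_row, coords_row = rows[0][1:], rows[1][1:], rows[2][1:]
    width = len(parts_row)
    if len(coords_row) != width or len(scorer_row) != width:
        raise ParseError(f"{path.name}: header rows have differing widths")
    if width == 0 or width % 3:
        raise ParseError(
            f"{path.name}: expected x,y,likelihood triplets, got {width} columns"
        )
    for j in range(0, width, 3):
        if tuple(coords_row[j : j + 3]) != COORDS:
            raise ParseError(
                f"{path.name}: columns {j + 2}-{j + 4} must be x,y,likelihood "
                f"for bodypart {parts_row[j]!r}"
            )
        if len(set(parts_row[j : j + 3])) != 1:
            raise ParseError(
                f"{path.name}: bodypart labels disagree within triplet at "
                f"column {j + 2}"
            )
    scorer = scorer_row[0] if scorer_row else "unknown"
    parts = [parts_row[j] for j in range(0, width, 3)]

    values = np.empty((len(rows) - 3, width), dtype=float)
    for i, row in enumerate(rows[3:], start=4):
        if len(row) != width + 1:
            raise ParseError(
                f"{path.name}: row {i} has {len(row)} cells, expected {width + 1}"
            )
        for j, cell in enumerate(row[1:]):
            if cell == "":
                values[i - 4, j] = np.nan
                continue
            try:
                values[i - 4, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric cell {cell!r} at row {i}, "
                    f"column {j + 2}"
                ) from None

    arrays = {p: values[:, 3 * k : 3 * k + 3] for k, p in enumerate(parts)}
    return KeypointTable.from_arrays(arrays, fps=fps, scorer=scorer)


def write_keypoints(table: KeypointTable, path: str | Path) -> None:
    """Write a table in the DeepLabCut CSV dialect (inverse of
    :func:`read_keypoints`; floats are written with repr so the round trip
    is byte-stable)."""

    def fmt(x: float) -> str:
        return "" if np.isnan(x) else repr(float(x))

    parts = table.bodyparts
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [table.scorer] * (3 * len(parts)))
        w.writerow(["bodyparts"] + [p for p in parts for _ in COORDS])
        w.writerow(["coords"] + list(COORDS) * len(parts))
        mat = table.data.to_numpy(float)
        for k in range(table.n_frames):
            w.writerow([k] + [fmt(v) for v in mat[k]])


def clean_track(
    table: KeypointTable,
    min_likelihood: float = 0.9,
    max_gap_frames: int | None = None,
) -> KeypointTable:
    """Mask low-confidence points and bridge short gaps.

    Points with likelihood below ``min_likelihood`` get NaN coordinates.
    Interior NaN runs of at most ``max_gap_frames`` frames (default: one
    second's worth) are filled by linear interpolation between the valid
    neighbours, and their likelihood is raised to ``min_likelihood`` so the
    fill survives re-cleaning — the operation is idempotent. Longer runs
    stay masked and are excluded from downstream durations.
    """
    if not 0 <= min_likelihood <= 1:
        raise ValueError("min_likelihood must be in [0, 1]")
    if max_gap_frames is None:
        max_gap_frames = round(table.fps)
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")

    df = table.data.copy()
    for part in table.bodyparts:
        like = df[(part, "likelihood")].to_numpy(float).copy()
        x = df[(part, "x")].to_numpy(float).copy()
        y = df[(part, "y")].to_numpy(float).copy()
        bad = (like < min_likelihood) | np.isnan(x) | np.isnan(y)
        x[bad] = np.nan
        y[bad] = np.nan
        for start, stop in _nan_runs(bad):
            length = stop - start
            if length > max_gap_frames or start == 0 or stop == len(bad):
                continue  # too long, or no anchor on one side
            ts = np.arange(start, stop)
            for arr in (x, y):
                arr[start:stop] = np.interp(
                    ts, [start - 1, stop], [arr[start - 1], arr[stop]]
                )
            like[start:stop] = np.maximum(like[start:stop], min_likelihood)
        df[(part, "x")] = x
        df[(part, "y")] = y
        df[(part, "likelihood")] = like
    return replace(table, data=df)


def _nan_runs(bad: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of consecutive True runs."""
    padded = np.concatenate([[False], bad, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def px_to_cm(table: KeypointTable, geometry: ArenaGeometry) -> KeypointTable:
    """Convert a pixel-space table to arena centimetres (affine, invertible)."""
    if table.units == "cm":
        return table
    df = table.data.copy()
    ox, oy = geometry.origin_px
    for part in table.bodyparts:
        df[(part, "x")] = (df[(part, "x")] - ox) / geometry.px_per_cm
        df[(part, "y")] = (df[(part, "y")] - oy) / geometry.px_per_cm
    return replace(table, data=df, units="cm")


def cm_to_px(table: KeypointTable, geometry: ArenaGeometry) -> KeypointTable:
    """Inverse of :func:`px_to_cm`."""
    if table.units == "px":
        return table
    df = table.data.copy()
    ox, oy = geometry.origin_px
    for part in table.bodyparts:
        df[(part, "x")] = df[(part, "x")] * geometry.px_per_cm + ox
        df[(part, "y")] = df[(part, "y")] * geometry.px_per_cm + oy
    return replace(table, data=df, units="px")


def fit_px_per_cm(
    arena_length_px: float, length_cm: float = 90.0, origin_x_px: float = 0.0
) -> float:
    """Isotropic scale from the arena's screen-to-screen extent in the image.

    ``arena_length_px`` is the pixel x of the right-screen wall,
    ``origin_x_px`` that of the left-screen wall; the scale maps that span
    onto the known arena length (90 cm by default). With the fitted scale
    a corner pixel at the far wall converts to x = length_cm.
    """
    span = arena_length_px - origin_x_px
    if span <= 0 or length_cm <= 0:
        raise ValueError("arena span and length_cm must be positive")
    return span / length_cm
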