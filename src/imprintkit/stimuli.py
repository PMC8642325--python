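"""Controlled numerosity stimuli: dot arrays with a prescribed total area.

In natural scenes the total area of similar elements covaries with their
number, which confounds numerosity experiments: an animal preferring "more
dots" may simply prefer "more white". These generators decouple the two.
The inverse covariation scheme holds the product ``n * TA`` constant across
a stimulus series, so total area varies *opposite* to numerosity — e.g.
anchoring at n=5 with TA=600 px^2 gives 300 px^2 at n=10 and 200 px^2 at
n=15.

:func:`measure_array` re-derives element count, foreground area, density
and convex-hull extent from the raster alone (flood fill / pixel counting),
independent of how the image was generated, so it doubles as an oracle for
the generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "StimulusSpec",
    "StimulusImage",
    "ArrayMeasurement",
    "CapacityError",
    "inverse_scheme_total_area",
    "generate_array",
    "measure_array",
    "save_png",
    "load_png",
]


class CapacityError(RuntimeError):
    """Raised when the requested elements cannot be placed without overlap."""


def inverse_scheme_total_area(n: int, anchor_n: int, anchor_ta: float) -> float:
    """Total area (px^2) for an n-element member of an inverse-covariation series.

    The series is anchored at (``anchor_n``, ``anchor_ta``) and keeps the
    product TA * n constant, so TA(n) = anchor_n * anchor_ta / n: total
    area decreases exactly as numerosity increases.
    """
    if n <= 0 or anchor_n <= 0 or anchor_ta <= 0:
        raise ValueError("n, anchor_n and anchor_ta must all be positive")
    return anchor_n * anchor_ta / n


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one numerosity array.

    Each of the ``n`` elements gets area ``total_area_px2 / n`` (homogeneous
    arrays); ``min_gap_px`` is the minimum clearance between element edges.
    ``element_shape='square'`` uses integer-sided squares whose measured
    area is exact, useful when rasterization tolerance is unwanted.
    """

    n: int
    total_area_px2: float
    canvas_w_px: int = 800
    canvas_h_px: int = 600
    element_shape: str = "disc"  # "disc" | "square"
    min_gap_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.total_area_px2 <= 0:
            raise ValueError("total_area_px2 must be positive")
        if self.element_shape not in ("disc", "square"):
            raise ValueError("element_shape must be 'disc' or 'square'")
        if self.canvas_w_px < 1 or self.canvas_h_px < 1:
            raise ValueError("canvas dimensions must be positive")


@dataclass(frozen=True)
class StimulusImage:
    """A rasterized numerosity array (white elements on black)."""

    raster: np.ndarray  # bool, shape (h, w)
    element_centers: tuple[tuple[float, float], ...]  # (x, y) px
    element_area_px2: float  # nominal per-element area
    spec: StimulusSpec


@dataclass(frozen=True)
class ArrayMeasurement:
    """Properties re-measured from a raster (independent of the generator)."""

    count: int
    area_px2: int
    density_per_px2: float  # count / convex hull area (nan if degenerate)
    hull_span_px: float  # largest extent of the foreground hull
    hull_area_px2: float


_MAX_PLACEMENT_TRIES = 10_000


def generate_array(spec: StimulusSpec) -> StimulusImage:
    """Place and rasterize ``spec.n`` non-overlapping elements, seeded.

    Disc elements get radius sqrt(TA / (n * pi)), squares an integer side
    close to sqrt(TA / n). Centres come from seeded rejection sampling
    honouring ``min_gap_px``; identical specs always produce identical
    rasters. Raises :class:`CapacityError` when the canvas cannot hold the
    requested configuration within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    per_area = spec.total_area_px2 / spec.n
    if spec.element_shape == "disc":
        radius = math.sqrt(per_area / math.pi)
        half_extent = radius
        min_center_dist = 2 * radius + spec.min_gap_px
    else:
        side = max(1, round(math.sqrt(per_area)))
        half_extent = side / 2.0
        min_center_dist = side + spec.min_gap_px
        per_area = float(side * side)

    w, h = spec.canvas_w_px, spec.canvas_h_px
    lo_x, hi_x = half_extent, w - half_extent
    lo_y, hi_y = half_extent, h - half_extent
    if lo_x >= hi_x or lo_y >= hi_y:
        raise CapacityError(
            f"element extent {2 * half_extent:.1f} px does not fit the "
            f"{w}x{h} canvas"
        )

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.n:
        if tries >= _MAX_PLACEMENT_TRIES:
            raise CapacityError(
                f"placed only {len(centers)}/{spec.n} elements after "
                f"{_MAX_PLACEMENT_TRIES} tries: min_gap_px={spec.min_gap_px:g} "
                f"with per-element area {per_area:.1f} px^2 exceeds the "
                f"{w}x{h} canvas capacity"
            )
        tries += 1
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        if all(
            math.hypot(cx - px, cy - py) >= min_center_dist for px, py in centers
        ):
            centers.append((cx, cy))

    raster = np.zeros((h, w), dtype=bool)
    for cx, cy in centers:
        if spec.element_shape == "disc":
            _stamp_disc(raster, cx, cy, radius)
        else:
            _stamp_square(raster, cx, cy, side)

    return StimulusImage(
        raster=raster,
        element_centers=tuple(centers),
        element_area_px2=per_area,
        spec=spec,
    )


def _stamp_disc(raster: np.ndarray, cx: float, cy: float, r: float) -> None:
    # rasterize only the bounding box; pixel (i, j) is foreground when its
    # centre lies inside the disc
    h, w = raster.shape
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r * r
    raster[y0:y1, x0:x1] |= mask


def _stamp_square(raster: np.ndarray, cx: float, cy: float, side: int) -> None:
    x0 = int(round(cx - side / 2.0))
    y0 = int(round(cy - side / 2.0))
    raster[y0 : y0 + side, x0 : x0 + side] = True


def measure_array(img: StimulusImage | np.ndarray) -> ArrayMeasurement:
    """Re-measure an array from its raster alone.

    Count is by 8-connected flood fill, area by foreground pixel count,
    density by count / convex-hull area of the foreground, span by the
    largest pairwise distance between hull vertices. Degenerate rasters
    (empty, or hull-collapsed) report nan density/span.
    """
    raster = img.raster if isinstance(img, StimulusImage) else np.asarray(img, bool)
    n_comp = int(ndimage.label(raster, structure=np.ones((3, 3), int))[1])
    area = int(raster.sum())
    if area == 0:
        return ArrayMeasurement(0, 0, float("nan"), float("nan"), float("nan"))
    ys, xs = np.nonzero(raster)
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
        diffs = verts[:, None, :] - verts[None, :, :]
        span = float(np.sqrt((diffs**2).sum(-1)).max())
        hull_area = float(hull.volume)  # 2-D ConvexHull: volume is the area
        density = n_comp / hull_area if hull_area > 0 else float("nan")
    except QhullError:  # fewer than 3 points, or collinear foreground
        span = float(np.ptp(pts, axis=0).max())
        hull_area = 0.0
        density = float("nan")
    return ArrayMeasurement(n_comp, area, density, span, hull_area)


def save_png(img: StimulusImage, path: str | Path, sidecar: bool = True) -> None:
    """Write an 8-bit grayscale PNG (white elements on black) plus an
    optional JSON sidecar carrying the spec, the centres and the measured
    properties."""
    path = Path(path)
    Image.fromarray(img.raster.astype(np.uint8) * 255, mode="L").save(path)
    if sidecar:
        m = measure_array(img)
        payload = {
            "spec": asdict(img.spec),
            "element_centers": [list(c) for c in img.element_centers],
            "element_area_px2": img.element_area_px2,
            "measured": asdict(m),
        }
        path.with_suffix(".json").write_text(json.dumps(payload, indent=1))


def load_png(path: str | Path) -> np.ndarray:
    """Read a PNG back as a boolean raster (foreground = value > 127)."""
    return np.asarray(Image.open(path).convert("L")) > 127
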