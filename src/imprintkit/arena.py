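"""Arena geometry for the two-screen imprinting cage.

The apparatus is a rectangular cage with one monitor screen at each short
wall. The screens are the only light source, so the whole arena is defined
by the screen-to-screen axis: x runs from the left screen (x = 0) to the
right screen (x = length_cm). The camera looks straight down, so pixel
coordinates follow the image convention (origin top-left, y downward) and a
single isotropic pixel-per-centimetre scale maps tracks into arena
centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ArenaGeometry"]


@dataclass(frozen=True)
class ArenaGeometry:
    """Physical layout of the dual-choice cage.

    Parameters
    ----------
    length_cm : float
        Distance between the two screens (the long, x axis). Default 90 cm.
    width_cm : float
        Width of the cage (y axis). Default 60 cm.
    px_per_cm : float
        Isotropic camera scale. The default of 7 px/cm puts a 90 cm arena
        in ~630 px, matching a 640x480 overhead webcam.
    zone_depth_cm : float
        Depth of each stimulus zone measured from its screen. The default
        30 cm splits the 90 cm arena into thirds.
    origin_px : tuple of float
        Pixel coordinates of the arena corner nearest the left screen.
    """

    length_cm: float = 90.0
    width_cm: float = 60.0
    px_per_cm: float = 7.0
    zone_depth_cm: float = 30.0
    origin_px: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("arena length_cm and width_cm must be positive")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if self.zone_depth_cm <= 0:
            raise ValueError("zone_depth_cm must be positive")
        if 2 * self.zone_depth_cm > self.length_cm:
            raise ValueError(
                "stimulus zones overlap: 2 * zone_depth_cm exceeds length_cm"
            )

    def screen_x_cm(self, side: str) -> float:
        """x coordinate of a screen plane ('left' -> 0, 'right' -> length)."""
        if side == "left":
            return 0.0
        if side == "right":
            return self.length_cm
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def screen_center_cm(self, side: str, y_cm: float | None = None) -> tuple[float, float]:
        """Point on a screen used as the gaze target.

        By default the point is at the chick's own y (``y_cm``), i.e. the
        screen is treated as a wall-spanning target; pass ``y_cm=None`` to
        use the geometric screen centre.
        """
        y = self.width_cm / 2.0 if y_cm is None else y_cm
        return (self.screen_x_cm(side), y)
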