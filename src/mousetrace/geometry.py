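"""Screen geometry of the two-choice mouse-tracking display.

All coordinates live in the *reference* pixel frame (800 x 600), with the
screen-native convention that y increases downward.  A participant's actual
display is the reference frame multiplied by a per-session ``display_scale``;
conversion into analysis coordinates happens in :mod:`mousetrace.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class GeometryError(ValueError):
    """Raised when a screen geometry is degenerate or inconsistent."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Layout of home box and target areas on the reference screen.

    The default layout places a 60 x 60 px home box at the bottom center and
    two target areas in the upper left / upper right, mirror-symmetric about
    the vertical midline.  Target entry is detected on a circle of
    ``target_entry_radius`` px around the target center, distinct from the
    rectangular target area used for clicking.
    """

    ref_width: float = 800.0
    ref_height: float = 600.0
    home_center: tuple[float, float] = (400.0, 570.0)
    home_size: tuple[float, float] = (60.0, 60.0)
    left_target_center: tuple[float, float] = (100.0, 100.0)
    right_target_center: tuple[float, float] = (700.0, 100.0)
    target_size: tuple[float, float] = (100.0, 100.0)
    target_entry_radius: float = 20.0
    display_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.display_scale <= 0:
            raise GeometryError("display_scale must be strictly positive")
        for name in ("home_size", "target_size"):
            w, h = getattr(self, name)
            if w <= 0 or h <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.target_entry_radius <= 0:
            raise GeometryError("target_entry_radius must be strictly positive")
        hx, hy = self.home_center
        lx, ly = self.left_target_center
        rx, ry = self.right_target_center
        # screen-native frame: "above" means smaller y
        if not (ly < hy and ry < hy):
            raise GeometryError("target centers must lie above the home center")
        mid = self.ref_width / 2.0
        if abs((mid - lx) - (rx - mid)) > 1e-9 or abs(ly - ry) > 1e-9:
            raise GeometryError(
                "left/right targets must be mirror-symmetric about the midline"
            )
        if abs(rx - hx) < 1e-12 or abs(ry - hy) < 1e-12:
            raise GeometryError("home-to-target distance must be nonzero on both axes")

    @property
    def horizontal_span_px(self) -> float:
        """|home -> target| horizontal distance in reference px (maps to 100 xu)."""
        return abs(self.right_target_center[0] - self.home_center[0])

    @property
    def vertical_span_px(self) -> float:
        """|home -> target| vertical distance in reference px (maps to 200 xu)."""
        return abs(self.home_center[1] - self.right_target_center[1])

    def target_center(self, side: str) -> tuple[float, float]:
        if side == "left":
            return self.left_target_center
        if side == "right":
            return self.right_target_center
        raise ValueError(f"unknown side: {side!r}")

    def with_scale(self, display_scale: float) -> "ScreenGeometry":
        return replace(self, display_scale=display_scale)


def image_geometry() -> ScreenGeometry:
    """Geometry variant with 100 x 100 px image targets."""
    return ScreenGeometry(target_size=(100.0, 100.0))


def text_geometry() -> ScreenGeometry:
    """Geometry variant with 250 x 50 px text targets."""
    return ScreenGeometry(target_size=(250.0, 50.0))


GEOMETRY_VARIANTS = {"image": image_geometry, "text": text_geometry}
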