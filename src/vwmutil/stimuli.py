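"""Stimulus geometry and color conventions for the model-reconstruction task.

The task presents a *target model*: 1, 2 or 4 colored squares (0.85 deg of
visual angle per side) scattered without overlap inside a 13.47 x 13.47 deg
black frame.  Square hues come from a wheel of 256 evenly spaced HSV hues at
full saturation and value.  All coordinates in this package are degrees of
visual angle with the origin at the frame center, x rightward and y upward;
``GeometryConfig.ppd`` (pixels per degree) converts to and from pixel logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryConfig",
    "SquareItem",
    "TargetModel",
    "N_PALETTE_HUES",
    "build_palette",
    "nearest_palette_index",
    "generate_target_model",
    "wheel_click_to_hue",
    "normalize_hue_deg",
    "circular_distance_deg",
]

#: Number of hues on the response color wheel.
N_PALETTE_HUES = 256


@dataclass(frozen=True)
class GeometryConfig:
    """Display geometry in degrees of visual angle (60 cm viewing distance).

    ``min_gap_deg`` is extra clearance beyond bare non-overlap; the task only
    requires that squares do not overlap, so the default is 0.  ``ppd`` is the
    pixels-per-degree factor used when ingesting pixel-based event logs.
    """

    frame_deg: float = 13.47
    square_deg: float = 0.85
    min_gap_deg: float = 0.0
    ppd: float = 36.0
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.frame_deg <= 0 or self.square_deg <= 0:
            raise ValueError("frame_deg and square_deg must be positive")
        if self.min_gap_deg < 0:
            raise ValueError("min_gap_deg must be >= 0")
        if self.square_deg > self.frame_deg:
            raise ValueError("square cannot exceed the frame")

    @property
    def half_extent_deg(self) -> float:
        """Largest |center coordinate| keeping a square fully inside the frame."""
        return (self.frame_deg - self.square_deg) / 2.0


def normalize_hue_deg(hue_deg: float) -> float:
    """Map an angle in degrees into [0, 360)."""
    return float(hue_deg) % 360.0


def circular_distance_deg(a_deg: float, b_deg: float) -> float:
    """Minimal angular distance between two hues, in degrees, in [0, 180]."""
    d = abs(normalize_hue_deg(a_deg) - normalize_hue_deg(b_deg))
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class SquareItem:
    """One colored square: center position (deg visual angle) and hue (deg).

    The hue renders as HSV with saturation = 100 and value = 100.
    """

    x_deg: float
    y_deg: float
    hue_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_deg < 360.0:
            object.__setattr__(self, "hue_deg", normalize_hue_deg(self.hue_deg))


@dataclass(frozen=True)
class TargetModel:
    """The to-be-reconstructed array of colored squares for one trial."""

    items: tuple[SquareItem, ...]
    set_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) != self.set_size:
            raise ValueError(
                f"set_size={self.set_size} but {len(self.items)} items given"
            )

    def validate_geometry(self, geometry: GeometryConfig | None = None) -> None:
        """Raise ``ValueError`` if any item leaves the frame or two overlap.

        Overlap is checked with the Chebyshev metric (max of |dx|, |dy|),
        which is the exact non-overlap condition for axis-aligned squares and
        implies the weaker Euclidean center-distance criterion.
        """
        geometry = geometry or GeometryConfig()
        half = geometry.half_extent_deg
        for i, it in enumerate(self.items):
            if abs(it.x_deg) > half or abs(it.y_deg) > half:
                raise ValueError(f"item {i} not fully inside the frame")
        min_sep = geometry.square_deg + geometry.min_gap_deg
        for i in range(len(self.items)):
            for j in range(i + 1, len(self.items)):
                dx = abs(self.items[i].x_deg - self.items[j].x_deg)
                dy = abs(self.items[i].y_deg - self.items[j].y_deg)
                if max(dx, dy) < min_sep:
                    raise ValueError(f"items {i} and {j} overlap")

    def positions(self) -> np.ndarray:
        """(set_size, 2) array of item centers."""
        return np.array([[it.x_deg, it.y_deg] for it in self.items])

    def hues(self) -> np.ndarray:
        return np.array([it.hue_deg for it in self.items])


def build_palette(n_hues: int = N_PALETTE_HUES) -> np.ndarray:
    """Evenly spaced hue wheel: k * (360 / n_hues) degrees for k = 0..n-1."""
    if n_hues < 1:
        raise ValueError("n_hues must be >= 1")
    return np.arange(n_hues) * (360.0 / n_hues)


def nearest_palette_index(hue_deg: float, palette: np.ndarray) -> int:
    """Index of the palette hue circularly closest to ``hue_deg``."""
    d = np.abs(palette - normalize_hue_deg(hue_deg))
    d = np.minimum(d, 360.0 - d)
    return int(np.argmin(d))


def generate_target_model(
    set_size: int,
    rng: np.random.Generator,
    geometry: GeometryConfig | None = None,
    palette: np.ndarray | None = None,
) -> TargetModel:
    """Randomly place ``set_size`` non-overlapping squares inside the frame.

    Positions are drawn by rejection sampling (uniform over in-frame centers,
    rejecting overlaps); hues are drawn uniformly from the palette.

    Raises
    ------
    RuntimeError
        If the attempt budget is exhausted (geometry too crowded to satisfy).
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    geometry = geometry or GeometryConfig()
    if palette is None:
        palette = build_palette()
    half = geometry.half_extent_deg
    min_sep = geometry.square_deg + geometry.min_gap_deg

    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < set_size:
        if attempts >= geometry.max_attempts:
            raise RuntimeError(
                f"could not place {set_size} non-overlapping squares in "
                f"{geometry.max_attempts} attempts; geometry too crowded"
            )
        attempts += 1
        x = rng.uniform(-half, half)
        y = rng.uniform(-half, half)
        if all(max(abs(x - cx), abs(y - cy)) >= min_sep for cx, cy in centers):
            centers.append((x, y))

    hues = palette[rng.integers(0, len(palette), size=set_size)]
    items = tuple(
        SquareItem(x_deg=c[0], y_deg=c[1], hue_deg=float(h))
        for c, h in zip(centers, hues)
    )
    model = TargetModel(items=items, set_size=set_size)
    model.validate_geometry(geometry)
    return model


def wheel_click_to_hue(
    click_x: float,
    click_y: float,
    wheel_center: tuple[float, float] = (0.0, 0.0),
    zero_angle_deg: float = 0.0,
    direction: str = "counterclockwise",
) -> float:
    """Convert a color-wheel click (pixels) to a hue angle in [0, 360).

    The wheel orientation is configurable: ``zero_angle_deg`` is the polar
    angle (counterclockwise from +x, y upward) at which hue 0 sits, and
    ``direction`` says which way hue increases around the wheel.  The click
    radius is irrelevant; only the angle matters.

    Raises
    ------
    ValueError
        If the click is exactly at the wheel center (angle undefined), or
        ``direction`` is not recognised.
    """
    dx = click_x - wheel_center[0]
    dy = click_y - wheel_center[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("click at wheel center: hue angle undefined")
    if direction not in ("clockwise", "counterclockwise"):
        raise ValueError(f"unknown direction {direction!r}")
    angle = math.degrees(math.atan2(dy, dx)) - zero_angle_deg
    if direction == "clockwise":
        angle = -angle
    return normalize_hue_deg(angle)
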