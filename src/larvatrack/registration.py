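"""Fiducial-based frame registration and dish localization.

The imaging template carries circular alignment dots.  Detected dot
centroids are matched to the template's reference dots (by sorted-x
correspondence) and a translation + uniform-scale transform is estimated by
least squares — rotation is excluded because the template is mechanically
seated and only position and zoom vary between assays.  Weighing-dish
regions are defined in template coordinates relative to the left-most dot
and mapped into each recording's frame coordinates through the inverse
transform.

Coordinate convention: pixel origin at the top-left, x rightward (columns),
y downward (rows), 0-based integer pixel centers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import InputError, LayoutError, RegistrationError
from .frames_io import FrameGrid

__all__ = [
    "Point",
    "SimilarityTransform",
    "DishSpec",
    "DishLayout",
    "DishRegion",
    "detect_alignment_dots",
    "estimate_transform",
    "locate_dishes",
    "circular_components",
]


@dataclass(frozen=True)
class Point:
    """A 2-D location in pixel coordinates."""

    x: float
    y: float

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass
class SimilarityTransform:
    """p ↦ scale·p + shift, mapping frame coordinates onto template coordinates."""

    scale: float
    shift_x: float
    shift_y: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise RegistrationError(f"transform scale must be positive, got {self.scale}")

    def apply(self, p: Point) -> Point:
        return Point(self.scale * p.x + self.shift_x, self.scale * p.y + self.shift_y)

    def apply_xy(self, x: float, y: float) -> tuple[float, float]:
        return self.scale * x + self.shift_x, self.scale * y + self.shift_y

    def invert(self) -> "SimilarityTransform":
        s = 1.0 / self.scale
        return SimilarityTransform(s, -self.shift_x * s, -self.shift_y * s)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, 0.0)


@dataclass(frozen=True)
class DishSpec:
    """An axis-aligned square dish region in template coordinates."""

    dish_id: str
    center: Point
    half_width_px: float

    def __post_init__(self) -> None:
        if self.half_width_px <= 0:
            raise LayoutError(f"dish {self.dish_id}: half_width must be positive")


@dataclass
class DishLayout:
    """Template geometry: reference dots plus non-overlapping dish squares.

    Dish positions are interpreted relative to the left-most reference dot,
    which anchors the template in every aligned frame.
    """

    reference_dots: list[Point]
    dishes: list[DishSpec]

    def __post_init__(self) -> None:
        if len(self.reference_dots) < 2:
            raise LayoutError("layout needs at least 2 reference dots")
        xs = sorted(p.x for p in self.reference_dots)
        if len(xs) > 1 and xs[0] == xs[1]:
            raise LayoutError("left-most reference dot is not unique (tied minimal x)")
        ids = [d.dish_id for d in self.dishes]
        if len(set(ids)) != len(ids):
            raise LayoutError(f"duplicate dish ids in layout: {ids}")
        for i, a in enumerate(self.dishes):
            for b in self.dishes[i + 1 :]:
                if (
                    abs(a.center.x - b.center.x) < a.half_width_px + b.half_width_px
                    and abs(a.center.y - b.center.y) < a.half_width_px + b.half_width_px
                ):
                    raise LayoutError(f"dish regions {a.dish_id} and {b.dish_id} overlap")

    @property
    def leftmost_dot(self) -> Point:
        return min(self.reference_dots, key=lambda p: p.x)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "reference_dots": [{"x": p.x, "y": p.y} for p in self.reference_dots],
            "dishes": [
                {"id": d.dish_id, "cx": d.center.x, "cy": d.center.y, "half_width": d.half_width_px}
                for d in self.dishes
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DishLayout":
        p = Path(source)
        try:
            text = p.read_text() if p.exists() else str(source)
        except OSError as exc:
            raise InputError(f"cannot read layout {source}: {exc}") from exc
        try:
            doc = json.loads(text)
            dots = [Point(float(d["x"]), float(d["y"])) for d in doc["reference_dots"]]
            dishes = [
                DishSpec(str(d["id"]), Point(float(d["cx"]), float(d["cy"])), float(d["half_width"]))
                for d in doc["dishes"]
            ]
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise InputError(f"malformed dish layout: {exc}") from exc
        return cls(dots, dishes)


@dataclass(frozen=True)
class DishRegion:
    """A dish's axis-aligned bounding box in frame coordinates (inclusive bounds)."""

    dish_id: str
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


def boundary_pixel_count(component: np.ndarray) -> int:
    """Number of component pixels with at least one 4-neighbour outside it."""
    padded = np.pad(component.astype(bool), 1)
    core = padded[1:-1, 1:-1]
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return int(np.count_nonzero(core & ~interior))


def circular_components(
    mask: np.ndarray,
    radius_range_px: tuple[float, float],
    circularity_min: float = 0.6,
) -> list[tuple[Point, int, float]]:
    """Connected components that look like discs of radius within ``radius_range_px``.

    A component qualifies if its area lies in the disc-area band
    [π·rmin², π·rmax²] and its circularity 4π·area / perimeter² (perimeter
    taken as the boundary pixel count) is at least ``circularity_min``.
    Returns (centroid, area, circularity) sorted by x then y.
    """
    rmin, rmax = radius_range_px
    if not (0 < rmin < rmax):
        raise InputError(f"invalid radius range {radius_range_px}")
    area_min = math.pi * rmin * rmin
    area_max = math.pi * rmax * rmax
    out: list[tuple[Point, int, float]] = []
    for region in regionprops(label(mask, connectivity=2)):
        area = int(region.area)
        if not (area_min <= area <= area_max):
            continue
        perim = boundary_pixel_count(region.image)
        circ = 4.0 * math.pi * area / (perim * perim) if perim else 0.0
        if circ < circularity_min:
            continue
        cy, cx = region.centroid
        out.append((Point(float(cx), float(cy)), area, float(circ)))
    out.sort(key=lambda t: (t[0].x, t[0].y))
    return out


def binarize_features(pixels: np.ndarray, polarity: str = "dark-on-light") -> np.ndarray:
    """Foreground mask via Otsu's threshold; relative, so invariant to intensity rescaling."""
    if polarity not in ("dark-on-light", "light-on-dark"):
        raise InputError(f"unknown polarity {polarity!r}")
    t = threshold_otsu(pixels)
    return pixels < t if polarity == "dark-on-light" else pixels > t


def detect_alignment_dots(
    frame: FrameGrid,
    polarity: str = "dark-on-light",
    radius_range_px: tuple[float, float] = (4.0, 8.0),
    circularity_min: float = 0.6,
) -> list[Point]:
    """Centroids of the template's circular alignment dots, sorted by x then y."""
    mask = binarize_features(frame.pixels, polarity)
    comps = circular_components(mask, radius_range_px, circularity_min)
    points = [c[0] for c in comps]
    if len(points) < 2:
        raise RegistrationError(
            f"found {len(points)} alignment dot(s); need at least 2 "
            f"(candidates: {[(round(p.x, 1), round(p.y, 1)) for p in points]})"
        )
    return points


def estimate_transform(
    detected: Sequence[Point], reference: Sequence[Point]
) -> SimilarityTransform:
    """Least-squares translation + uniform scale mapping detected → reference dots.

    Correspondence is by sorted-x order; both lists must have equal length ≥ 2.
    """
    if len(detected) != len(reference):
        raise RegistrationError(
            f"detected {len(detected)} dots but template has {len(reference)}"
        )
    if len(detected) < 2:
        raise RegistrationError("need at least 2 corresponding dots")
    p = np.array([[pt.x, pt.y] for pt in sorted(detected, key=lambda q: (q.x, q.y))])
    q = np.array([[pt.x, pt.y] for pt in sorted(reference, key=lambda q: (q.x, q.y))])
    p_mean = p.mean(axis=0)
    q_mean = q.mean(axis=0)
    pc = p - p_mean
    qc = q - q_mean
    denom = float((pc * pc).sum())
    if denom == 0.0:
        raise RegistrationError("degenerate geometry: detected dots are coincident")
    scale = float((pc * qc).sum()) / denom
    if scale <= 0:
        raise RegistrationError(f"non-physical scale {scale:.4g} from dot correspondence")
    shift = q_mean - scale * p_mean
    tf = SimilarityTransform(scale, float(shift[0]), float(shift[1]))
    resid = q - (scale * p + shift)
    tf.residual_rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tf


def locate_dishes(
    transform: SimilarityTransform,
    layout: DishLayout,
    frame_shape: tuple[int, int] | None = None,
) -> list[DishRegion]:
    """Map template dish squares into frame coordinates through the inverse transform.

    ``frame_shape`` is (height, width); when given, regions are clipped to the
    frame with a warning, and a region falling fully outside raises.
    """
    inv = transform.invert()
    regions: list[DishRegion] = []
    for dish in layout.dishes:
        cx, cy = inv.apply_xy(dish.center.x, dish.center.y)
        half = dish.half_width_px * inv.scale
        x0, x1 = cx - half, cx + half
        y0, y1 = cy - half, cy + half
        if frame_shape is not None:
            h, w = frame_shape
            if x1 < 0 or y1 < 0 or x0 > w - 1 or y0 > h - 1:
                raise LayoutError(
                    f"dish {dish.dish_id} maps fully outside the frame "
                    f"(x [{x0:.0f},{x1:.0f}], y [{y0:.0f},{y1:.0f}])"
                )
            cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
            cx1, cy1 = min(x1, w - 1.0), min(y1, h - 1.0)
            if (cx0, cy0, cx1, cy1) != (x0, y0, x1, y1):
                warnings.warn(
                    f"dish {dish.dish_id} clipped to frame bounds", stacklevel=2
                )
            x0, y0, x1, y1 = cx0, cy0, cx1, cy1
        regions.append(DishRegion(dish.dish_id, x0, y0, x1, y1))
    return regions
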