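"""Frame differencing, movement-blob extraction, and penny detection.

Each sampled frame is compared against the previous sampled frame (the
"comparison frame"); pixels whose absolute intensity change reaches the
threshold mark larval movement.  Because larvae are dark on a bright
diffuser, the *sign* of the change distinguishes the vacated body location
(brightened: the larva left) from the newly occupied one (darkened): that
polarity feeds the before/after split used by the closest-point matcher.

Stimulus administration is marked in the recording by a penny placed in the
field of view outside the dishes; it is detected as a dark disc and latched
from its first appearance onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.measure import label, regionprops

from .errors import InputError
from .frames_io import FrameGrid
from .registration import DishRegion, Point, binarize_features, circular_components

__all__ = [
    "DiffMask",
    "Blob",
    "PennyEvent",
    "frame_difference",
    "extract_movements",
    "detect_penny",
]

# Fraction of a component's mask pixels that must share one sign of intensity
# change for the blob to be called pure "before" (+1) or "after" (-1);
# components in between carry both body positions and use the major-axis rule.
POLARITY_PURITY = 0.7


@dataclass
class DiffMask:
    """Thresholded absolute frame difference plus the signed difference it came from."""

    mask: np.ndarray
    signed: np.ndarray
    threshold_used: float
    frame_pair: tuple[int, int]


@dataclass(frozen=True)
class Blob:
    """One contiguous movement component assigned to a dish.

    ``polarity`` is +1 for a vacated (before) location, -1 for a newly
    occupied (after) location, and 0 when the component mixes both (a larva
    whose old and new body positions overlap in one component).
    ``major_axis_px`` is the pixel extent along the component's principal
    axis, used to estimate displacement for mixed-polarity blobs.
    """

    centroid: Point
    pixel_count: int
    dish_id: str
    polarity: int = 0
    major_axis_px: float = 0.0


@dataclass
class PennyEvent:
    """First sampled frame index at which the penny is present; latched thereafter."""

    first_frame_index: int | None = None

    def present_at(self, frame_index: int) -> bool:
        return self.first_frame_index is not None and frame_index >= self.first_frame_index


def frame_difference(current: FrameGrid, comparison: FrameGrid, threshold: float) -> DiffMask:
    """Mask of pixels where |current − comparison| ≥ threshold."""
    if current.pixels.shape != comparison.pixels.shape:
        raise InputError(
            f"frame shape mismatch: {current.pixels.shape} vs {comparison.pixels.shape}"
        )
    if not (0.0 < threshold < 1.0):
        raise InputError(f"difference threshold must be in (0,1), got {threshold}")
    signed = current.pixels - comparison.pixels
    mask = np.abs(signed) >= threshold
    return DiffMask(
        mask=mask,
        signed=signed,
        threshold_used=float(threshold),
        frame_pair=(comparison.frame_index, current.frame_index),
    )


def _principal_extent(rows: np.ndarray, cols: np.ndarray) -> float:
    """Pixel extent of a component along its principal axis (max−min projection + 1)."""
    if rows.size == 1:
        return 1.0
    coords = np.column_stack([cols, rows]).astype(np.float64)
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords / coords.shape[0]
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]  # eigenvector of the largest eigenvalue
    proj = coords @ axis
    return float(proj.max() - proj.min() + 1.0)


def _component_polarity(signed_vals: np.ndarray) -> int:
    n_pos = int(np.count_nonzero(signed_vals > 0))
    n_neg = int(np.count_nonzero(signed_vals < 0))
    total = n_pos + n_neg
    if total == 0:
        return 0
    frac_pos = n_pos / total
    if frac_pos >= POLARITY_PURITY:
        return 1
    if frac_pos <= 1.0 - POLARITY_PURITY:
        return -1
    return 0


def _assign_dish(regions: Sequence[DishRegion], x: float, y: float) -> str | None:
    for r in regions:
        if r.contains(x, y):
            return r.dish_id
    return None


def _merge_group(blobs: list[Blob]) -> Blob:
    n = sum(b.pixel_count for b in blobs)
    x = sum(b.centroid.x * b.pixel_count for b in blobs) / n
    y = sum(b.centroid.y * b.pixel_count for b in blobs) / n
    pol_score = sum(b.polarity * b.pixel_count for b in blobs)
    pol = 1 if pol_score > 0 else (-1 if pol_score < 0 else 0)
    return Blob(
        centroid=Point(x, y),
        pixel_count=n,
        dish_id=blobs[0].dish_id,
        polarity=pol,
        major_axis_px=max(b.major_axis_px for b in blobs),
    )


def _merge_within_dish(blobs: list[Blob], merge_radius_px: float) -> list[Blob]:
    # union-find over centroid proximity; merged blob gets the
    # pixel-count-weighted centroid
    parent = list(range(len(blobs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            if blobs[i].centroid.distance_to(blobs[j].centroid) <= merge_radius_px:
                parent[find(i)] = find(j)
    groups: dict[int, list[Blob]] = {}
    for i, b in enumerate(blobs):
        groups.setdefault(find(i), []).append(b)
    return [_merge_group(g) if len(g) > 1 else g[0] for g in groups.values()]


def extract_movements(
    diff: DiffMask,
    dish_regions: Sequence[DishRegion],
    min_blob_px: int = 3,
    merge_radius_px: float = 0.0,
) -> list[Blob]:
    """8-connected movement components per dish.

    Components smaller than ``min_blob_px`` or whose centroid falls outside
    every dish are discarded.  Components within one dish whose centroids are
    within ``merge_radius_px`` are merged (pixel-count-weighted centroid);
    merging is off by default.  Blobs are returned sorted by dish then x.
    """
    if min_blob_px < 1:
        raise InputError(f"min_blob_px must be >= 1, got {min_blob_px}")
    lab = label(diff.mask, connectivity=2)
    per_dish: dict[str, list[Blob]] = {}
    for region in regionprops(lab):
        if region.area < min_blob_px:
            continue
        cy, cx = region.centroid
        dish = _assign_dish(dish_regions, float(cx), float(cy))
        if dish is None:
            continue
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        pol = _component_polarity(diff.signed[rows, cols])
        blob = Blob(
            centroid=Point(float(cx), float(cy)),
            pixel_count=int(region.area),
            dish_id=dish,
            polarity=pol,
            major_axis_px=_principal_extent(rows, cols),
        )
        per_dish.setdefault(dish, []).append(blob)
    out: list[Blob] = []
    for dish in sorted(per_dish):
        blobs = per_dish[dish]
        if merge_radius_px > 0 and len(blobs) > 1:
            blobs = _merge_within_dish(blobs, merge_radius_px)
        out.extend(sorted(blobs, key=lambda b: (b.centroid.x, b.centroid.y)))
    return out


def detect_penny(
    frame: FrameGrid,
    exclude_regions: Sequence[DishRegion] = (),
    radius_range_px: tuple[float, float] = (10.0, 14.0),
    circularity_min: float = 0.6,
) -> bool:
    """True iff a dark disc consistent with ``radius_range_px`` sits outside the dishes.

    The search region defaults to the whole frame minus the dish regions, so
    larval movement never masquerades as the stimulus marker.
    """
    mask = binarize_features(frame.pixels, "dark-on-light")
    for r in exclude_regions:
        y0, y1 = int(np.floor(r.y0)), int(np.ceil(r.y1)) + 1
        x0, x1 = int(np.floor(r.x0)), int(np.ceil(r.x1)) + 1
        mask[max(y0, 0) : y1, max(x0, 0) : x1] = False
    return len(circular_components(mask, radius_range_px, circularity_min)) > 0


def scan_penny(
    frames: Iterable[FrameGrid],
    exclude_regions: Sequence[DishRegion] = (),
    radius_range_px: tuple[float, float] = (10.0, 14.0),
    circularity_min: float = 0.6,
) -> PennyEvent:
    """Scan a recording for the penny and latch its first appearance."""
    for frame in frames:
        if detect_penny(frame, exclude_regions, radius_range_px, circularity_min):
            return PennyEvent(first_frame_index=frame.frame_index)
    return PennyEvent(first_frame_index=None)
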