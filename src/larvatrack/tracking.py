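"""Closest-point matching of movement locations and per-dish distance series.

Within each dish and frame pair, before/after movement locations are paired
greedily by globally smallest Euclidean distance (the closest-point rule),
subject to a maximum plausible step.  Matched pairs contribute their
centroid separation to the dish's distance traveled that second; a blob that
carries both body positions in one component (old and new overlapping)
contributes its principal-axis extent minus one body length instead.

Distances are reported in pixels at template scale — the registration
transform's scale factor converts frame-pixel displacements so that results
are comparable across recordings with different zoom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import Blob, PennyEvent
from .errors import InputError, PipelineError
from .frames_io import RESULTS_COLUMNS, Recording
from .registration import Point, SimilarityTransform

__all__ = [
    "MovementEvent",
    "SingleBlobEvent",
    "DishSeries",
    "match_points",
    "build_series",
    "series_from_results",
]


@dataclass(frozen=True)
class MovementEvent:
    """A matched before/after larva position pair (template coordinates)."""

    dish_id: str
    frame_pair: tuple[int, int]
    before: Point
    after: Point
    displacement_px: float


@dataclass(frozen=True)
class SingleBlobEvent:
    """A single-component movement whose displacement comes from the major-axis rule."""

    dish_id: str
    frame_pair: tuple[int, int]
    location: Point
    displacement_px: float
    major_axis_px: float


@dataclass
class DishSeries:
    """Per-second distance traveled for one dish (one replicate)."""

    dish_id: str
    condition_label: str = ""
    source_id: str = ""
    time_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    distance_px: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_fish_moved: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def cumulative(self, window_s: tuple[float, float], origin_s: float = 0.0) -> float:
        """Total distance over the half-open window [origin+w0, origin+w1)."""
        t0, t1 = window_s
        sel = (self.time_s >= origin_s + t0) & (self.time_s < origin_s + t1)
        return float(self.distance_px[sel].sum())

    @property
    def total_distance_px(self) -> float:
        return float(self.distance_px.sum())


def match_points(
    before: Sequence[Point],
    after: Sequence[Point],
    max_step_px: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy globally-closest-first bipartite matching with a distance gate.

    Repeatedly takes the unmatched (before, after) pair with the smallest
    Euclidean distance ≤ ``max_step_px``; ties break on lower before index,
    then lower after index.  Returns (pairs, unmatched_before, unmatched_after)
    as index lists.
    """
    if max_step_px <= 0:
        raise InputError(f"max_step_px must be positive, got {max_step_px}")
    candidates = []
    for i, b in enumerate(before):
        for j, a in enumerate(after):
            d = b.distance_to(a)
            if d <= max_step_px:
                candidates.append((d, i, j))
    candidates.sort()
    used_b: set[int] = set()
    used_a: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_b or j in used_a:
            continue
        pairs.append((i, j))
        used_b.add(i)
        used_a.add(j)
    unmatched_b = [i for i in range(len(before)) if i not in used_b]
    unmatched_a = [j for j in range(len(after)) if j not in used_a]
    return pairs, unmatched_b, unmatched_a


def _singleton_event(
    blob: Blob, pair: tuple[int, int], scale: float, tf: SimilarityTransform, body_length_px: float
) -> SingleBlobEvent:
    axis_template = blob.major_axis_px * scale
    disp = max(0.0, axis_template - body_length_px)
    x, y = tf.apply_xy(blob.centroid.x, blob.centroid.y)
    return SingleBlobEvent(
        dish_id=blob.dish_id,
        frame_pair=pair,
        location=Point(x, y),
        displacement_px=disp,
        major_axis_px=axis_template,
    )


def build_series(
    recording: Recording,
    blobs_per_frame: Sequence[Sequence[Blob]],
    penny: PennyEvent,
    max_step_px: float = 100.0,
    body_length_px: float = 8.0,
    transform: SimilarityTransform | None = None,
    dish_ids: Sequence[str] | None = None,
) -> tuple[list[DishSeries], pd.DataFrame, list[MovementEvent], list[SingleBlobEvent]]:
    """Accumulate per-dish per-second distance from movement blobs.

    ``blobs_per_frame[k]`` holds the blobs for frame pair (k, k+1), so its
    length must be len(recording) − 1.  Per dish and pair: pure-polarity
    blobs form the before (+1) / after (−1) lists for :func:`match_points`
    (the gate ``max_step_px`` is in template pixels and is rescaled into
    frame pixels through the transform); mixed-polarity and unmatched blobs
    become single-blob movements via the major-axis rule.  n_fish_moved is
    the number of matched pairs plus singletons.
    """
    n_pairs = len(recording) - 1
    if len(blobs_per_frame) != n_pairs:
        raise PipelineError(
            f"expected blob lists for {n_pairs} frame pairs, got {len(blobs_per_frame)}"
        )
    tf = transform if transform is not None else SimilarityTransform.identity()
    scale = tf.scale
    gate_frame_px = max_step_px / scale

    if dish_ids is None:
        seen = {b.dish_id for blobs in blobs_per_frame for b in blobs}
        dish_ids = sorted(seen)
    per_dish: dict[str, dict[str, list]] = {
        d: {"t": [], "dist": [], "n": [], "px": []} for d in dish_ids
    }
    events: list[MovementEvent] = []
    singles: list[SingleBlobEvent] = []
    rows: list[dict] = []

    for k in range(n_pairs):
        frame_index = k + 1
        time_s = frame_index / recording.sample_rate_hz
        pair = (k, k + 1)
        by_dish: dict[str, list[Blob]] = {d: [] for d in dish_ids}
        for b in blobs_per_frame[k]:
            if b.dish_id not in by_dish:
                raise PipelineError(f"blob in unknown dish {b.dish_id!r} at frame pair {pair}")
            by_dish[b.dish_id].append(b)
        for dish in dish_ids:
            blobs = by_dish[dish]
            before = [b for b in blobs if b.polarity > 0]
            after = [b for b in blobs if b.polarity < 0]
            mixed = [b for b in blobs if b.polarity == 0]
            pairs, ub, ua = match_points(
                [b.centroid for b in before], [b.centroid for b in after], gate_frame_px
            )
            dish_events: list[MovementEvent] = []
            for i, j in pairs:
                bx, by = tf.apply_xy(before[i].centroid.x, before[i].centroid.y)
                ax, ay = tf.apply_xy(after[j].centroid.x, after[j].centroid.y)
                bp, ap = Point(bx, by), Point(ax, ay)
                dish_events.append(
                    MovementEvent(dish, pair, bp, ap, displacement_px=bp.distance_to(ap))
                )
            dish_singles = [
                _singleton_event(b, pair, scale, tf, body_length_px)
                for b in mixed + [before[i] for i in ub] + [after[j] for j in ua]
            ]
            events.extend(dish_events)
            singles.extend(dish_singles)
            n_moved = len(dish_events) + len(dish_singles)
            dist = sum(e.displacement_px for e in dish_events) + sum(
                s.displacement_px for s in dish_singles
            )
            px = sum(b.pixel_count for b in blobs)
            d = per_dish[dish]
            d["t"].append(time_s)
            d["dist"].append(dist)
            d["n"].append(n_moved)
            d["px"].append(px)
            rows.append(
                {
                    "source_id": recording.source_id,
                    "dish_id": dish,
                    "frame_index": frame_index,
                    "time_s": time_s,
                    "n_fish_moved": n_moved,
                    "distance_px": dist,
                    "pixel_count": px,
                    "penny_present": penny.present_at(frame_index),
                }
            )

    series = [
        DishSeries(
            dish_id=d,
            source_id=recording.source_id,
            time_s=np.array(per_dish[d]["t"]),
            distance_px=np.array(per_dish[d]["dist"]),
            n_fish_moved=np.array(per_dish[d]["n"], dtype=int),
        )
        for d in dish_ids
    ]
    results = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    if results.empty:
        from .frames_io import empty_results

        results = empty_results()
    return series, results, events, singles


def series_from_results(results: pd.DataFrame, condition_label: str = "") -> list[DishSeries]:
    """Rebuild per-dish series from a results table (one replicate per source/dish)."""
    out: list[DishSeries] = []
    for (src, dish), grp in results.groupby(["source_id", "dish_id"], sort=True):
        grp = grp.sort_values("frame_index")
        out.append(
            DishSeries(
                dish_id=str(dish),
                condition_label=condition_label,
                source_id=str(src),
                time_s=grp["time_s"].to_numpy(dtype=float),
                distance_px=grp["distance_px"].to_numpy(dtype=float),
                n_fish_moved=grp["n_fish_moved"].to_numpy(dtype=int),
            )
        )
    return out
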