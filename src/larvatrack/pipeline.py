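"""End-to-end tracking: load → register → difference → extract → match → tabulate.

Registration is computed once from the first sampled frame and reused for the
whole recording (the apparatus is rigid); per-frame re-registration is a
config option.  Frames are processed as a stream, keeping only the current
and comparison frames in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .detection import (
    Blob,
    PennyEvent,
    detect_penny,
    extract_movements,
    frame_difference,
)
from .errors import ConfigError
from .frames_io import Recording
from .registration import (
    DishLayout,
    DishRegion,
    Point,
    SimilarityTransform,
    detect_alignment_dots,
    estimate_transform,
    locate_dishes,
)
from .tracking import DishSeries, MovementEvent, SingleBlobEvent, build_series

__all__ = ["TrackConfig", "TrackResult", "track_recording"]


@dataclass
class TrackConfig:
    """Detection and matching thresholds; every field has a frozen default."""

    diff_threshold: float = 0.15  # fraction of dynamic range
    min_blob_px: int = 3
    merge_radius_px: float = 0.0  # 0 disables blob merging
    body_length_px: float = 8.0  # template pixels, for the single-blob rule
    max_step_px: float = 100.0  # template pixels; larvae cannot cross a dish in 1 s
    dot_radius_range_px: tuple[float, float] = (4.0, 8.0)
    penny_radius_range_px: tuple[float, float] = (10.0, 14.0)
    circularity_min: float = 0.6
    polarity: str = "dark-on-light"
    detect_penny: bool = True
    reregister_every_frame: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "TrackConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("dot_radius_range_px", "penny_radius_range_px"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "TrackConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file does not exist: {path}")
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(text)
        else:
            try:
                doc = json.loads(text)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"malformed config {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(doc)


@dataclass
class TrackResult:
    """Everything one tracking run produces."""

    results: pd.DataFrame
    series: list[DishSeries]
    events: list[MovementEvent]
    singles: list[SingleBlobEvent]
    blob_points: dict[tuple[int, str], list[Point]]  # (frame_index, dish) -> template coords
    penny: PennyEvent
    transform: SimilarityTransform
    regions: list[DishRegion]


def track_recording(
    recording: Recording,
    layout: DishLayout,
    config: TrackConfig | None = None,
) -> TrackResult:
    """Run the full movement-analysis pipeline on one recording."""
    cfg = config if config is not None else TrackConfig()
    frames = recording.iter_frames()
    first = next(frames)
    shape = first.pixels.shape

    dots = detect_alignment_dots(
        first, cfg.polarity, cfg.dot_radius_range_px, cfg.circularity_min
    )
    transform = estimate_transform(dots, layout.reference_dots)
    regions = locate_dishes(transform, layout, frame_shape=shape)

    penny = PennyEvent()
    if cfg.detect_penny and detect_penny(
        first, regions, cfg.penny_radius_range_px, cfg.circularity_min
    ):
        penny = PennyEvent(first_frame_index=0)

    blobs_per_pair: list[list[Blob]] = []
    blob_points: dict[tuple[int, str], list[Point]] = {}
    prev = first
    for current in frames:
        if cfg.reregister_every_frame:
            dots = detect_alignment_dots(
                current, cfg.polarity, cfg.dot_radius_range_px, cfg.circularity_min
            )
            transform = estimate_transform(dots, layout.reference_dots)
            regions = locate_dishes(transform, layout, frame_shape=shape)
        if cfg.detect_penny and penny.first_frame_index is None:
            if detect_penny(current, regions, cfg.penny_radius_range_px, cfg.circularity_min):
                penny = PennyEvent(first_frame_index=current.frame_index)
        diff = frame_difference(current, prev, cfg.diff_threshold)
        blobs = extract_movements(diff, regions, cfg.min_blob_px, cfg.merge_radius_px)
        blobs_per_pair.append(blobs)
        for b in blobs:
            x, y = transform.apply_xy(b.centroid.x, b.centroid.y)
            blob_points.setdefault((current.frame_index, b.dish_id), []).append(Point(x, y))
        prev = current

    dish_ids = [d.dish_id for d in layout.dishes]
    series, results, events, singles = build_series(
        recording,
        blobs_per_pair,
        penny,
        max_step_px=cfg.max_step_px,
        body_length_px=cfg.body_length_px,
        transform=transform,
        dish_ids=dish_ids,
    )
    return TrackResult(
        results=results,
        series=series,
        events=events,
        singles=singles,
        blob_points=blob_points,
        penny=penny,
        transform=transform,
        regions=regions,
    )
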