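"""Synthetic recordings with ground truth for tracker benchmarking.

The generator emulates the assay apparatus: dark larvae (oriented ellipses)
in square weighing dishes on a bright diffuser, two circular alignment dots
at the top of the template, an optional penny appearing when the stimulus is
administered, additive Gaussian pixel noise, and an optional global zoom and
shift of the whole scene.

Kinematics are a deliberately simple bout model: each second a larva moves
with probability ``p_move``; a moving larva takes a Gamma-distributed step
(truncated at ``max_step_px``) in a heading correlated with its previous
one, reflecting off the dish walls and avoiding close approaches to other
larvae.  A stimulus multiplies the movement probability by a dose-dependent
activation factor with an inverted-U (log-Gaussian) dose profile, and a
pretreatment drug attenuates the activation excess by a fraction ``a``.
None of this claims behavioral realism beyond what exercises the tracker
contract; see the methods note for what these scenes do and do not test.

All outputs are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LayoutError, ScoringError
from .frames_io import Recording
from .registration import DishLayout, DishSpec, Point
from .tracking import DishSeries

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "AccuracyReport",
    "default_layout",
    "simulate_trajectories",
    "generate_scene",
    "score_tracker",
    "benchmark_validation_scale",
    "truth_series",
    "simulate_condition_series",
]

#: Movement probability for the validation-scale benchmark: 20 larvae × 60
#: frame pairs × p ≈ 591 expected true movements.
BENCHMARK_P_MOVE = 591.0 / 1200.0


def default_layout(
    n_dishes: int = 2,
    frame_width: int = 640,
    frame_height: int = 360,
) -> DishLayout:
    """Template with two alignment dots along the top and a row of square dishes."""
    if n_dishes < 1:
        raise InputError("need at least one dish")
    dots = [Point(20.0, 20.0), Point(frame_width - 20.0, 20.0)]
    usable = frame_width - 40.0
    pitch = usable / n_dishes
    half = min((frame_height - 60.0) / 2.0, (pitch - 20.0) / 2.0)
    if half <= 20.0:
        raise LayoutError(f"frame {frame_width}x{frame_height} too small for {n_dishes} dishes")
    dishes = [
        DishSpec(f"dish{i + 1}", Point(20.0 + (i + 0.5) * pitch, 50.0 + half), half)
        for i in range(n_dishes)
    ]
    return DishLayout(dots, dishes)


@dataclass
class SceneSpec:
    """Full description of a synthetic recording (the study conditions)."""

    n_dishes: int = 2
    larvae_per_dish: int = 10
    duration_s: int = 60
    seed: int = 0
    frame_width: int = 640
    frame_height: int = 360
    background: float = 0.9
    body_length_px: float = 8.0
    body_width_px: float = 3.0
    body_intensity: float = 0.25
    # bout model: ~1-2 body lengths per second when moving
    p_move: float = 0.6
    step_gamma_shape: float = 12.0
    step_gamma_scale: float = 1.0
    max_step_px: float = 15.0
    heading_persistence: float = 0.7
    min_separation_px: float = 20.0
    placement_min_separation_px: float = 24.0
    boundary_margin_px: float = 6.0
    # stimulus / drug model
    stimulus_time_s: float | None = None
    dose: float = 0.0
    peak_dose: float = 20.0
    activation_max: float = 2.0
    activation_log_width: float = 1.0
    step_factor_exponent: float = 0.0  # activation acts on p_move only by default
    drug_attenuation: float = 0.0
    # rendering
    noise_sigma: float = 0.02
    penny: bool = False
    penny_radius_px: float = 12.0
    penny_time_s: float | None = None
    dot_radius_px: float = 6.0
    zoom: float = 1.0
    shift_x: float = 0.0
    shift_y: float = 0.0
    # error-mode injection: in-place reorientation that mimics a twisting larva
    twist_prob: float = 0.0
    layout: DishLayout | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_move <= 1.0):
            raise InputError(f"p_move must be in [0,1], got {self.p_move}")
        if not (0.0 <= self.drug_attenuation <= 1.0):
            raise InputError("drug_attenuation must be in [0,1]")
        if self.zoom <= 0:
            raise InputError("zoom must be positive")

    @property
    def n_larvae(self) -> int:
        return self.n_dishes * self.larvae_per_dish

    def effective_layout(self) -> DishLayout:
        return self.layout if self.layout is not None else default_layout(
            self.n_dishes, self.frame_width, self.frame_height
        )

    @property
    def penny_center(self) -> Point:
        return Point(self.frame_width / 2.0, 25.0)

    @property
    def effective_penny_time(self) -> float | None:
        if self.penny_time_s is not None:
            return self.penny_time_s
        return self.stimulus_time_s

    def activation_factor(self, t: float) -> float:
        """Movement-rate multiplier at time t (1.0 before stimulus / without dose)."""
        if self.stimulus_time_s is None or t < self.stimulus_time_s or self.dose <= 0:
            return 1.0
        z = math.log(self.dose / self.peak_dose) / self.activation_log_width
        f = 1.0 + self.activation_max * math.exp(-0.5 * z * z)
        return 1.0 + (f - 1.0) * (1.0 - self.drug_attenuation)


@dataclass
class GroundTruth:
    """True trajectories of a scene: positions at each second in template coordinates."""

    spec: SceneSpec
    positions: np.ndarray  # (T+1, n_larvae, 2) float
    headings: np.ndarray  # (T+1, n_larvae)
    moved: np.ndarray  # (T+1, n_larvae) bool; row 0 unused
    step_px: np.ndarray  # (T+1, n_larvae) float; actual displacement
    dish_ids: list[str] = field(default_factory=list)
    larva_dish: list[str] = field(default_factory=list)
    penny_first_frame: int | None = None

    @property
    def duration_s(self) -> int:
        return self.positions.shape[0] - 1

    def dish_totals(self) -> dict[str, float]:
        totals = {d: 0.0 for d in self.dish_ids}
        for n, dish in enumerate(self.larva_dish):
            totals[dish] += float(self.step_px[1:, n].sum())
        return totals

    def movements(self, min_step_px: float = 2.0) -> pd.DataFrame:
        """True movements at or above the detectability floor, with their midpoints."""
        rows = []
        for t in range(1, self.positions.shape[0]):
            for n in range(self.positions.shape[1]):
                if not self.moved[t, n] or self.step_px[t, n] < min_step_px:
                    continue
                bx, by = self.positions[t - 1, n]
                ax, ay = self.positions[t, n]
                rows.append(
                    {
                        "t": t,
                        "larva": n,
                        "dish_id": self.larva_dish[n],
                        "bx": bx,
                        "by": by,
                        "ax": ax,
                        "ay": ay,
                        "mid_x": 0.5 * (bx + ax),
                        "mid_y": 0.5 * (by + ay),
                        "step_px": self.step_px[t, n],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["t", "larva", "dish_id", "bx", "by", "ax", "ay", "mid_x", "mid_y", "step_px"],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        T1, N, _ = self.positions.shape
        for n in range(N):
            for t in range(T1):
                rows.append(
                    {
                        "larva_id": n,
                        "dish_id": self.larva_dish[n],
                        "t": t,
                        "x": self.positions[t, n, 0],
                        "y": self.positions[t, n, 1],
                        "moved": bool(self.moved[t, n]),
                        "step_px": self.step_px[t, n],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        return path


def _dish_boxes(spec: SceneSpec) -> dict[str, tuple[float, float, float, float]]:
    m = spec.boundary_margin_px
    boxes = {}
    for d in spec.effective_layout().dishes:
        boxes[d.dish_id] = (
            d.center.x - d.half_width_px + m,
            d.center.x + d.half_width_px - m,
            d.center.y - d.half_width_px + m,
            d.center.y + d.half_width_px - m,
        )
    return boxes


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    while v < lo or v > hi:
        if v < lo:
            v = 2 * lo - v
        else:
            v = 2 * hi - v
        if span <= 0:
            return lo
    return v


def simulate_trajectories(spec: SceneSpec) -> GroundTruth:
    """Simulate larva positions second by second (no rendering)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    layout = spec.effective_layout()
    boxes = _dish_boxes(spec)
    dish_ids = [d.dish_id for d in layout.dishes]
    larva_dish = [dish_ids[n // spec.larvae_per_dish] for n in range(spec.n_larvae)]

    T = int(spec.duration_s)
    N = spec.n_larvae
    pos = np.zeros((T + 1, N, 2))
    head = np.zeros((T + 1, N))
    moved = np.zeros((T + 1, N), dtype=bool)
    step = np.zeros((T + 1, N))

    # initial placement: uniform in the inset dish box with a minimum spacing
    for n in range(N):
        x0, x1, y0, y1 = boxes[larva_dish[n]]
        for _ in range(10000):
            p = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
            same = [m for m in range(n) if larva_dish[m] == larva_dish[n]]
            if all(
                np.hypot(*(p - pos[0, m])) >= spec.placement_min_separation_px for m in same
            ):
                pos[0, n] = p
                break
        else:
            raise InputError("could not place larvae with the requested spacing")
        head[0, n] = rng.uniform(-math.pi, math.pi)

    sigma_h = (1.0 - spec.heading_persistence) * math.pi
    for t in range(1, T + 1):
        pos[t] = pos[t - 1]
        head[t] = head[t - 1]
        factor = spec.activation_factor(float(t))
        p_eff = min(0.95, spec.p_move * factor)
        scale_eff = spec.step_gamma_scale * factor**spec.step_factor_exponent
        for n in range(N):
            x0, x1, y0, y1 = boxes[larva_dish[n]]
            if rng.random() >= p_eff:
                if spec.twist_prob > 0 and rng.random() < spec.twist_prob:
                    # in-place reorientation: the rendered body rotates without
                    # translating, the classic twisting error mode
                    head[t, n] = head[t - 1, n] + rng.uniform(math.pi / 2, math.pi) * (
                        1 if rng.random() < 0.5 else -1
                    )
                continue
            accepted = None
            for attempt in range(10):
                if attempt == 0:
                    phi = head[t - 1, n] + rng.normal(0.0, sigma_h)
                else:
                    phi = rng.uniform(-math.pi, math.pi)
                s = min(rng.gamma(spec.step_gamma_shape, scale_eff), spec.max_step_px)
                cand = np.array(
                    [
                        _reflect(pos[t - 1, n, 0] + s * math.cos(phi), x0, x1),
                        _reflect(pos[t - 1, n, 1] + s * math.sin(phi), y0, y1),
                    ]
                )
                others = [m for m in range(N) if m != n and larva_dish[m] == larva_dish[n]]
                if all(np.hypot(*(cand - pos[t, m])) >= spec.min_separation_px for m in others):
                    accepted = cand
                    break
            if accepted is None:
                continue
            delta = accepted - pos[t - 1, n]
            d = float(np.hypot(*delta))
            pos[t, n] = accepted
            moved[t, n] = d > 0
            step[t, n] = d
            if d > 0:
                head[t, n] = math.atan2(delta[1], delta[0])

    penny_first = None
    if spec.penny and spec.effective_penny_time is not None:
        penny_first = int(math.ceil(spec.effective_penny_time))
    return GroundTruth(
        spec=spec,
        positions=pos,
        headings=head,
        moved=moved,
        step_px=step,
        dish_ids=dish_ids,
        larva_dish=larva_dish,
        penny_first_frame=penny_first,
    )


def _draw_ellipse(
    img: np.ndarray, cx: float, cy: float, a: float, b: float, phi: float, value: float
) -> None:
    """Darken pixels inside the ellipse (semi-axes a ≥ b, orientation phi)."""
    h, w = img.shape
    r = a + 2.0
    x_lo, x_hi = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    y_lo, y_hi = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    dx = xs - cx
    dy = ys - cy
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    sub = img[y_lo:y_hi, x_lo:x_hi]
    sub[inside] = np.minimum(sub[inside], value)


def render_frame(spec: SceneSpec, truth: GroundTruth, t: int, noise_rng: np.random.Generator) -> np.ndarray:
    """Render one frame (uint8 grayscale) of the scene at second ``t``."""
    img = np.full((spec.frame_height, spec.frame_width), spec.background, dtype=np.float64)
    z, sx, sy = spec.zoom, spec.shift_x, spec.shift_y
    for dot in spec.effective_layout().reference_dots:
        _draw_ellipse(img, dot.x * z + sx, dot.y * z + sy, spec.dot_radius_px * z,
                      spec.dot_radius_px * z, 0.0, 0.2)
    penny_t = truth.penny_first_frame
    if spec.penny and penny_t is not None and t >= penny_t:
        c = spec.penny_center
        _draw_ellipse(img, c.x * z + sx, c.y * z + sy, spec.penny_radius_px * z,
                      spec.penny_radius_px * z, 0.0, 0.2)
    a = spec.body_length_px / 2.0
    b = spec.body_width_px / 2.0
    for n in range(spec.n_larvae):
        x, y = truth.positions[t, n]
        _draw_ellipse(img, x * z + sx, y * z + sy, a * z, b * z,
                      truth.headings[t, n], spec.body_intensity)
    if spec.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def generate_scene(spec: SceneSpec, out_dir: str | Path | None = None) -> tuple[Recording, GroundTruth]:
    """Render a full synthetic recording; optionally write PNG frames + truth CSV.

    Deterministic: the same spec (same seed) produces byte-identical frames
    and ground truth.
    """
    truth = simulate_trajectories(spec)
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))
    frames = [render_frame(spec, truth, t, noise_rng) for t in range(spec.duration_s + 1)]
    source_id = f"scene-seed{spec.seed}"
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for t, fr in enumerate(frames):
            iio.imwrite(out / f"frame_{t:04d}.png", fr)
        truth.to_csv(out / "ground_truth.csv")
        source_id = out.name
    rec = Recording.from_arrays(frames, sample_rate_hz=1.0, source_id=source_id)
    return rec, truth


@dataclass
class AccuracyReport:
    """Tracker output scored against generator ground truth."""

    n_true_movements: int
    n_detected: int
    detection_rate: float
    n_match_attempts: int
    n_correct_matches: int
    match_rate: float
    n_false_positive_blobs: int
    distance_relative_error: float
    per_dish_relative_error: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_true_movements": self.n_true_movements,
            "n_detected": self.n_detected,
            "detection_rate": self.detection_rate,
            "n_match_attempts": self.n_match_attempts,
            "n_correct_matches": self.n_correct_matches,
            "match_rate": self.match_rate,
            "n_false_positive_blobs": self.n_false_positive_blobs,
            "distance_relative_error": self.distance_relative_error,
            "per_dish_relative_error": dict(sorted(self.per_dish_relative_error.items())),
        }


def score_tracker(
    result,
    truth: GroundTruth,
    match_tol_px: float | None = None,
    detect_floor_px: float = 2.0,
) -> AccuracyReport:
    """Score a :class:`~larvatrack.pipeline.TrackResult` against ground truth.

    A true movement (step ≥ ``detect_floor_px``) counts as detected when some
    blob centroid of its dish/frame-pair lies within ``match_tol_px`` (default
    one body length) of the movement's midpoint.  A matched pair is correct
    when both endpoints lie within the tolerance of the true before/after
    positions of one movement.  All comparisons are in template coordinates.
    """
    tol = match_tol_px if match_tol_px is not None else truth.spec.body_length_px
    tracked_dishes = {s.dish_id for s in result.series}
    if not tracked_dishes.issubset(set(truth.dish_ids)):
        raise ScoringError(
            f"tracker dishes {sorted(tracked_dishes)} do not match truth {truth.dish_ids}"
        )

    moves = truth.movements(min_step_px=detect_floor_px)
    all_moves = truth.movements(min_step_px=0.0)

    n_detected = 0
    for row in moves.itertuples():
        pts = result.blob_points.get((int(row.t), row.dish_id), [])
        if any(math.hypot(p.x - row.mid_x, p.y - row.mid_y) <= tol for p in pts):
            n_detected += 1

    by_key: dict[tuple[int, str], list] = {}
    for row in all_moves.itertuples():
        by_key.setdefault((int(row.t), row.dish_id), []).append(row)
    n_correct = 0
    for ev in result.events:
        t = ev.frame_pair[1]
        ok = any(
            math.hypot(ev.before.x - m.bx, ev.before.y - m.by) <= tol
            and math.hypot(ev.after.x - m.ax, ev.after.y - m.ay) <= tol
            for m in by_key.get((t, ev.dish_id), [])
        )
        n_correct += ok

    n_fp = 0
    for (t, dish), pts in result.blob_points.items():
        mids = [(m.mid_x, m.mid_y) for m in by_key.get((t, dish), [])]
        for p in pts:
            if not any(math.hypot(p.x - mx, p.y - my) <= tol for mx, my in mids):
                n_fp += 1

    true_totals = truth.dish_totals()
    per_dish_err = {}
    for s in result.series:
        t_true = true_totals.get(s.dish_id, 0.0)
        if t_true > 0:
            per_dish_err[s.dish_id] = abs(s.total_distance_px - t_true) / t_true
    n_true = len(moves)
    n_attempts = len(result.events)
    return AccuracyReport(
        n_true_movements=n_true,
        n_detected=n_detected,
        detection_rate=n_detected / n_true if n_true else 0.0,
        n_match_attempts=n_attempts,
        n_correct_matches=n_correct,
        match_rate=n_correct / n_attempts if n_attempts else 0.0,
        n_false_positive_blobs=n_fp,
        distance_relative_error=max(per_dish_err.values()) if per_dish_err else 0.0,
        per_dish_relative_error=per_dish_err,
    )


def benchmark_validation_scale(seed: int = 0):
    """Accuracy benchmark at the published validation scale.

    Two weighing dishes of 10 larvae, 60 analyzed frame pairs, movement
    probability set so the expected number of true movements is ≈591, default
    noise, no twisting.  Runs the full default-configuration pipeline and
    scores it against ground truth with a one-body-length tolerance.
    """
    from .pipeline import TrackConfig, track_recording

    spec = SceneSpec(
        n_dishes=2,
        larvae_per_dish=10,
        duration_s=60,
        seed=int(seed),
        p_move=BENCHMARK_P_MOVE,
    )
    recording, truth = generate_scene(spec)
    result = track_recording(recording, spec.effective_layout(), TrackConfig())
    return score_tracker(result, truth, match_tol_px=spec.body_length_px)


def truth_series(truth: GroundTruth, condition_label: str = "") -> list[DishSeries]:
    """Per-dish per-second distance series computed from ground truth (no tracking)."""
    T = truth.duration_s
    out = []
    src = f"truth-seed{truth.spec.seed}"
    for dish in truth.dish_ids:
        idx = [n for n, d in enumerate(truth.larva_dish) if d == dish]
        dist = truth.step_px[1:, idx].sum(axis=1)
        n_moved = truth.moved[1:, idx].sum(axis=1)
        out.append(
            DishSeries(
                dish_id=dish,
                condition_label=condition_label,
                source_id=src,
                time_s=np.arange(1, T + 1, dtype=float),
                distance_px=dist.astype(float),
                n_fish_moved=n_moved.astype(int),
            )
        )
    return out


def simulate_condition_series(
    base: SceneSpec,
    condition_label: str,
    n_replicates: int = 3,
    seed0: int = 0,
    dose: float | None = None,
    drug_attenuation: float | None = None,
) -> list[DishSeries]:
    """Replicate dishes for one assay condition, simulated without rendering.

    Each replicate is an independent single-dish scene with seed ``seed0 + r``;
    the dose and drug attenuation default to the base spec's values.
    """
    series: list[DishSeries] = []
    for r in range(n_replicates):
        spec = replace(
            base,
            n_dishes=1,
            seed=int(seed0) + r,
            dose=base.dose if dose is None else dose,
            drug_attenuation=(
                base.drug_attenuation if drug_attenuation is None else drug_attenuation
            ),
        )
        truth = simulate_trajectories(spec)
        for s in truth_series(truth, condition_label):
            s.dish_id = f"{condition_label}-rep{r + 1}"
            s.source_id = f"sim-seed{spec.seed}"
            series.append(s)
    return series
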