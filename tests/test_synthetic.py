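"""Scene generator: determinism, physical invariants, and model recovery."""

import numpy as np
import pytest
from dataclasses import replace

from larvatrack.assay_stats import AssayDesign, dose_response_table, summarize_condition
from larvatrack.pipeline import TrackConfig, TrackResult, track_recording
from larvatrack.synthetic import (
    SceneSpec,
    generate_scene,
    score_tracker,
    simulate_condition_series,
    simulate_trajectories,
    truth_series,
)


def test_same_seed_bit_identical_different_seed_not(small_spec):
    rec1, truth1 = generate_scene(small_spec)
    rec2, truth2 = generate_scene(small_spec)
    f1, f2 = rec1.load_all(), rec2.load_all()
    for a, b in zip(f1, f2):
        np.testing.assert_array_equal(a.pixels, b.pixels)
    np.testing.assert_array_equal(truth1.positions, truth2.positions)
    rec3, _ = generate_scene(replace(small_spec, seed=small_spec.seed + 1))
    assert any(
        not np.array_equal(a.pixels, b.pixels) for a, b in zip(f1, rec3.load_all())
    )


def test_png_output_bit_identical(small_spec, tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_scene(small_spec, out_dir=d1)
    generate_scene(small_spec, out_dir=d2)
    for p1 in sorted(d1.iterdir()):
        assert p1.read_bytes() == (d2 / p1.name).read_bytes()


def test_frozen_larvae_static_frames():
    spec = SceneSpec(n_dishes=1, larvae_per_dish=3, duration_s=5, seed=1,
                     frame_width=320, frame_height=200, p_move=0.0, noise_sigma=0.0)
    rec, truth = generate_scene(spec)
    frames = rec.load_all()
    for f in frames[1:]:
        np.testing.assert_array_equal(f.pixels, frames[0].pixels)
    assert truth.dish_totals() == {"dish1": 0.0}


def test_trajectories_confined_to_dishes():
    for seed in range(3):
        spec = SceneSpec(n_dishes=2, larvae_per_dish=5, duration_s=20, seed=seed)
        truth = simulate_trajectories(spec)
        for dish in spec.effective_layout().dishes:
            idx = [n for n, d in enumerate(truth.larva_dish) if d == dish.dish_id]
            xs = truth.positions[:, idx, 0]
            ys = truth.positions[:, idx, 1]
            assert (np.abs(xs - dish.center.x) <= dish.half_width_px).all()
            assert (np.abs(ys - dish.center.y) <= dish.half_width_px).all()


def test_truth_series_additivity():
    spec = SceneSpec(n_dishes=2, larvae_per_dish=4, duration_s=15, seed=2)
    truth = simulate_trajectories(spec)
    totals = truth.dish_totals()
    for s in truth_series(truth):
        assert s.total_distance_px == pytest.approx(totals[s.dish_id])


def test_perfect_scene_scores_perfectly(tracked_small):
    result, truth = tracked_small
    report = score_tracker(result, truth)
    assert report.detection_rate == 1.0
    assert report.match_rate == 1.0
    assert report.n_false_positive_blobs == 0


def test_empty_tracker_scores_zero(tracked_small):
    result, truth = tracked_small
    empty = TrackResult(
        results=result.results.iloc[:0], series=result.series, events=[], singles=[],
        blob_points={}, penny=result.penny, transform=result.transform,
        regions=result.regions,
    )
    report = score_tracker(empty, truth)
    assert report.detection_rate == 0.0
    assert report.n_match_attempts == 0


def test_noiseless_rates_at_least_noisy(small_spec):
    noisy_rec, truth = generate_scene(small_spec)
    clean_rec, _ = generate_scene(replace(small_spec, noise_sigma=0.0))
    layout = small_spec.effective_layout()
    noisy = score_tracker(track_recording(noisy_rec, layout), truth)
    clean = score_tracker(track_recording(clean_rec, layout), truth)
    assert clean.detection_rate >= noisy.detection_rate
    assert clean.match_rate >= noisy.match_rate


def test_zoomed_scene_distance_consistent():
    """A global zoom is undone by registration: template-scale distances agree to 1%."""
    base = SceneSpec(n_dishes=1, larvae_per_dish=5, duration_s=30, seed=4,
                     frame_width=320, frame_height=200)
    zoomed = replace(base, zoom=0.95, shift_x=3.0, shift_y=2.0)
    layout = base.effective_layout()
    rec1, truth = generate_scene(base)
    rec2, _ = generate_scene(zoomed)
    r1 = track_recording(rec1, layout)
    r2 = track_recording(rec2, layout)
    assert r2.transform.scale == pytest.approx(1 / 0.95, rel=1e-2)
    d1 = sum(s.total_distance_px for s in r1.series)
    d2 = sum(s.total_distance_px for s in r2.series)
    assert d2 == pytest.approx(d1, rel=0.01)


def test_whole_frame_dish_conserves_total_distance():
    """One dish covering everything yields the same total as the per-dish split."""
    from larvatrack.registration import DishLayout, DishSpec, Point

    spec = SceneSpec(n_dishes=2, larvae_per_dish=4, duration_s=15, seed=6)
    recording, _ = generate_scene(spec)
    layout = spec.effective_layout()
    big = DishLayout(layout.reference_dots,
                     [DishSpec("all", Point(320.0, 190.0), 290.0)])
    split = track_recording(recording, layout)
    merged = track_recording(recording, big)
    total_split = sum(s.total_distance_px for s in split.series)
    total_merged = sum(s.total_distance_px for s in merged.series)
    assert total_merged == pytest.approx(total_split, rel=1e-9)


def assay_spec(**kw):
    return SceneSpec(
        n_dishes=1, larvae_per_dish=10, duration_s=300,
        frame_width=320, frame_height=200,
        p_move=0.2, stimulus_time_s=60.0, dose=20.0, **kw,
    )


def assay_design():
    return AssayDesign(stimulus_label="stim", stimulus_time_s=60.0,
                       analysis_window_s=(0.0, 240.0))


def test_dose_response_recovers_generator_peak():
    """Scanning doses across the activation curve recovers the generator's peak dose."""
    doses = [5.0, 10.0, 20.0, 40.0, 80.0]
    entries = []
    series = simulate_condition_series(assay_spec(), "stim", n_replicates=3, seed0=100)
    for i, dose in enumerate(doses):
        label = f"dose{dose:g}"
        series_d = simulate_condition_series(
            assay_spec(), label, n_replicates=3, seed0=200 + 10 * i, dose=dose
        )
        summary = summarize_condition(series + series_d, assay_design(), label)
        entries.append((dose, summary))
    table, peak, inv_u = dose_response_table(entries)
    assert peak == 20.0  # the generator's peak_dose default
    assert inv_u


def test_drug_attenuation_recovered_in_percent():
    """Generated attenuation a maps onto percent-of-stimulus ~ 100*f_a/f."""
    spec = assay_spec()
    a = 0.5
    f = spec.activation_factor(100.0)  # post-stimulus factor without drug
    f_a = 1.0 + (f - 1.0) * (1.0 - a)
    predicted = 100.0 * f_a / f
    percents = []
    for seed0 in (300, 400, 500):
        stim = simulate_condition_series(spec, "stim", n_replicates=3, seed0=seed0)
        drug = simulate_condition_series(spec, "drug", n_replicates=3,
                                         seed0=seed0 + 50, drug_attenuation=a)
        s = summarize_condition(stim + drug, assay_design(), "drug")
        percents.append(s.percent_of_stimulus)
    assert abs(np.mean(percents) - predicted) <= 8.0


def test_benchmark_report_deterministic():
    from larvatrack.synthetic import benchmark_validation_scale

    r1 = benchmark_validation_scale(3)
    r2 = benchmark_validation_scale(3)
    assert r1.to_dict() == r2.to_dict()
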