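"""Render a small synthetic dish scene and track it end to end.

Builds a one-minute recording of two dishes with a penny appearing at t=30 s,
runs registration, frame differencing and closest-point matching, and prints
the per-dish distance traveled before and after the stimulus marker.
"""

from larvatrack import SceneSpec, TrackConfig, generate_scene, track_recording

spec = SceneSpec(n_dishes=2, larvae_per_dish=10, duration_s=60, seed=42,
                 penny=True, penny_time_s=30.0)
recording, truth = generate_scene(spec)
result = track_recording(recording, spec.effective_layout(), TrackConfig())

print(f"registration scale {result.transform.scale:.4f}, "
      f"residual {result.transform.residual_rms:.3f} px")
print(f"penny first detected at frame {result.penny.first_frame_index} "
      f"(truth: {truth.penny_first_frame})")
for s in result.series:
    pre = s.cumulative((0, 30))
    post = s.cumulative((30, 61))
    true_total = truth.dish_totals()[s.dish_id]
    print(f"{s.dish_id}: {pre:7.1f} px before marker, {post:7.1f} px after; "
          f"tracked total {s.total_distance_px:7.1f} vs true {true_total:7.1f} px")

# The per-dish totals are distance traveled in template-scale pixels; tracked
# and true totals agreeing within a few percent means the frame-differencing
# tracker is recovering the larvae's actual displacements, not just activity.
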