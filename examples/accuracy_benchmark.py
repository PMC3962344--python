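"""Run the validation-scale tracker benchmark against synthetic ground truth.

Two weighing dishes of 10 larvae, 60 analyzed frame pairs, movement
probability targeting ~591 true movements, default pixel noise.  Prints the
detection and matching rates and the per-dish distance error.
"""

from larvatrack import benchmark_validation_scale

report = benchmark_validation_scale(seed=0)
print(f"true movements: {report.n_true_movements}")
print(f"detection rate: {100 * report.detection_rate:.1f}% "
      f"({report.n_detected}/{report.n_true_movements})")
print(f"match rate:     {100 * report.match_rate:.1f}% "
      f"({report.n_correct_matches}/{report.n_match_attempts} matched pairs)")
print(f"false-positive blobs: {report.n_false_positive_blobs}")
for dish, err in sorted(report.per_dish_relative_error.items()):
    print(f"{dish}: distance error {100 * err:.2f}%")
# Detection counts a true movement as found when a movement blob lies within
# one body length of its midpoint; a matched pair is correct when both of its
# endpoints land on the true before/after positions.
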