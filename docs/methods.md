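# Methods

## Tracking model

The tracker treats a recording as a sequence of grayscale frames sampled at
1 Hz (configurable).  Its core assumptions are the ones the assay apparatus
is built to satisfy: dark larvae on a uniformly bright diffuser, rigid dish
template with two circular fiducial dots, a fixed camera whose position and
zoom vary only between recordings, and larvae that stay within their dishes.

**Registration.**  Dot candidates are connected components of an Otsu
foreground mask whose area falls inside the disc-area band implied by the
configured radius range and whose circularity 4π·area/perimeter² ≥ 0.6 (the
perimeter is the component's boundary-pixel count).  Because Otsu's
threshold is relative, detection is invariant to global intensity rescaling.
A translation + uniform-scale transform (no rotation: the template is
mechanically seated, only placement and zoom vary) is fitted by least
squares to the sorted-x correspondence between detected and template dots;
it is estimated once from the first frame and reused, with per-frame
re-registration available by config.  Dish squares, defined in template
coordinates relative to the left-most dot, are mapped into frame coordinates
through the inverse transform and clipped to the frame with a warning.

**Movement detection.**  The comparison frame is the previous sampled frame
rather than a static background, so slow lighting drift cancels.  Pixels
with |Δintensity| ≥ 0.15 (fraction of dynamic range) form the movement mask;
8-connected components of at least 3 px are assigned to the dish containing
their centroid and discarded outside all dishes.  A moving dark larva leaves
a *brightened* component where its body was and a *darkened* one where it
now is; a component with ≥ 70 % one sign is labeled before (+) or after (−)
accordingly, and mixed-sign components are treated as a single blob covering
both body positions.  Optional merging of nearby components within a dish
(pixel-count-weighted centroid) exists for twisting-type artifacts and is
off by default.

**Matching and distance.**  Within each dish and frame pair, before and
after centroids are paired greedily by globally smallest Euclidean distance
with a gate of 100 template pixels (larvae cannot cross a dish in one
second); ties break deterministically on indices.  A matched pair
contributes its centroid separation; a mixed-polarity or unmatched blob
contributes max(0, principal-axis extent − one body length), which is exact
for a straight-line sub-body-length move (the union of old and new body
spans extent L + d).  The number of fish moved per second is matched pairs
plus singletons.  Distances are reported at template scale by multiplying
frame displacements by the registration scale; no millimeter calibration is
attempted because the screen normalizes to the stimulus-only response, so
absolute units cancel.

Known bias: when a move shorter than one body length yields *two* clean
opposite-polarity remnants instead of one mixed component, the remnant
centroids sit one body length apart regardless of the true step, so such
events are over-measured by up to (L − d).  With the default synthetic
kinematics (below) about 10 % of moves fall in this regime and the per-dish
distance bias stays under ~2 %; on real recordings the same bias applies to
slow drifting movements.

**Penny.**  The stimulus marker is a dark disc (radius range 10–14 px,
same circularity gate) searched outside all dish regions; its first
appearance is latched, so isolated missed detections cannot clear the flag.

## Statistics

The replicate dish is the unit of analysis (the screen runs 3 replicates of
10–15 larvae per condition; 6 for ethanol).  Each replicate's readout is the
cumulative distance over the analysis window relative to stimulus time —
(0, 240) s by default, (1800, 2400) s for ethanol.  The baseline window
(−120, 0) s is reported but not subtracted by default, because normalization
is to the stimulus-only arm rather than to baseline; a baseline-delta mode
exists.  percent_of_stimulus = 100 × mean(condition)/mean(stimulus-only),
and significance is Student's pooled-variance two-sided t-test (Welch by
config) at α = 0.05, with degenerate zero-variance cases resolved to p = 1
(equal means) or p = 0 (unequal).  No multiple-testing correction is applied
by default, matching per-drug testing practice in this screen design.

Attenuation requires both p < α and percent < 100, so significant
potentiation is never mislabeled attenuation (it is flagged separately).
Category logic: attenuation of nicotine only → (iv); of nicotine and at
least one oil control → (iii); no attenuation with/without toxicity evidence
→ (ii)/(i).  A nicotine-attenuating drug with no oil-control data is a
provisional (iv) with a warning.

Bliss Independence uses E = 1 − (D + V − D·V), algebraically the product of
the monotherapy percent responses.  Monotherapy attenuations outside [0, 1]
(potentiating arms) are clamped with a warning since the model is undefined
there.  The additive band is ±2 percentage points — the interaction calls in
this literature are qualitative, so the band is an explicit package choice;
a result's margin (measured − expected) is always reported so borderline
calls are visible.

## Synthetic scenes

The generator renders what the scoring needs and nothing more: larvae as
oriented ellipses (8 × 3 px, intensity 0.25 on background 0.9), dots and
penny as discs, additive Gaussian noise (σ = 0.02 of dynamic range),
optional global zoom/shift.  Kinematics per larva per second: move with
probability `p_move` (0.6 default); step length Gamma(shape 12, scale 1 px)
truncated at 15 px, i.e. roughly one to two body lengths per active second;
heading persistence 0.7; reflective boundaries 6 px inside the dish wall;
and collision avoidance that re-draws a step landing within 20 px of another
larva (up to 10 tries, else the larva stays put).  A stimulus at time t₀
multiplies `p_move` by an activation factor 1 + A·exp(−ln²(dose/peak)/2w²)
(A = 2, peak 20, w = 1 in log-dose), the inverted-U profile of stimulant
locomotor activation; a drug scales the factor's excess by (1 − a), which
keeps the generated attenuation linearly recoverable as percent-of-stimulus.
Coupling the factor into the step-length scale is available
(`step_factor_exponent`) but off by default.  A `twist_prob` option injects
in-place reorientations — the error mode in which one movement appears as
two — for degradation studies; it is off in all benchmarks.

What these scenes do *not* contain: crossing or touching larvae, twisting
(unless injected), shadows, water-surface glare, dish-wall reflections, or
compression artifacts.  Passing the benchmark therefore demonstrates the
correctness of the differencing/matching/accounting machinery under the
apparatus's intended imaging conditions, not robustness to every failure
mode of real video; the published validation against manually counted
movements identifies twisting as the dominant real-world error source, and
that mode is deliberately excluded from the headline benchmark and available
for injection.

**Scoring.**  A true movement (step ≥ 2 px, the detectability floor) counts
as detected if some blob centroid of its dish/frame-pair lies within one
body length of the movement's midpoint — the midpoint, not the endpoints,
because a sub-body-length move yields blobs near the midpoint; this choice
also means steps beyond two body lengths would not score as detected, which
the step-length truncation keeps out of the benchmark by construction.  A
matched pair is correct if both endpoints lie within tolerance of the true
before/after positions.  Distance error is the per-dish relative error of
total distance.

**Benchmark scale.**  The validation-scale benchmark uses 2 dishes × 10
larvae × 60 frame pairs with p_move = 591/1200 so the expected movement
count is ≈591; it runs in a few seconds.  Parameter-recovery checks use ten
default scenes (seeds 0–9); dose-response and drug-recovery checks simulate
trajectories only (no rendering) with 3 replicate dishes per condition and
300-second assays, sizes chosen to keep the whole suite fast while leaving
the statistical margins wide.

## Numerical and design choices

- Grayscale conversion is the unweighted channel mean; no colorspace is
  assumed.  Subsampling takes the nearest native frame per tick, ties to the
  earlier frame.  PNG frame directories are the canonical fixture medium
  because containers decode codec-dependently.
- Frame iteration is streaming (constant memory in recording length);
  results CSVs round-trip losslessly through pandas with a fixed schema.
- Greedy closest-first matching is intentionally *not* an optimal-assignment
  solver — it is the described closest-point method — but tests verify it
  coincides with the exhaustive optimum whenever inter-larva spacing exceeds
  twice the maximum displacement, the regime the dishes are stocked for.
- Sorting conventions (blobs by dish then x, dots by x then y, deterministic
  tie-breaks) plus per-frame seeded noise streams make every pipeline output
  byte-reproducible from (inputs, config, seed).
- Degenerate inputs fail loudly with typed errors mapped to distinct CLI
  exit codes; empty dishes, empty masks and all-zero conditions are valid
  data, not errors, except where normalization would divide by zero.

## Limitations

Identity is not tracked across seconds — the output is movement events per
frame pair, so per-larva trajectories, velocities and turn statistics are
out of scope.  Real-video robustness (twisting, occlusion, reflections) is
not claimed, only exposed as injectable degradations.  The t-test flavor and
the replicate-as-unit choice are explicit configuration, since screen
designs vary on both.
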