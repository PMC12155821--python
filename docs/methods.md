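# Methods

## Reconstruction model

The depth camera exposes no intrinsics; calibration instead provides a
look-up table (LUT) of per-pixel unit ray directions in depth-camera
coordinates. Rays are normalized at load time, and a depth reading d (mm)
is interpreted as the **ray length**, so the camera-frame point of pixel
(u, v) is `ray(u,v) * d` — not a z-depth. Points then traverse the rigid
chain

```
world = Rig2World_Depth · Rig2Cam_Depth⁻¹ · p_cam
p_rgb_cam = Cam2World_RGB⁻¹ · world
(u', v') = perspective(K_RGB · p_rgb_cam)
```

Perspective division by the RGB-camera-frame z is applied explicitly:
without it the intrinsics product yields (u·z, v·z, z), which is not in
pixels. Points with z ≤ 1e-6 m are discarded before division; survivors
are kept when 0 ≤ u' < width and 0 ≤ v' < height (0-based pixel centers
at integer coordinates). The retained (pixel, world-point) pairs form the
RGB-depth composite.

2D hand landmarks arrive as 21 normalized coordinates per RGB frame from
a pluggable detector adapter (`detect(image) -> (21, 2) in [0,1] or
None`); multiplying by the image width/height gives pixels. Each landmark
takes the world point of the composite entry with minimum 2D pixel
distance; ties resolve to the lowest row-major depth-pixel index, which
is deterministic because composite entries are stored in that order.

### Validity and interpolation

Each RGB frame is paired to the depth frame minimizing the absolute
timestamp difference. The missing-depth threshold is computed as half the
median depth-frame period rather than hard-coded (11.1 ms at 45 Hz), so
rigs at other rates work unchanged. A sample is invalid when its pairing
exceeds that threshold, when the ray length of *any* selected composite
entry falls outside 15–45 cm (the rule is applied per landmark to the
depth actually used, the most conservative reading), or when detection
fails. Invalid samples are rebuilt by per-coordinate linear interpolation
between the nearest valid neighbours; leading/trailing gaps hold the
nearest valid sample, since linear interpolation is undefined at the
edges. A trial with zero valid samples raises a quality error, mirroring
trial exclusion in practice. During full-bundle reconstruction the
composite is built over all returning pixels and the 15–45 cm test is
applied to the selected entries, so a landmark hovering over an
out-of-range region invalidates its sample instead of silently lifting
to a distant in-range point.

## Kinematics

Processing order is fixed: resample (60 Hz, linear) → trim (first 2 s,
last 1 s) → thumb-index 3D distance in cm → optional cross-system lag
alignment → low-pass → velocity → segmentation → summary.

* **Filter**: 4th-order Butterworth, 5 Hz cutoff, applied
  forward-backward (`sosfiltfilt`) so cycle timing carries no group
  delay; a config switch selects a single causal pass. The effective
  passband gain for a tone at frequency f is `1/(1 + (f/5)⁸)` (two
  passes): 0.1 % loss at 2 Hz, ≈4 % at 3.4 Hz. This bounds how exactly
  per-cycle amplitude can be recovered for fast taps and is inherent to
  the published processing chain, not an implementation artifact.
* **Velocity**: central differences, `v[i] = (x[i+1] − x[i−1])/(2Δt)`,
  one-sided at the ends; opening (distance increasing) is positive.
  Central differencing attenuates a tone by `sin(ωΔt)/(ωΔt)` (0.7 % at
  2 Hz, 1.6 % at 3 Hz at 60 Hz sampling).
* **Segmentation**: local minima of the distance signal found on the
  negated signal with topographic prominence ≥ 0.5 cm; the ≥ 0.15 s
  separation is enforced by greedy retention in decreasing prominence
  order. Consecutive minima bound one tap cycle; fewer than two minima
  means zero cycles, which is a valid (flagged) outcome.
* **Per-cycle metrics**: `Dur` = time between bounding minima, `Freq` =
  1/`Dur` exactly, `Amp` = in-cycle maximum minus the *initial* closure
  value (not the deeper of the two), `MaxCloseVel` reported as a
  magnitude. Cycles without interior samples are dropped with a warning.
* **Summary**: CVs use the sample standard deviation (n−1), the
  conventional choice at the small cycle counts of a 20 s trial. NPL is
  computed over the whole trimmed, filtered signal independently of
  cycle detection. With zero cycles the means/CVs are NaN and NPL is
  still reported.
* **Cross-system alignment** mean-centers the signals, shifts each
  non-reference signal by the integer lag maximizing its
  cross-correlation with the reference, and cuts all to the common
  overlap. It is used only for equivalence studies, never for
  single-system metrics.

## Statistics

Equivalence of a candidate system to the reference uses a linear mixed
model `value ~ system (+ group)` with random intercepts for participant
and for trial within participant, fitted by REML (statsmodels). The
published analyses report single "equivalence p-values" without spelling
out the construction; this package operationalizes them as TOST: the
system fixed effect is tested against ±margin where margin = 5 % of the
reference grand mean, and the reported p is the larger one-sided
p-value, so p < α declares equivalence. Known-group comparisons fit
`value ~ group` with participant random intercepts.

Fixed-effect tests use t references with containment-style denominator
degrees of freedom — residual df (n_obs − n_participants − p) for the
within-participant system effect, between-participant df
(n_participants − 2) for the group effect — recorded in the result's
`df_method` field. Kenward–Roger (and Satterthwaite) corrections are not
available in the Python mixed-model backend; at the cohort sizes this
package targets (tens of participants) the difference from
containment df is negligible, and simulation under the null shows the
group test rejecting at 5.0–5.6 % across seeds (the acceptance script
recomputes this). Descriptive group means/SDs and Hedges' g (pooled SD,
small-sample correction `J = 1 − 3/(4n − 9)`) use participant-level
values collapsed across hands/trials before group summaries.

Percent differences between systems are `100·(candidate − reference) /
reference` computed from grand means (a per-trial-difference variant is
not provided; grand-mean-based reproduces the published worked values).

## Synthetic rig

The generator emulates the study conditions, not photorealistic data:

* **Waveform**: thumb-index distance is a concatenation of raised-cosine
  open-close cycles, `d = d₀ + A_k (1 − cos 2πφ)/2`, with per-cycle
  amplitude `A_k = A₀(1−decrement)^k · ε_k` (multiplicative normal
  dispersion, floor 0.05), per-cycle duration `D_k = D₀ · η_k`, and an
  optional apex-position skew that decouples opening from closing
  velocity. Raised cosine gives zero velocity at closures, so cycles
  join C¹-smoothly for any amplitude sequence, and each cycle is a
  single harmonic at 1/D_k — its amplitude survives the 5 Hz filter
  predictably. Closed forms used as oracles: peak opening velocity
  `πA/(2cD)`, closing `πA/(2(1−c)D)` (apex fraction c), path length 2A
  per cycle. Amplitude draws are capped so closure distance + amplitude
  never exceeds 16 cm, the anatomical ceiling of thumb-index span.
* **Profiles**: healthy-control-like defaults (11.3 cm, 3.38 Hz,
  amp CV 0.24, freq CV 0.12) and Parkinson-like defaults (8.40 cm,
  3.42 Hz, amp CV 0.34, freq CV 0.16, mild decrement) follow published
  cohort moments for unconstrained finger tapping; cohort simulation
  draws participant-level parameters from those (mean, SD) pairs with
  physiological clipping, two trials per participant with 5 %
  between-trial jitter.
* **Rendering**: a rigid virtual rig (640x360 @ 30 Hz RGB, 512x512 @
  45 Hz depth, pinhole depth LUT with f = 256 px, ~3 cm RGB baseline,
  small off-axis rig rotations so the transform chain is exercised)
  writes integer-millimeter ray lengths splatted as radius-3 discs
  around each projected landmark — large enough that nearest-pixel
  lifting lands on the disc despite sub-pixel landmark jitter. The
  depth clock is offset by a third of its period by default so pairing
  offsets are realistic but below threshold; Gaussian depth noise and
  random frame drops are available. The oracle landmark track is the
  exact RGB projection of ground truth and stands in for the neural
  detector.
* **What it does not emulate**: real RGB imagery (and hence detector
  error statistics), hand articulation beyond the thumb-index axis,
  surface geometry (discs, not a hand mesh), occlusion, tremor, motion
  blur, or rolling shutter. Passing tests therefore demonstrate the
  correctness of the geometry, signal processing, and statistics — not
  the accuracy of any particular 2D detector on real video.

## Problem sizes and numerical choices

The end-to-end fixture renders a 10 s trial (2.5 Hz, 6 cm, mild
dispersion) at full 512x512/45 Hz resolution; a 10 s bundle keeps the
depth archive at ~250 MB of temporary I/O while containing ~17
analyzable cycles after the 3 s trim. The geometric round-trip check
uses ~10⁴ points on depth-pixel rays in the region both cameras see;
the 2 mm position claim is validated on a synchronized-clock variant
(60 Hz depth, zero offset) because with interleaved clocks the lifted
point reflects the hand at the depth frame's timestamp, adding
fingertip-speed × clock-offset of motion skew that is a property of the
capture geometry, not of the reconstruction. Statistical calibration
uses 500 null replicates at the published cohort shape (24 + 55
participants, two trials); replicate seeds are spawned from one master
generator, since large batches of consecutive integer seeds showed
measurable rate artifacts. Tie-breaking, edge handling, and degenerate
inputs (empty composites, zero-variance signals, zero cycles) are
specified in the relevant docstrings and covered by tests.

## Known limitations

* Mixed-model df are containment-style, not Kenward–Roger; p-values for
  very small cohorts (< ~10 participants) should be treated as
  approximate.
* The equivalence margin is anchored to the reference grand mean; for
  outcomes whose mean is near zero the ±5 % margin becomes degenerate
  (rejected with a contract error rather than silently tested).
* The renderer's disc splats do not occlude like a real hand; depth
  noise is i.i.d. Gaussian, while real time-of-flight noise is
  range- and reflectivity-dependent.
* `MaxCloseVel`/`MaxOpenVel` recovery degrades above ~3.5 Hz tapping due
  to the 5 Hz filter and central-difference attenuation documented
  above, as it does in any pipeline with those published settings.
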