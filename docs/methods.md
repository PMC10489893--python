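# Methods

This note documents the models implemented in `virtualgate`, the parameter
defaults and why they hold, the simulation conditions, and the design choices
made where the underlying method description left the design open.

## Detection model

The barrier statistic is the region-banded mean squared error between
consecutive frames: per pixel, squared channel differences are summed over
the k channels (k = 3 RGB, k = 1 grayscale) and averaged over the n pixels of
the region Ω. Properties relied on throughout:

* **Size invariance.** The 1/n normalisation makes the statistic independent
  of region size, so one sensitivity threshold θ serves all regions of a
  multi-barrier.
* **Outlier sensitivity.** Squaring emphasises large per-pixel changes, which
  is what a crossing produces.

The decision is `1 iff MSE > θ + τ` with a *strict* inequality — an MSE
exactly at the boundary is not a trigger. θ defaults to 400; τ is the noise
floor, defined as the **maximum** consecutive-pair MSE over a static
calibration scene, so that both sensor noise and slow background
perturbation (foliage, flicker) are folded into one conservative bound. τ
defaults to 0 when no calibration has been run; the CLI warns in that case.

MSE is computed in floating point on 8-bit channel values. For
firmware-faithful studies a native-RGB565-domain variant
(`mse_diff_rgb565_native`) computes on truncated 5/6-bit values; the
expanded 8-bit path is the default because it keeps magnitudes comparable
across acquisition modes. RGB565 expansion uses bit replication rather than
zero padding so full-scale white maps to 255. Grayscale conversion is the
unweighted channel mean (the metric treats channels symmetrically, so
perceptual weighting would be unmotivated); colour mode is the default since
grayscale collapses chromatic contrast (a dark shirt against dark tarmac).

### Multi-barrier and trigger policy

A multi-barrier fires only when every region's decision is 1 **on the same
frame pair** — the strictest reading of simultaneity; a tolerance-window
variant is a possible future option. Design choices where the method
description is silent:

* **Event timestamp** = capture time of the *later* frame of the pair (the
  first frame exhibiting motion); `earlier_frame` and `midpoint` conventions
  are selectable.
* **Refractory period** default 1000 ms: one athlete's limbs, torso and
  trailing edge produce a single event. Configurable per gate.
* **Default region**: a full-height band 6 columns wide centred horizontally
  (960 pixels at 240×160), emulating a beam spanning the track at the
  measurement line; fully configurable.
* The emulation evaluates every captured frame (the real firmware sustains
  ~26 fps; frame skipping under load is not modelled).

## Camera emulation

Synthetic streams emulate the target camera module: 240×160 (HQVGA-class)
RGB at 25 fps, 8 bits per channel with an optional RGB565 quantisation pass.
Timestamps are integer milliseconds, `round(i·1000/fps)`; sub-millisecond
precision is not modelled. Rolling-shutter geometric skew, JPEG artefacts
and camera-shake trajectories are out of scope.

### Sensor noise calibration

Noise is i.i.d. Gaussian per channel per frame, rounded and clamped to
[0, 255] — the simplest model consistent with a single scalar noise figure.
For two independently-noised frames each channel difference has variance
2σ², so the expected three-channel MSE is 6σ² and a target MSE m needs
σ = √(m/6). The package default σ = 2.0 targets MSE 24, the midpoint of the
20–30 band measured on the real sensor across lighting conditions.
(Rounding adds ~1/12 quantisation variance per channel per frame, lifting
the realised mean MSE by ≈ 2% — well inside the band.) The maximum over
~50–150 pairs of a ~960-pixel region concentrates a few percent above the
mean, which is why the *max*-based τ estimate still lands inside 20–30.

### Crossing scenes and ground truth

The athlete is a solid high-contrast rectangle (optional ellipse)
translating horizontally at constant speed; defaults — 40×120 px at
800 px/s against a mid-gray background — correspond to a torso sprinting at
~6.7 m/s seen at roughly 120 px/m. Ground truth is the *continuous* instant
the silhouette's leading edge reaches the crossing column (default: the
centre of the detection band); it is deliberately not snapped to the frame
grid, so only the detector's report is quantised. Lighting steps (global
clamped offsets from a given time) and periodic patch flicker reproduce the
documented false-positive modes; a large-enough step provably fires the
barrier (a global Δ = 40 step gives MSE 3·40² = 4800 ≫ θ+τ), and the tests
exercise this as a negative control. All generators are bit-exact
reproducible from (spec, seed).

What the synthetic scenes do **not** emulate: articulated limbs (so
"chest vs. limb" trigger ambiguity of the real system never arises),
photorealistic texture, shadows, wind-induced camera motion. Passing tests
therefore demonstrate the correctness of the measurement chain and its
quantisation behaviour, not robustness to every field condition.

## Clock synchronization

Gates and controller keep independent millisecond clocks. Each ping carries
the controller clock out (`t_send`), the gate clock back (`t_device`), and is
received at `t_recv`. The midpoint (Cristian-style) estimator
`o = t_device − (t_send + t_recv)/2` has per-ping error
(forward − backward)/2, bounded by rtt/2 and zero under symmetric latency.
A session averages 20 pings after discarding those with rtt > 1.5× the
median rtt (radio latency is volatile and heavy-tailed; trimming removes the
most asymmetric round trips, and the rule can never discard everything since
at least the at-or-below-median half survives). Averaging N pings with
i.i.d. one-way latency of standard deviation s gives a standard error
s/√(2N); the suite checks recovery at 3× this bound as an RMS over seeded
trials (an RMS rather than per-trial bound, since individual ~Gaussian
errors exceed 3×SE with probability ≈ 0.3% and some of 1000 trials would by
construction). Clock drift within a session is assumed zero — the protocol
re-synchronises on every connection. Simulated latencies are lognormal
(median 30 ms, log-sd 0.8 by default), matching "a few to several hundred
milliseconds" of volatile radio delay.

## Timing

Elapsed times are computed in the controller domain from offset-corrected
trigger timestamps and paired greedily in chronological order, with
plausibility bounds (default 1–30 s for a 25 m flying run) that reject limb
double-triggers surviving the refractory logic. Repeated gate ids in the
gate order support shuttle courses. With identical frame rates and perfect
sync, elapsed times are exact multiples of the 1000/fps ms resolution; the
clock-offset residual adds a real-valued term. Single-athlete operation is
assumed (as in the validation protocol); multi-athlete disambiguation is out
of scope.

## Agreement analysis and simulated validation

Bland–Altman statistics use the sample standard deviation (n−1) and 1.96
limits; boundary points count as within (immaterial on continuous data).
The two validation experiments are replicated as Monte-Carlo simulations,
since the original trial data are not packaged: true flight times uniform on
3.5–7.5 s (84 runs, children) or 3.0–6.5 s (45 runs, adults), reference =
truth, camera = truth + Normal(94, 62) ms or Normal(−52, 91) ms snapped to
the 40 ms grid. The within-limits percentage of one realisation is
integer-valued (multiples of 1/n), so comparisons average ≥ 100 seeded
replicates; the acceptance script uses 200. The end-to-end harness drives
the full chain — two crossing scenes per run separated by a known interval,
independent device-clock offsets uniform in ±60 s, ping-based correction,
detection, pairing — and reports the error distribution against ground
truth; missed detections are counted, never silently dropped. Scene sizes in
the default suite (e.g. 2 s scenes, 100 runs) were chosen to keep the full
simulation battery comfortably small while leaving the statistics stable.

## Numerical and degenerate-input notes

* MSE accumulates in float64; the brute-force oracle agreement is asserted
  at 1e-9 relative error.
* An infinite frame rate in the experiment simulator disables grid snapping
  (resolution 0 ms) rather than dividing by zero.
* Streams require ≥ 2 frames everywhere a frame pair is consumed; empty
  regions, non-disjoint multi-barrier regions, negative latencies and
  non-positive thresholds are rejected at construction.
* Zero-contrast silhouettes (colour equal to background) are representable
  and yield no trigger — the documented dark-on-dark failure mode.

## Known limitations

* The noise model is stationary and white; real sensors show
  lighting-dependent, spatially correlated noise (the 20–30 band already
  spans lighting variation, but extremes are not modelled).
* The latency model is symmetric in distribution; systematically asymmetric
  radio paths would bias the midpoint estimator by half the mean asymmetry.
* Bland–Altman confidence intervals on the limits, and regression-based
  limits, are not implemented.
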