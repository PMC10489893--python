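# virtualgate

Camera-based **virtual photoelectric barrier** timing gates for short-distance
sprint measurement, as software: a tested implementation of the detection
method, the clock synchronization, the run timing, and the simulation and
agreement-analysis harness used to validate it.

## The problem

Flying sprints (a running start, timed between two gates so reaction time is
excluded) are a staple diagnostic in track-and-field training. Professional
reflective-photocell gates are accurate (~30 ms) but expensive; stopwatches
are cheap but ~350 ms. A low-cost alternative replaces each light beam with a
cheap camera: a narrow image region across the track acts as a *virtual
barrier*, and frame-to-frame change in that region above a threshold is
interpreted as an athlete crossing the measurement line. This package is for
sports scientists and practitioners who want to study, simulate, or extend
that measurement chain.

## The method

For a consecutive image tuple {I_t, I_t+1} and a region Ω of n pixels, the
change statistic is the mean squared error over the region,

    MSE(I_t, I_t+1) = (1/n) Σ_{y∈Ω} (ΔI^r)² + (ΔI^g)² + (ΔI^b)²

(one channel for grayscale), and the barrier decision is

    B(I_t, I_t+1) = 1  iff  MSE > θ + τ

with θ a user sensitivity threshold (default 400) and τ the **noise floor** —
the maximum consecutive-pair MSE observed in a static scene (typically MSE
20–30 for the emulated sensor). Because the MSE is size-invariant, several
disjoint regions can share one θ (a *multi-barrier*, which fires only when all
regions exceed threshold on the same frame pair, rejecting limb-only
triggers). Each gate timestamps triggers on its own clock; a Cristian-style
midpoint estimator over repeated ping round-trips maps gate time into the
controller's clock domain, and start/finish triggers are paired into runs.
At 25 frames per second the theoretical timing resolution is 1000/25 = 40 ms.

Accuracy is assessed the standard way for method comparison: Bland–Altman
limits of agreement, bias ± 1.96·SD of the paired differences.

## Worked example

```python
import numpy as np
from virtualgate import *

# calibrate the noise floor on a static synthetic scene (240x160 @ 25 fps)
static = make_static_scene(SceneSpec(duration_s=2.0, noise_sd=2.0, seed=3))
region = default_region(160, 240)          # full-height 6-column band
tau = estimate_noise(static, region)

# detect a high-contrast silhouette crossing the band
spec = SceneSpec(duration_s=2.0, noise_sd=2.0,
                 silhouette=Silhouette(start_col=-60.0), seed=3)
stream, gt = make_crossing_scene(spec)
cfg = BarrierConfig(regions=[region], theta=400.0, tau_per_region=[tau])
events = detect_triggers(stream, cfg, gate_id="start")

# synchronize a gate clock from simulated ping round-trips
pings = simulate_ping_session(true_offset_ms=8421.0, n_pings=20,
                              rng=np.random.default_rng(0))
offset = estimate_offset(pings)

# replicate a field validation experiment (n=84 paired timings)
stats, _ = simulate_experiment(n_trials=84, bias_ms=94.0, sd_ms=62.0, seed=1)
```

This prints (via the obvious f-strings):

```
noise floor tau = 25.8
ground-truth crossing 225.0 ms, trigger at 240 ms (MSE 18180)
estimated clock offset 8417.2 ms (15 pings kept)
replicate: bias 88 ms, LoA [-29, 205] ms, 79/84 within (94.05%)
```

Reading the numbers: the calibrated sensor noise lands in the expected 20–30
MSE band, far below θ = 400. The detector reports the crossing at the first
frame after the true 225.0 ms instant — a 15 ms error, inside the 40 ms frame
interval. The clock offset is recovered to ~4 ms despite volatile simulated
radio latency (5 heavy-tailed pings rejected). The simulated validation run
puts 79 of 84 paired differences inside the 95% limits of agreement.

There is also a CLI mirroring the field workflow:

```sh
virtualgate simulate scene.json --seed 1 --out scene/     # render a scene
virtualgate calibrate scene/frames --config gate.json     # write tau back
virtualgate detect scene/frames --config gate.json --out triggers.csv
virtualgate time --start-events a.csv --finish-events b.csv --out runs.csv
virtualgate evaluate experiment.json --seed 1 --out eval/
```

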