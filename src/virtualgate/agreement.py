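"""Bland-Altman method comparison and Monte-Carlo validation experiments.

The accuracy of the camera-based system (CBS) against a reference timing
system is evaluated the standard way for method comparison in sports and
clinical science: Bland-Altman limits of agreement.  For paired timings the
per-trial difference d_i = candidate - reference is summarised by

    bias = mean(d),   LoA = bias +/- 1.96 * sd(d)     (sample sd, n-1)

with ~95% of differences expected inside the limits when errors are roughly
normal.  This module provides the statistic, a simulator that replicates the
field validation protocol (reference = true flight time; candidate = true
time plus a normal timing error snapped to the camera's frame grid), and an
end-to-end harness that drives the full pipeline — synthetic scenes, trigger
detection, clock sync and run pairing — and reports the error distribution
against the scenes' ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .detection import BarrierConfig, default_region, detect_triggers, estimate_noise
from .errors import InputError
from .sync import estimate_offset, simulate_ping_session, to_controller_time
from .synth import SceneSpec, make_crossing_scene, make_static_scene
from .timing import pair_runs, resolution_ms

__all__ = [
    "PairedTimes",
    "AgreementStats",
    "EndToEndResult",
    "bland_altman",
    "bland_altman_plot",
    "simulate_experiment",
    "end_to_end_accuracy",
]


@dataclass(frozen=True)
class PairedTimes:
    """Paired trial timings from two systems, in seconds."""

    reference_s: tuple[float, ...]
    candidate_s: tuple[float, ...]
    reference_label: str = "reference"
    candidate_label: str = "candidate"

    def __post_init__(self) -> None:
        if len(self.reference_s) != len(self.candidate_s):
            raise InputError("paired series must have equal length")
        if len(self.reference_s) < 2:
            raise InputError("need at least 2 paired trials")
        if any(t <= 0 for t in self.reference_s + self.candidate_s):
            raise InputError("all times must be positive")

    @property
    def n(self) -> int:
        return len(self.reference_s)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.candidate_s) - np.asarray(self.reference_s)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired differences (candidate - reference)."""

    n: int
    bias_s: float
    sd_s: float
    loa_low_s: float
    loa_high_s: float
    n_within: int

    @property
    def pct_within(self) -> float:
        return 100.0 * self.n_within / self.n

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "bias_s": self.bias_s,
                "sd_s": self.sd_s,
                "loa_low_s": self.loa_low_s,
                "loa_high_s": self.loa_high_s,
                "n_within": self.n_within,
                "pct_within": self.pct_within,
            },
            indent=2,
        )


def bland_altman(paired: PairedTimes) -> AgreementStats:
    """Limits-of-agreement statistics for paired timings.

    The sd uses the n-1 denominator and the limits the conventional 1.96
    multiplier; differences exactly on a limit count as within (immaterial
    for continuous data, and the generous reading for ties).
    """
    d = paired.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    n_within = int(np.sum((d >= lo) & (d <= hi)))
    return AgreementStats(
        n=paired.n, bias_s=bias, sd_s=sd, loa_low_s=lo, loa_high_s=hi, n_within=n_within
    )


def bland_altman_plot(paired: PairedTimes, stats: AgreementStats | None = None):
    """Standard Bland-Altman plot: mean vs difference, bias line, both limits.

    Returns a matplotlib Figure; callers save or show it.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if stats is None:
        stats = bland_altman(paired)
    ref = np.asarray(paired.reference_s)
    cand = np.asarray(paired.candidate_s)
    means = (ref + cand) / 2.0
    diffs = cand - ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, label="trials")
    ax.axhline(stats.bias_s, color="k", label=f"bias {stats.bias_s * 1000:.0f} ms")
    ax.axhline(stats.loa_low_s, color="r", linestyle="--",
               label=f"LoA {stats.loa_low_s * 1000:.0f} ms")
    ax.axhline(stats.loa_high_s, color="r", linestyle="--",
               label=f"LoA {stats.loa_high_s * 1000:.0f} ms")
    ax.set_xlabel(f"mean of {paired.reference_label} and {paired.candidate_label} (s)")
    ax.set_ylabel(f"{paired.candidate_label} - {paired.reference_label} (s)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def simulate_experiment(
    n_trials: int,
    bias_ms: float,
    sd_ms: float,
    fps: float = 25.0,
    true_time_range_s: tuple[float, float] = (3.5, 7.5),
    seed: int | np.random.Generator | None = 0,
) -> tuple[AgreementStats, PairedTimes]:
    """Monte-Carlo replicate of a gate-validation experiment.

    True flight times are uniform on ``true_time_range_s``; the reference
    system reports the truth; the camera system reports truth plus a
    Normal(bias_ms, sd_ms) error snapped to the camera's frame grid
    (multiples of 1000/fps ms).  Returns the Bland-Altman statistics and the
    simulated pairs.
    """
    if n_trials < 2:
        raise InputError("need at least 2 trials")
    if sd_ms < 0:
        raise InputError("sd_ms must be non-negative")
    lo, hi = true_time_range_s
    if not (0 < lo <= hi):
        raise InputError("invalid true-time range")
    rng = np.random.default_rng(seed)
    truth_s = rng.uniform(lo, hi, size=n_trials)
    error_s = rng.normal(bias_ms, sd_ms, size=n_trials) / 1000.0
    res_s = resolution_ms(fps) / 1000.0
    if res_s > 0:
        candidate_s = np.round((truth_s + error_s) / res_s) * res_s
    else:  # infinite frame rate: no quantization
        candidate_s = truth_s + error_s
    paired = PairedTimes(
        reference_s=tuple(truth_s),
        candidate_s=tuple(candidate_s),
        reference_label="reference gates",
        candidate_label="camera gates",
    )
    return bland_altman(paired), paired


@dataclass(frozen=True)
class EndToEndResult:
    """Error summary of full-pipeline simulated sprints."""

    stats: AgreementStats
    errors_ms: tuple[float, ...]
    n_runs_requested: int
    n_detected: int

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_runs_requested

    @property
    def max_abs_error_ms(self) -> float:
        return max(abs(e) for e in self.errors_ms) if self.errors_ms else float("nan")


def end_to_end_accuracy(
    scene_template: SceneSpec,
    n_runs: int,
    gate_separation_s: float = 4.0,
    seed: int = 0,
    theta: float | None = None,
    n_pings: int = 20,
    clock_offset_range_ms: tuple[float, float] = (-60_000.0, 60_000.0),
) -> EndToEndResult:
    """Drive the whole pipeline on simulated two-gate sprints.

    For each run two crossing scenes are generated (start and finish gate),
    the finish gate's frames delayed by ``gate_separation_s`` in controller
    time.  Each gate's device clock carries an independent random offset;
    the offsets are re-estimated from simulated lognormal-latency ping
    sessions, triggers are detected with a calibrated noise floor, converted
    to controller time and paired into runs.  The elapsed times are compared
    with the ground-truth elapsed time; missed detections are counted, never
    silently dropped.
    """
    if n_runs < 2:
        raise InputError("need at least 2 runs")
    if scene_template.silhouette is None:
        raise InputError("scene template must include a silhouette")
    rng = np.random.default_rng(seed)
    theta = theta if theta is not None else 400.0

    region = default_region(scene_template.height, scene_template.width)
    # calibrate tau once on a matching static scene
    static_spec = replace(
        scene_template,
        silhouette=None,
        duration_s=2.0,
        seed=int(rng.integers(2**31)),
    )
    tau = estimate_noise(make_static_scene(static_spec), region)
    config = BarrierConfig(regions=[region], theta=theta, tau_per_region=[tau])

    truths_s: list[float] = []
    measured_s: list[float] = []
    errors_ms: list[float] = []
    n_detected = 0
    sep_ms = gate_separation_s * 1000.0
    for _ in range(n_runs):
        offsets_true = rng.uniform(*clock_offset_range_ms, size=2)
        specs = [
            replace(scene_template, seed=int(rng.integers(2**31))) for _ in range(2)
        ]
        events_ctrl: dict[str, list[float]] = {"start": [], "finish": []}
        gts = []
        for g, (gate, spec, off) in enumerate(
            zip(("start", "finish"), specs, offsets_true)
        ):
            stream, gt = make_crossing_scene(spec)
            gts.append(gt)
            base = 0.0 if gate == "start" else sep_ms
            # device clock = controller clock + off; frames start at `base`
            shifted = [
                f.__class__(
                    pixels=f.pixels,
                    capture_time=round(f.capture_time + base + off),
                    index=f.index,
                )
                for f in stream
            ]
            dev_stream = stream.__class__(
                frames=shifted, nominal_fps=stream.nominal_fps, source=stream.source
            )
            events = detect_triggers(dev_stream, config, gate_id=gate)
            pings = simulate_ping_session(
                off, n_pings=n_pings, rng=np.random.default_rng(int(rng.integers(2**31)))
            )
            est = estimate_offset(pings)
            events_ctrl[gate] = [to_controller_time(e.device_time_ms, est) for e in events]

        truth_elapsed_s = (sep_ms + gts[1].crossing_time_ms - gts[0].crossing_time_ms) / 1000.0
        runs = pair_runs(events_ctrl, ["start", "finish"],
                         min_elapsed_s=1.0, max_elapsed_s=max(30.0, truth_elapsed_s + 5))
        if runs:
            n_detected += 1
            truths_s.append(truth_elapsed_s)
            measured_s.append(runs[0].elapsed_s)
            errors_ms.append((runs[0].elapsed_s - truth_elapsed_s) * 1000.0)

    if len(measured_s) < 2:
        raise InputError(
            f"only {len(measured_s)} of {n_runs} runs produced a timing; "
            "cannot form agreement statistics"
        )
    paired = PairedTimes(
        reference_s=tuple(truths_s),
        candidate_s=tuple(measured_s),
        reference_label="ground truth",
        candidate_label="camera gates",
    )
    return EndToEndResult(
        stats=bland_altman(paired),
        errors_ms=tuple(errors_ms),
        n_runs_requested=n_runs,
        n_detected=n_detected,
    )
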