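"""The virtual photoelectric barrier core.

A gate is a narrow image region (or several disjoint regions) in which the
frame-to-frame mean squared error (MSE) is monitored.  For a consecutive
image tuple {I_t, I_t+1} and a region Ω of n pixels,

    MSE(I_t, I_t+1) = (1/n) * Σ_{y∈Ω} (Δr)² + (Δg)² + (Δb)²

(a single channel for grayscale).  The barrier fires when

    B(I_t, I_t+1) = 1  iff  MSE > θ + τ

where θ is the user sensitivity threshold (default 400, which is reliable in
most lighting) and τ the noise floor, estimated as the maximum
consecutive-pair MSE over a static scene.  Dividing by n makes the statistic
invariant to region size, so one θ serves every region of a multi-barrier;
τ is estimated per region.

A multi-barrier (emulating professional dual-beam gates) triggers only when
*every* region fires on the same frame pair, rejecting limb-only crossings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .frames import Frame, FrameStream, to_grayscale

__all__ = [
    "Region",
    "BarrierConfig",
    "TriggerEvent",
    "DEFAULT_THETA",
    "mse_diff",
    "estimate_noise",
    "decide",
    "detect_triggers",
    "default_region",
    "load_barrier_config",
    "save_barrier_config",
    "write_trigger_csv",
    "read_trigger_csv",
]

#: Default sensitivity threshold θ; reliable in most lighting conditions and
#: far above the typical static-scene noise floor (MSE ≈ 20-30).
DEFAULT_THETA: float = 400.0

ColorMode = Literal["rgb", "grayscale"]
TimestampConvention = Literal["later_frame", "earlier_frame", "midpoint"]


@dataclass(frozen=True)
class Region:
    """A pixel band Ω in which the change metric is computed.

    Coordinates are 0-based and half-open: columns ``[col_start, col_end)``,
    rows ``[row_start, row_end)``.
    """

    col_start: int
    col_end: int
    row_start: int
    row_end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.col_end <= self.col_start or self.row_end <= self.row_start:
            raise ConfigurationError(f"empty region: {self}")
        if self.col_start < 0 or self.row_start < 0:
            raise ConfigurationError(f"negative region bounds: {self}")

    @property
    def n_pixels(self) -> int:
        return (self.col_end - self.col_start) * (self.row_end - self.row_start)

    @property
    def center_col(self) -> float:
        return (self.col_start + self.col_end) / 2.0

    def check_within(self, height: int, width: int) -> None:
        if self.row_end > height or self.col_end > width:
            raise ConfigurationError(
                f"region {self} exceeds frame bounds {height}x{width}"
            )

    def slice_of(self, frame: Frame) -> np.ndarray:
        self.check_within(frame.height, frame.width)
        return frame.pixels[self.row_start : self.row_end, self.col_start : self.col_end]


def default_region(height: int, width: int, band_width: int = 6, label: str = "barrier") -> Region:
    """Full-height band of *band_width* columns centred horizontally.

    This mirrors how a physical gate's beam spans the full track height at
    one measurement line.
    """
    c0 = max(0, width // 2 - band_width // 2)
    return Region(col_start=c0, col_end=min(width, c0 + band_width),
                  row_start=0, row_end=height, label=label)


def _regions_disjoint(regions: Sequence[Region]) -> bool:
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if (a.col_start < b.col_end and b.col_start < a.col_end
                    and a.row_start < b.row_end and b.row_start < a.row_end):
                return False
    return True


@dataclass
class BarrierConfig:
    """Configuration of one gate: regions, thresholds and trigger policy."""

    regions: list[Region]
    theta: float = DEFAULT_THETA
    tau_per_region: list[float] | None = None
    color_mode: ColorMode = "rgb"
    refractory_ms: int = 1000
    timestamp_convention: TimestampConvention = "later_frame"

    def __post_init__(self) -> None:
        if not self.regions:
            raise ConfigurationError("at least one region is required")
        if self.theta <= 0:
            raise ConfigurationError("theta must be positive")
        if self.tau_per_region is None:
            self.tau_per_region = [0.0] * len(self.regions)
        if len(self.tau_per_region) != len(self.regions):
            raise ConfigurationError("tau_per_region length must match regions")
        if any(t < 0 for t in self.tau_per_region):
            raise ConfigurationError("tau values must be non-negative")
        if self.refractory_ms < 0:
            raise ConfigurationError("refractory_ms must be non-negative")
        if not _regions_disjoint(self.regions):
            raise ConfigurationError("regions must be pairwise disjoint")


@dataclass(frozen=True)
class TriggerEvent:
    """One gate firing: the device-clock time and per-region MSEs."""

    gate_id: str
    device_time_ms: int
    frame_index: int
    region_mse: tuple[float, ...]


def mse_diff(
    frame_a: Frame,
    frame_b: Frame,
    region: Region,
    color_mode: ColorMode = "rgb",
) -> float:
    """Mean squared error between two frames over a region.

    For RGB, squared differences of the three channels are summed per pixel
    and averaged over the n pixels of Ω; for grayscale a single channel is
    used.  Symmetric in its frame arguments and invariant to region size.
    """
    if (frame_a.height, frame_a.width) != (frame_b.height, frame_b.width):
        raise InputError("frames must share dimensions")
    if color_mode == "grayscale":
        if frame_a.channels == 3:
            frame_a = to_grayscale(frame_a)
        if frame_b.channels == 3:
            frame_b = to_grayscale(frame_b)
    elif frame_a.channels != 3 or frame_b.channels != 3:
        raise InputError("rgb color_mode requires 3-channel frames")
    a = region.slice_of(frame_a).astype(np.float64)
    b = region.slice_of(frame_b).astype(np.float64)
    d = a - b
    # per-pixel sum over channels, then mean over the n pixels of the region
    return float(np.square(d).sum() / region.n_pixels)


def estimate_noise(
    stream: FrameStream, region: Region, color_mode: ColorMode = "rgb"
) -> float:
    """Noise floor τ: maximum consecutive-pair MSE over a static scene.

    Taking the maximum (rather than the mean) folds both sensor noise and
    slow background perturbation into a single conservative bound.
    """
    if len(stream) < 2:
        raise InputError("noise estimation needs at least 2 frames")
    return max(mse_diff(a, b, region, color_mode) for a, b in stream.pairs())


def decide(mse_value: float, theta: float, tau: float) -> int:
    """Barrier decision function: 1 iff mse_value strictly exceeds θ + τ."""
    if mse_value < 0:
        raise InputError("mse_value must be non-negative")
    if theta <= 0:
        raise InputError("theta must be positive")
    if tau < 0:
        raise InputError("tau must be non-negative")
    return 1 if mse_value > theta + tau else 0


def _event_time(earlier: Frame, later: Frame, convention: TimestampConvention) -> int:
    if convention == "later_frame":
        return later.capture_time
    if convention == "earlier_frame":
        return earlier.capture_time
    if convention == "midpoint":
        return round((earlier.capture_time + later.capture_time) / 2.0)
    raise ConfigurationError(f"unknown timestamp convention {convention!r}")


def detect_triggers(
    stream: FrameStream, config: BarrierConfig, gate_id: str = "gate"
) -> list[TriggerEvent]:
    """Scan a stream and emit one :class:`TriggerEvent` per barrier firing.

    For each consecutive frame pair the gate fires iff the decision function
    is 1 for *every* configured region on that same pair (multi-barrier AND).
    After a firing, pairs whose event timestamp falls within ``refractory_ms``
    are suppressed so a single athlete produces a single event.
    """
    if len(stream) < 2:
        raise InputError("trigger detection needs at least 2 frames")
    for r in config.regions:
        r.check_within(stream.height, stream.width)
    if config.color_mode == "rgb" and stream.channels != 3:
        raise ConfigurationError("rgb color_mode requires an RGB stream")

    events: list[TriggerEvent] = []
    last_fire: int | None = None
    for earlier, later in stream.pairs():
        t = _event_time(earlier, later, config.timestamp_convention)
        if last_fire is not None and t - last_fire < config.refractory_ms:
            continue
        mses = [
            mse_diff(earlier, later, r, config.color_mode) for r in config.regions
        ]
        if all(
            decide(m, config.theta, tau)
            for m, tau in zip(mses, config.tau_per_region)
        ):
            events.append(
                TriggerEvent(
                    gate_id=gate_id,
                    device_time_ms=t,
                    frame_index=later.index,
                    region_mse=tuple(mses),
                )
            )
            last_fire = t
    return events


def mse_diff_rgb565_native(frame_a: Frame, frame_b: Frame, region: Region) -> float:
    """MSE computed directly on native 5/6-bit RGB565 channel values.

    Firmware-faithful variant: channels are truncated to their RGB565 bit
    depth (R,B: 5 bits; G: 6 bits) and differenced without expansion back to
    8 bits, so magnitudes are smaller than :func:`mse_diff` by roughly the
    squared bit-depth ratio.  Offered for emulation studies; the expanded
    8-bit path is the default everywhere else.
    """
    if frame_a.channels != 3 or frame_b.channels != 3:
        raise InputError("native RGB565 MSE requires RGB frames")
    if (frame_a.height, frame_a.width) != (frame_b.height, frame_b.width):
        raise InputError("frames must share dimensions")
    shifts = np.array([3, 2, 3], dtype=np.uint8)  # bits dropped per channel
    a = region.slice_of(frame_a) >> shifts
    b = region.slice_of(frame_b) >> shifts
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.square(d).sum() / region.n_pixels)


# ---------------------------------------------------------------------------
# Configuration and trigger-log serialization
# ---------------------------------------------------------------------------

def save_barrier_config(config: BarrierConfig, path: str | Path, gate_id: str = "gate") -> None:
    doc = {
        "gate_id": gate_id,
        "regions": [
            {
                "col_start": r.col_start,
                "col_end": r.col_end,
                "row_start": r.row_start,
                "row_end": r.row_end,
                "label": r.label,
            }
            for r in config.regions
        ],
        "theta": config.theta,
        "tau_per_region": list(config.tau_per_region),
        "color_mode": config.color_mode,
        "refractory_ms": config.refractory_ms,
        "timestamp_convention": config.timestamp_convention,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_barrier_config(path: str | Path) -> tuple[BarrierConfig, str]:
    """Load a JSON gate configuration; returns (config, gate_id)."""
    try:
        doc = json.loads(Path(path).read_text())
        config = BarrierConfig(
            regions=[Region(**r) for r in doc["regions"]],
            theta=float(doc.get("theta", DEFAULT_THETA)),
            tau_per_region=[float(t) for t in doc["tau_per_region"]]
            if doc.get("tau_per_region") is not None
            else None,
            color_mode=doc.get("color_mode", "rgb"),
            refractory_ms=int(doc.get("refractory_ms", 1000)),
            timestamp_convention=doc.get("timestamp_convention", "later_frame"),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"malformed barrier config {path}: {exc}") from exc
    return config, str(doc.get("gate_id", "gate"))


def write_trigger_csv(events: Sequence[TriggerEvent], path: str | Path) -> None:
    n_regions = max((len(e.region_mse) for e in events), default=1)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["gate_id", "frame_index", "device_time_ms"]
            + [f"mse_region_{i}" for i in range(n_regions)]
        )
        for e in events:
            writer.writerow(
                [e.gate_id, e.frame_index, e.device_time_ms]
                + [f"{m:.6f}" for m in e.region_mse]
            )


def read_trigger_csv(path: str | Path) -> list[TriggerEvent]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mses = tuple(
                float(v) for k, v in sorted(row.items()) if k.startswith("mse_region_")
            )
            events.append(
                TriggerEvent(
                    gate_id=row["gate_id"],
                    device_time_ms=int(row["device_time_ms"]),
                    frame_index=int(row["frame_index"]),
                    region_mse=mses,
                )
            )
    return events
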