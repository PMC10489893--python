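"""Clock-offset estimation between the controller and gate devices.

Each gate keeps its own millisecond clock.  The controller (a phone in the
field; here, any caller) periodically sends a ping carrying its clock value;
the gate appends its own clock and echoes the message.  One round trip gives

    t_send    controller clock at transmission
    t_device  gate clock at the reply
    t_recv    controller clock at reception

Under the usual midpoint (Cristian-style) assumption that the gate's reply
occurs halfway through the round trip, each ping yields an offset estimate

    o_i = t_device_i - (t_send_i + t_recv_i) / 2

whose error is exactly (backward - forward latency)/2, bounded by rtt/2.
Radio latency is volatile and heavy-tailed, so pings whose round-trip time
exceeds 1.5x the median RTT are discarded before averaging; with symmetric
per-ping latency the true offset is recovered exactly regardless of latency
magnitude.  Clock drift within a session is assumed zero (the system
re-synchronises on every connection).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "PingRecord",
    "ClockOffset",
    "DEFAULT_N_PINGS",
    "simulate_ping",
    "simulate_ping_session",
    "estimate_offset",
    "to_controller_time",
    "to_device_time",
    "write_ping_csv",
    "read_ping_csv",
]

#: Default number of pings per synchronization session.
DEFAULT_N_PINGS: int = 20

#: RTT outlier rejection factor (multiples of the median round-trip time).
RTT_REJECT_FACTOR: float = 1.5


@dataclass(frozen=True)
class PingRecord:
    """One ping round trip: controller send/receive and gate reply clocks (ms)."""

    t_send: float
    t_device: float
    t_recv: float

    def __post_init__(self) -> None:
        if self.t_recv < self.t_send:
            raise InputError("t_recv must not precede t_send")

    @property
    def rtt(self) -> float:
        return self.t_recv - self.t_send

    @property
    def offset_estimate(self) -> float:
        """Midpoint offset estimate for this single ping."""
        return self.t_device - (self.t_send + self.t_recv) / 2.0


@dataclass(frozen=True)
class ClockOffset:
    """Estimated gate-minus-controller clock offset."""

    offset_ms: float
    n_used: int
    rtt_median_ms: float

    def __post_init__(self) -> None:
        if self.n_used < 1:
            raise InputError("n_used must be at least 1")
        if not np.isfinite(self.offset_ms):
            raise InputError("offset must be finite")


#: Identity offset, used when no ping log is available.
ZERO_OFFSET = ClockOffset(offset_ms=0.0, n_used=1, rtt_median_ms=0.0)


def simulate_ping(
    true_offset_ms: float,
    forward_latency_ms: float,
    backward_latency_ms: float,
    controller_time_ms: float,
) -> PingRecord:
    """Construct the ping record a given offset and one-way latencies produce."""
    if forward_latency_ms < 0 or backward_latency_ms < 0:
        raise InputError("latencies must be non-negative")
    return PingRecord(
        t_send=float(controller_time_ms),
        t_device=float(controller_time_ms + forward_latency_ms + true_offset_ms),
        t_recv=float(controller_time_ms + forward_latency_ms + backward_latency_ms),
    )


def simulate_ping_session(
    true_offset_ms: float,
    n_pings: int = DEFAULT_N_PINGS,
    rng: np.random.Generator | int | None = None,
    latency_median_ms: float = 30.0,
    latency_sigma: float = 0.8,
    interval_ms: float = 100.0,
    start_time_ms: float = 0.0,
) -> list[PingRecord]:
    """Simulate a synchronization session with lognormal one-way latencies.

    Forward and backward latencies are drawn i.i.d. from a lognormal with the
    given median and log-sd, emulating volatile radio delays that range from
    a few to several hundred milliseconds.
    """
    if n_pings < 1:
        raise InputError("need at least one ping")
    rng = np.random.default_rng(rng)
    mu = np.log(latency_median_ms)
    lat = rng.lognormal(mean=mu, sigma=latency_sigma, size=(n_pings, 2))
    return [
        simulate_ping(
            true_offset_ms,
            forward_latency_ms=lat[i, 0],
            backward_latency_ms=lat[i, 1],
            controller_time_ms=start_time_ms + i * interval_ms,
        )
        for i in range(n_pings)
    ]


def estimate_offset(pings: Sequence[PingRecord]) -> ClockOffset:
    """Estimate the gate-minus-controller clock offset from ping round trips.

    Pings with RTT above 1.5x the median RTT are rejected (unless that would
    empty the set); the offset is the mean of the surviving per-ping midpoint
    estimates.
    """
    if not pings:
        raise InputError("need at least one ping")
    rtts = np.array([p.rtt for p in pings])
    median_rtt = float(np.median(rtts))
    keep = [p for p, r in zip(pings, rtts) if r <= RTT_REJECT_FACTOR * median_rtt]
    if not keep:
        keep = list(pings)
    offset = float(np.mean([p.offset_estimate for p in keep]))
    return ClockOffset(offset_ms=offset, n_used=len(keep), rtt_median_ms=median_rtt)


def theoretical_offset_se(latency_sd_ms: float, n_pings: int) -> float:
    """Standard error of the mean midpoint estimator.

    Per-ping error is (backward - forward)/2; with i.i.d. one-way latencies of
    standard deviation sd, its sd is sd/sqrt(2), and averaging N pings gives
    sd / sqrt(2 N).
    """
    if n_pings < 1:
        raise InputError("need at least one ping")
    return latency_sd_ms / np.sqrt(2.0 * n_pings)


def to_controller_time(device_time_ms: float, clock_offset: ClockOffset) -> float:
    """Map a gate-device timestamp into the controller clock domain."""
    return device_time_ms - clock_offset.offset_ms


def to_device_time(controller_time_ms: float, clock_offset: ClockOffset) -> float:
    """Inverse of :func:`to_controller_time`."""
    return controller_time_ms + clock_offset.offset_ms


def write_ping_csv(pings: Sequence[PingRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_send", "t_device", "t_recv"])
        for p in pings:
            writer.writerow([repr(float(p.t_send)), repr(float(p.t_device)),
                             repr(float(p.t_recv))])


def read_ping_csv(path: str | Path) -> list[PingRecord]:
    with open(path, newline="") as fh:
        return [
            PingRecord(
                t_send=float(row["t_send"]),
                t_device=float(row["t_device"]),
                t_recv=float(row["t_recv"]),
            )
            for row in csv.DictReader(fh)
        ]


def offset_report(offset: ClockOffset) -> str:
    """JSON offset report for logging/export."""
    return json.dumps(
        {
            "offset_ms": offset.offset_ms,
            "n_used": offset.n_used,
            "rtt_median_ms": offset.rtt_median_ms,
        },
        indent=2,
    )
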