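"""Frame and stream data model, sequence I/O and camera-fidelity transforms.

A *virtual photoelectric barrier* operates on a stream of low-resolution
camera frames.  This module provides the in-memory containers (:class:`Frame`,
:class:`FrameStream`), readers/writers for numbered PNG/PPM sequences with an
optional ``timestamps.csv`` sidecar, grayscale conversion, and an RGB565
quantizer that emulates the 16-bit colour path of the HQVGA camera module the
system targets.

Conventions
-----------
* Pixels are 8 bits per channel, stored as ``uint8`` arrays of shape
  ``(H, W, 3)`` (RGB) or ``(H, W)`` (grayscale).
* Pixel coordinates are 0-based, row-major; ranges are half-open.
* Capture timestamps are integer milliseconds on the capturing device's own
  clock; sub-millisecond precision is not modelled.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InputError

__all__ = [
    "Frame",
    "FrameStream",
    "read_frame_sequence",
    "write_frame_sequence",
    "to_grayscale",
    "quantize_rgb565",
]

_FRAME_NAME_RE = re.compile(r"(\d+)\.(png|ppm)$", re.IGNORECASE)


@dataclass(frozen=True)
class Frame:
    """One captured image plus its device-clock timestamp.

    Parameters
    ----------
    pixels
        ``uint8`` array, shape ``(H, W, 3)`` for RGB or ``(H, W)`` for
        grayscale.
    capture_time
        Integer milliseconds on the capturing device's clock.
    index
        Non-negative sequence position within the stream.
    """

    pixels: np.ndarray
    capture_time: int
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise InputError(f"pixels must be (H,W) or (H,W,3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("frame must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.index < 0:
            raise InputError("frame index must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        """Number of colour channels k (3 for RGB, 1 for grayscale)."""
        return 1 if self.pixels.ndim == 2 else 3


@dataclass
class FrameStream:
    """An ordered, homogeneous sequence of frames from one camera.

    All frames must share dimensions and channel count; indices and capture
    times must be strictly increasing.
    """

    frames: list[Frame]
    nominal_fps: float
    source: str = "memory"

    def __post_init__(self) -> None:
        if self.nominal_fps <= 0:
            raise InputError("nominal_fps must be positive")
        if self.frames:
            h, w, k = self.frames[0].height, self.frames[0].width, self.frames[0].channels
            for f in self.frames:
                if (f.height, f.width, f.channels) != (h, w, k):
                    raise FormatError("all frames in a stream must share dimensions and mode")
            times = [f.capture_time for f in self.frames]
            idx = [f.index for f in self.frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise InputError("capture times must be strictly increasing")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise InputError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def height(self) -> int:
        return self.frames[0].height

    @property
    def width(self) -> int:
        return self.frames[0].width

    @property
    def channels(self) -> int:
        return self.frames[0].channels

    def pairs(self) -> Iterator[tuple[Frame, Frame]]:
        """Yield consecutive frame tuples (I_t, I_t+1)."""
        return zip(self.frames, self.frames[1:])


def synthesize_timestamps(n: int, fps: float) -> list[int]:
    """Capture times for *n* frames on a uniform grid: round(i * 1000 / fps)."""
    if fps <= 0:
        raise InputError("fps must be positive")
    return [round(i * 1000.0 / fps) for i in range(n)]


def read_frame_sequence(directory_path: str | Path, fps: float) -> FrameStream:
    """Read a numbered PNG/PPM image sequence into a :class:`FrameStream`.

    Frames are sorted by the numeric part of their file names.  Capture times
    are synthesised from *fps* unless a ``timestamps.csv`` sidecar (columns
    ``index,capture_time_ms``) is present.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    named = []
    for p in sorted(directory.iterdir()):
        m = _FRAME_NAME_RE.search(p.name)
        if m:
            named.append((int(m.group(1)), p))
    named.sort(key=lambda t: t[0])
    if len(named) < 2:
        raise InputError(
            f"need at least 2 frames to form an image tuple, found {len(named)} in {directory}"
        )

    sidecar = directory / "timestamps.csv"
    times: dict[int, int] | None = None
    if sidecar.exists():
        times = {}
        with open(sidecar, newline="") as fh:
            for row in csv.DictReader(fh):
                times[int(row["index"])] = int(row["capture_time_ms"])

    frames: list[Frame] = []
    shape = None
    default_times = synthesize_timestamps(len(named), fps)
    for i, (_, path) in enumerate(named):
        px = np.asarray(iio.imread(path))
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha if present
            px = px[:, :, :3]
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise FormatError(
                f"mixed frame dimensions in {directory}: {px.shape} vs {shape}"
            )
        t = times.get(i, default_times[i]) if times is not None else default_times[i]
        frames.append(Frame(pixels=px.astype(np.uint8), capture_time=t, index=i))
    return FrameStream(frames=frames, nominal_fps=fps, source=str(directory))


def write_frame_sequence(stream: FrameStream, directory_path: str | Path) -> Path:
    """Write a stream as ``frame_000000.png ...`` plus a ``timestamps.csv`` sidecar.

    Round-trips bit-exactly through :func:`read_frame_sequence`.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stream):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame.pixels)
    with open(directory / "timestamps.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "capture_time_ms"])
        for i, frame in enumerate(stream):
            writer.writerow([i, frame.capture_time])
    return directory


def to_grayscale(frame: Frame) -> Frame:
    """Convert an RGB frame to single-channel grayscale.

    Uses the unweighted channel mean rounded to the nearest integer: the MSE
    change metric treats the three channels symmetrically, so no perceptual
    weighting is applied.  Grayscale input passes through unchanged.
    """
    if frame.channels == 1:
        return frame
    gray = np.rint(frame.pixels.astype(np.float64).mean(axis=2)).astype(np.uint8)
    return Frame(pixels=gray, capture_time=frame.capture_time, index=frame.index)


def quantize_rgb565(frame: Frame) -> Frame:
    """Project an 8-bit RGB frame through the RGB565 colour path.

    R and B are truncated to 5 bits, G to 6 bits, then expanded back to
    8 bits by bit replication (the high bits are copied into the vacated low
    bits).  Bit replication keeps full-scale white at 255, so change-metric
    magnitudes stay comparable with native 8-bit streams.  Idempotent.
    """
    if frame.channels != 3:
        raise InputError("RGB565 quantization requires an RGB frame")
    px = frame.pixels
    r5 = px[:, :, 0] >> 3
    g6 = px[:, :, 1] >> 2
    b5 = px[:, :, 2] >> 3
    out = np.empty_like(px)
    out[:, :, 0] = (r5 << 3) | (r5 >> 2)
    out[:, :, 1] = (g6 << 2) | (g6 >> 4)
    out[:, :, 2] = (b5 << 3) | (b5 >> 2)
    return Frame(pixels=out, capture_time=frame.capture_time, index=frame.index)


def stream_map(stream: FrameStream, fn) -> FrameStream:
    """Apply a per-frame transform, preserving stream metadata."""
    return FrameStream(
        frames=[fn(f) for f in stream],
        nominal_fps=stream.nominal_fps,
        source=stream.source,
    )
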