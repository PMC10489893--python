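"""Synthetic camera scenes with known ground truth.

The generator emulates the low-resolution rolling-shutter camera module the
gate hardware uses: a 240x160 (HQVGA-class) RGB stream at ~25 fps with
per-pixel Gaussian sensor noise calibrated so a static scene's frame-to-frame
MSE lands in the 20-30 band measured on the real sensor.  On top of the
static background it can composite

* a high-contrast rectangular silhouette translating at constant speed (the
  athlete crossing the measurement line, with a continuous-time ground-truth
  crossing instant),
* global lighting steps (lights switched on/off, sun appearing), and
* a periodic local flicker patch (foliage moving in the background),

the latter two being the documented false-positive modes of a camera-based
gate.  Every generator is bit-exact reproducible from (spec, seed).

Noise calibration
-----------------
For i.i.d. per-channel Gaussian noise of standard deviation sd added to two
independent frames, each channel difference has variance 2 sd^2, so the
expected three-channel MSE between consecutive frames is 6 sd^2.  Hitting a
target MSE therefore needs sd = sqrt(target / 6); the measured band 20-30
corresponds to sd between 1.83 and 2.24 gray levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GroundTruthError, InputError
from .frames import Frame, FrameStream, synthesize_timestamps

__all__ = [
    "Silhouette",
    "Flicker",
    "SceneSpec",
    "GroundTruth",
    "calibrate_noise_sd",
    "make_static_scene",
    "make_crossing_scene",
    "add_lighting_step",
]


@dataclass(frozen=True)
class Silhouette:
    """A solid moving rectangle standing in for the athlete's torso.

    The leading edge is the right edge for rightward motion.  Default size
    and speed correspond to a sprinting adult seen side-on by a gate camera
    at a few metres (~120 px/m): a 40 px wide, 120 px tall torso at 800 px/s
    (~6.7 m/s).
    """

    width_px: int = 40
    height_px: int = 120
    color: tuple[int, int, int] = (230, 40, 40)
    speed_px_per_s: float = 800.0
    row_offset: int = 20
    start_col: float = 0.0  # leading-edge column at t=0
    shape: str = "rectangle"  # or "ellipse"


@dataclass(frozen=True)
class Flicker:
    """Periodic square-wave brightness modulation of a background patch."""

    col_start: int = 0
    col_end: int = 20
    row_start: int = 0
    row_end: int = 20
    amplitude: int = 15
    period_s: float = 0.4


@dataclass
class SceneSpec:
    """Recipe for one synthetic gate-camera stream."""

    width: int = 240
    height: int = 160
    fps: float = 25.0
    duration_s: float = 4.0
    background: tuple[int, int, int] = (110, 110, 110)
    noise_sd: float = 2.0
    silhouette: Silhouette | None = None
    crossing_col: int | None = None  # ground-truth column; default: frame centre
    lighting_steps: tuple[tuple[float, tuple[int, int, int]], ...] = ()
    flicker: Flicker | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise InputError("fps and duration must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        if self.width < 1 or self.height < 1:
            raise InputError("frame dimensions must be positive")
        if self.silhouette is not None:
            s = self.silhouette
            if s.height_px + s.row_offset > self.height or s.width_px > self.width:
                raise InputError("silhouette does not fit in the frame")

    @property
    def n_frames(self) -> int:
        return max(2, int(round(self.duration_s * self.fps)))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        doc = json.loads(text)
        if doc.get("silhouette") is not None:
            sil = dict(doc["silhouette"])
            if "color" in sil:
                sil["color"] = tuple(sil["color"])
            doc["silhouette"] = Silhouette(**sil)
        if doc.get("flicker") is not None:
            doc["flicker"] = Flicker(**doc["flicker"])
        doc["background"] = tuple(doc["background"])
        doc["lighting_steps"] = tuple(
            (float(t), tuple(d)) for t, d in doc.get("lighting_steps", ())
        )
        return cls(**doc)


@dataclass(frozen=True)
class GroundTruth:
    """Continuous-time crossing instant the detector is judged against.

    ``crossing_time_ms`` is the moment the silhouette's leading edge reaches
    the ground-truth column — real-valued, not snapped to the frame grid;
    only the detector's report is quantised.
    """

    crossing_time_ms: float
    crossing_col: int
    spec: SceneSpec

    def to_json(self) -> str:
        return json.dumps(
            {
                "crossing_time_ms": self.crossing_time_ms,
                "crossing_col": self.crossing_col,
                "scene": json.loads(self.spec.to_json()),
            },
            indent=2,
        )


def calibrate_noise_sd(target_mse: float) -> float:
    """Per-channel noise sd that yields an expected static-scene MSE of *target_mse*.

    Closed form sd = sqrt(target / 6): each of the three channel differences
    between two independently-noised frames has variance 2 sd^2.
    """
    if target_mse <= 0:
        raise InputError("target MSE must be positive")
    return float(np.sqrt(target_mse / 6.0))


def _add_noise(clean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return clean.astype(np.uint8)
    noisy = clean + rng.normal(0.0, sd, size=clean.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _apply_flicker(clean: np.ndarray, flicker: Flicker, t_s: float) -> np.ndarray:
    phase = (t_s / flicker.period_s) % 1.0
    if phase < 0.5:
        return clean
    out = clean.copy()
    patch = out[flicker.row_start : flicker.row_end, flicker.col_start : flicker.col_end]
    out[flicker.row_start : flicker.row_end, flicker.col_start : flicker.col_end] = np.clip(
        patch + flicker.amplitude, 0, 255
    )
    return out


def make_static_scene(spec: SceneSpec) -> FrameStream:
    """Flat background plus fresh i.i.d. sensor noise per frame.

    The silhouette must be disabled; lighting steps and flicker, if present,
    are applied (they are part of the static-scene failure modes).
    """
    if spec.silhouette is not None:
        raise InputError("static scene must not contain a silhouette")
    return _render(spec, silhouette=None)[0]


def make_crossing_scene(spec: SceneSpec) -> tuple[FrameStream, GroundTruth]:
    """A silhouette translating across the frame, with its true crossing time.

    The ground truth is the continuous instant the leading edge reaches
    ``spec.crossing_col`` (default: the horizontal centre of the frame,
    where the default detection band sits).
    """
    if spec.silhouette is None:
        raise InputError("crossing scene requires a silhouette")
    if spec.silhouette.speed_px_per_s <= 0:
        raise InputError("silhouette speed must be positive")
    stream, gt = _render(spec, silhouette=spec.silhouette)
    assert gt is not None
    return stream, gt


def _render(
    spec: SceneSpec, silhouette: Silhouette | None
) -> tuple[FrameStream, GroundTruth | None]:
    rng = np.random.default_rng(spec.seed)
    bg = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    bg[:] = np.asarray(spec.background, dtype=np.float64)

    gt: GroundTruth | None = None
    if silhouette is not None:
        crossing_col = (
            spec.crossing_col if spec.crossing_col is not None else spec.width // 2
        )
        crossing_time_ms = (
            (crossing_col - silhouette.start_col) / silhouette.speed_px_per_s * 1000.0
        )
        if not (0.0 <= crossing_time_ms <= spec.duration_s * 1000.0):
            raise GroundTruthError(
                f"silhouette never reaches column {crossing_col} within "
                f"{spec.duration_s} s (would cross at {crossing_time_ms:.1f} ms)"
            )
        gt = GroundTruth(
            crossing_time_ms=crossing_time_ms, crossing_col=crossing_col, spec=spec
        )

    steps = sorted(spec.lighting_steps, key=lambda s: s[0])
    times = synthesize_timestamps(spec.n_frames, spec.fps)
    frames: list[Frame] = []
    for i, t_ms in enumerate(times):
        t_s = i / spec.fps
        clean = bg.copy()
        if silhouette is not None:
            lead = silhouette.start_col + silhouette.speed_px_per_s * t_s
            c1 = int(np.floor(lead))
            c0 = c1 - silhouette.width_px
            c0v, c1v = max(0, c0), min(spec.width, c1)
            if c1v > c0v:
                r0 = silhouette.row_offset
                r1 = r0 + silhouette.height_px
                color = np.asarray(silhouette.color, dtype=np.float64)
                if silhouette.shape == "ellipse":
                    rows = np.arange(r0, r1)[:, None]
                    cols = np.arange(c0v, c1v)[None, :]
                    cy, cx = (r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0
                    ry, rx = silhouette.height_px / 2.0, silhouette.width_px / 2.0
                    mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
                    clean[r0:r1, c0v:c1v][mask] = color
                else:
                    clean[r0:r1, c0v:c1v] = color
        # lighting steps accumulate from the first frame at/after each step time
        for step_t, delta in steps:
            if t_s >= step_t:
                clean = np.clip(clean + np.asarray(delta, dtype=np.float64), 0, 255)
        if spec.flicker is not None:
            clean = _apply_flicker(clean, spec.flicker, t_s)
        frames.append(
            Frame(pixels=_add_noise(clean, spec.noise_sd, rng), capture_time=t_ms, index=i)
        )
    return FrameStream(frames=frames, nominal_fps=spec.fps, source="synthetic"), gt


def add_lighting_step(
    stream: FrameStream, time_s: float, delta: Sequence[int]
) -> FrameStream:
    """Shift all pixels by *delta* from the first frame at/after *time_s* on.

    Models lights being switched on/off; values are clamped to [0, 255].
    Returns a new stream; the input is untouched.
    """
    t_ms = time_s * 1000.0
    if not stream.frames or t_ms > stream.frames[-1].capture_time:
        raise InputError("lighting step time lies outside the stream span")
    d = np.asarray(delta, dtype=np.float64)
    out = []
    for f in stream:
        if f.capture_time >= t_ms:
            px = np.clip(f.pixels.astype(np.float64) + d, 0, 255).astype(np.uint8)
            out.append(Frame(pixels=px, capture_time=f.capture_time, index=f.index))
        else:
            out.append(f)
    return FrameStream(frames=out, nominal_fps=stream.nominal_fps, source=stream.source)
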