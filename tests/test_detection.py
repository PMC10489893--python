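"""MSE change metric, noise floor, decision function and trigger extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtualgate import (
    BarrierConfig,
    ConfigurationError,
    InputError,
    Region,
    decide,
    default_region,
    detect_triggers,
    estimate_noise,
    load_barrier_config,
    mse_diff,
    mse_diff_rgb565_native,
    save_barrier_config,
)
from virtualgate.detection import read_trigger_csv, write_trigger_csv

from conftest import random_frame, rgb_frame, stream_from_frames, uniform_frame


def brute_force_mse(frame_a, frame_b, region, gray=False):
    """Independent per-pixel double-loop oracle for the change metric."""
    from virtualgate import to_grayscale

    if gray:
        frame_a, frame_b = to_grayscale(frame_a), to_grayscale(frame_b)
    total = 0.0
    n = 0
    for row in range(region.row_start, region.row_end):
        for col in range(region.col_start, region.col_end):
            pa = frame_a.pixels[row, col]
            pb = frame_b.pixels[row, col]
            if gray:
                total += (float(pa) - float(pb)) ** 2
            else:
                for c in range(3):
                    total += (float(pa[c]) - float(pb[c])) ** 2
            n += 1
    return total / n


class TestMseDiff:
    def test_identical_frames_zero(self, rng):
        f = random_frame(rng, 8, 8)
        r = Region(1, 5, 2, 7)
        assert mse_diff(f, f, r) == 0.0

    def test_one_pixel_hand_value(self):
        a = rgb_frame([[(0, 0, 0)]])
        b = rgb_frame([[(3, 4, 0)]], t=40, index=1)
        assert mse_diff(a, b, Region(0, 1, 0, 1)) == 25.0

    def test_two_pixel_hand_value(self):
        a = rgb_frame([[(10, 10, 10), (20, 20, 20)]])
        b = rgb_frame([[(11, 11, 11), (21, 21, 21)]], t=40, index=1)
        assert mse_diff(a, b, Region(0, 2, 0, 1)) == 3.0

    @pytest.mark.parametrize("gray", [False, True])
    def test_matches_brute_force_oracle(self, rng, gray):
        for _ in range(25):
            h, w = rng.integers(2, 33, size=2)
            a = random_frame(rng, h, w)
            b = random_frame(rng, h, w, t=40, index=1)
            c0, c1 = sorted(rng.choice(w + 1, size=2, replace=False))
            r0, r1 = sorted(rng.choice(h + 1, size=2, replace=False))
            region = Region(int(c0), int(c1), int(r0), int(r1))
            mode = "grayscale" if gray else "rgb"
            expected = brute_force_mse(a, b, region, gray=gray)
            assert mse_diff(a, b, region, mode) == pytest.approx(expected, rel=1e-9)

    def test_symmetric(self, rng):
        a, b = random_frame(rng, 6, 6), random_frame(rng, 6, 6, t=40, index=1)
        r = Region(0, 6, 0, 6)
        assert mse_diff(a, b, r) == mse_diff(b, a, r)

    def test_region_size_invariance(self, rng):
        # tiling the same content p times leaves the statistic unchanged
        tile_a = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        tile_b = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
        for p in (1, 2, 3):
            a = rgb_frame(np.tile(tile_a, (p, 1, 1)))
            b = rgb_frame(np.tile(tile_b, (p, 1, 1)), t=40, index=1)
            region = Region(0, 4, 0, 4 * p)
            assert mse_diff(a, b, region) == pytest.approx(
                brute_force_mse(rgb_frame(tile_a), rgb_frame(tile_b, t=1, index=1),
                                Region(0, 4, 0, 4)),
                rel=1e-12,
            )

    def test_region_out_of_bounds(self, rng):
        a, b = random_frame(rng, 4, 4), random_frame(rng, 4, 4, t=40, index=1)
        with pytest.raises(ConfigurationError):
            mse_diff(a, b, Region(0, 5, 0, 4))

    def test_dimension_mismatch(self, rng):
        a, b = random_frame(rng, 4, 4), random_frame(rng, 4, 5, t=40, index=1)
        with pytest.raises(InputError):
            mse_diff(a, b, Region(0, 2, 0, 2))

    def test_native_rgb565_smaller_magnitude(self, rng):
        a = uniform_frame(4, 4, (0, 0, 0))
        b = uniform_frame(4, 4, (255, 255, 255), t=40, index=1)
        r = Region(0, 4, 0, 4)
        native = mse_diff_rgb565_native(a, b, r)
        assert native == pytest.approx(31**2 + 63**2 + 31**2)
        assert native < mse_diff(a, b, r)


class TestEstimateNoise:
    def test_identical_frames_zero(self, rng):
        f0 = random_frame(rng, 4, 4)
        frames = [rgb_frame(f0.pixels, t=i * 40, index=i) for i in range(5)]
        assert estimate_noise(stream_from_frames(frames), Region(0, 4, 0, 4)) == 0.0

    def test_maximum_of_pair_mses(self):
        # consecutive-pair MSEs of this gray ramp are {4, 25, 9}
        levels = [0, 2, 7, 10]
        frames = [uniform_frame(2, 2, (v, v, v), t=i * 40, index=i)
                  for i, v in enumerate(levels)]
        region = Region(0, 2, 0, 2)
        tau = estimate_noise(stream_from_frames(frames), region, "grayscale")
        assert tau == 25.0

    def test_too_few_frames(self, rng):
        with pytest.raises(InputError):
            estimate_noise(stream_from_frames([random_frame(rng, 2, 2)]),
                           Region(0, 2, 0, 2))


class TestDecide:
    @pytest.mark.parametrize(
        "mse,theta,tau,expected",
        [
            (425.0, 400.0, 25.0, 0),  # boundary is not a trigger (strict >)
            (425.01, 400.0, 25.0, 1),
            (0.0, 400.0, 0.0, 0),
        ],
    )
    def test_strict_threshold(self, mse, theta, tau, expected):
        assert decide(mse, theta, tau) == expected

    def test_negative_mse_rejected(self):
        with pytest.raises(InputError):
            decide(-1.0, 400.0, 0.0)

    @settings(max_examples=300, deadline=None)
    @given(
        mse=st.floats(0, 1e6),
        mse_hi=st.floats(0, 1e6),
        theta=st.floats(1e-3, 1e6),
        theta_hi=st.floats(1e-3, 1e6),
        tau=st.floats(0, 1e6),
        tau_hi=st.floats(0, 1e6),
    )
    def test_monotonicity(self, mse, mse_hi, theta, theta_hi, tau, tau_hi):
        """Non-decreasing in the MSE, non-increasing in theta and tau."""
        lo, hi = sorted((mse, mse_hi))
        assert decide(lo, theta, tau) <= decide(hi, theta, tau)
        t_lo, t_hi = sorted((theta, theta_hi))
        assert decide(mse, t_hi, tau) <= decide(mse, t_lo, tau)
        u_lo, u_hi = sorted((tau, tau_hi))
        assert decide(mse, theta, u_hi) <= decide(mse, theta, u_lo)


def edge_sweep_stream(width=20, height=8, n_frames=8, step=3, contrast=200):
    """A full-height vertical edge entering from the left, step px/frame."""
    frames = []
    for i in range(n_frames):
        px = np.zeros((height, width, 3), dtype=np.uint8)
        px[:, : min(width, i * step)] = contrast
        frames.append(rgb_frame(px, t=i * 40, index=i))
    return stream_from_frames(frames)


class TestDetectTriggers:
    def test_static_noise_stream_is_silent(self, rng):
        # calibrated sensor noise stays far below theta=400
        from virtualgate import SceneSpec, make_static_scene

        spec = SceneSpec(width=60, height=40, duration_s=1.0, noise_sd=2.0, seed=9)
        stream = make_static_scene(spec)
        cfg = BarrierConfig(regions=[default_region(40, 60)], theta=400.0)
        assert detect_triggers(stream, cfg) == []

    def test_single_event_at_first_exceeding_pair(self):
        stream = edge_sweep_stream()
        region = Region(9, 12, 0, 8)  # edge reaches col 9 between frames 3 and 4
        cfg = BarrierConfig(regions=[region], theta=400.0, tau_per_region=[0.0])
        events = detect_triggers(stream, cfg, gate_id="g")
        assert len(events) == 1
        # pair (3,4): edge moves from col 9 to col 12, covering the whole band
        assert events[0].frame_index == 4
        assert events[0].device_time_ms == 160  # later-frame convention
        assert events[0].region_mse[0] > 400.0

    def test_timestamp_conventions(self):
        stream = edge_sweep_stream()
        region = Region(9, 12, 0, 8)
        for conv, expected in [("later_frame", 160), ("earlier_frame", 120),
                               ("midpoint", 140)]:
            cfg = BarrierConfig(regions=[region], theta=400.0,
                                timestamp_convention=conv)
            assert detect_triggers(stream, cfg)[0].device_time_ms == expected

    def test_multibarrier_requires_all_regions(self):
        stream = edge_sweep_stream(n_frames=6)
        crossed = Region(3, 6, 0, 8)
        never_crossed = Region(16, 19, 0, 8)
        cfg = BarrierConfig(regions=[crossed, never_crossed], theta=400.0)
        assert detect_triggers(stream, cfg) == []

    def test_multibarrier_subset_property(self, rng):
        """Multi-region triggers are a subset of each region's solo triggers."""
        for trial in range(20):
            frames = [random_frame(rng, 10, 20, t=i * 40, index=i) for i in range(10)]
            stream = stream_from_frames(frames)
            r1, r2 = Region(2, 5, 0, 10), Region(10, 13, 0, 10)
            theta = float(rng.uniform(1000, 15000))
            both = BarrierConfig(regions=[r1, r2], theta=theta, refractory_ms=0)
            fired_both = {e.frame_index for e in detect_triggers(stream, both)}
            for region in (r1, r2):
                solo = BarrierConfig(regions=[region], theta=theta, refractory_ms=0)
                fired_solo = {e.frame_index for e in detect_triggers(stream, solo)}
                assert fired_both <= fired_solo

    def test_refractory_suppresses_followup(self):
        # edge crosses the band, then the trailing edge would fire again
        frames = []
        for i in range(6):
            px = np.zeros((4, 10, 3), dtype=np.uint8)
            if i in (1, 2):  # object inside the band on frames 1-2 only
                px[:, 4:7] = 200
            frames.append(rgb_frame(px, t=i * 40, index=i))
        stream = stream_from_frames(frames)
        cfg_short = BarrierConfig(regions=[Region(4, 7, 0, 4)], theta=400.0,
                                  refractory_ms=0)
        cfg_long = BarrierConfig(regions=[Region(4, 7, 0, 4)], theta=400.0,
                                 refractory_ms=1000)
        assert len(detect_triggers(stream, cfg_short)) == 2  # entry and exit
        assert len(detect_triggers(stream, cfg_long)) == 1

    def test_region_config_mismatch(self, rng):
        frames = [random_frame(rng, 4, 4, t=i * 40, index=i) for i in range(3)]
        cfg = BarrierConfig(regions=[Region(0, 8, 0, 4)], theta=400.0)
        with pytest.raises(ConfigurationError):
            detect_triggers(stream_from_frames(frames), cfg)


class TestConfigSerialization:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(ConfigurationError):
            BarrierConfig(regions=[Region(0, 4, 0, 4), Region(2, 6, 0, 4)])

    def test_tau_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            BarrierConfig(regions=[Region(0, 4, 0, 4)], tau_per_region=[1.0, 2.0])

    def test_json_roundtrip(self, tmp_path):
        cfg = BarrierConfig(
            regions=[Region(10, 16, 0, 60, label="left"),
                     Region(30, 36, 0, 60, label="right")],
            theta=350.0,
            tau_per_region=[21.5, 28.0],
            color_mode="grayscale",
            refractory_ms=800,
            timestamp_convention="midpoint",
        )
        path = tmp_path / "gate.json"
        save_barrier_config(cfg, path, gate_id="start")
        back, gate_id = load_barrier_config(path)
        assert gate_id == "start"
        assert back == cfg

    def test_trigger_csv_roundtrip(self, tmp_path):
        from virtualgate import TriggerEvent

        events = [
            TriggerEvent("g", 160, 4, (512.25, 730.5)),
            TriggerEvent("g", 1200, 30, (9000.0, 401.125)),
        ]
        path = tmp_path / "triggers.csv"
        write_trigger_csv(events, path)
        assert read_trigger_csv(path) == events
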