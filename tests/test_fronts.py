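"""Leading-edge analytics: geometry, smoothing arithmetic, distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agardrift import (
    Calibration,
    FrontTrack,
    HyperStack,
    UncalibratedError,
    average_regions,
    detect_front,
    expansion_rate,
    front_distance,
    track_fronts,
)
from agardrift.synth import generate, two_colony_config


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestDetect:
    def test_blank_plane_is_absent(self):
        assert np.isnan(detect_front(np.zeros((32, 32), np.uint8)))

    def test_disc_front_geometry(self):
        plane = np.where(disc_mask((101, 101), 50, 50, 10), 200, 0).astype(np.uint8)
        assert detect_front(plane, axis="x", direction="+", pixel_size=1.0) == 60.0
        assert detect_front(plane, axis="x", direction="-", pixel_size=1.0) == 40.0
        assert detect_front(plane, axis="y", direction="+", pixel_size=1.0) == 60.0
        assert detect_front(plane, axis="x", direction="+", pixel_size=0.5) == 30.0

    def test_small_components_filtered(self):
        plane = np.zeros((40, 40), np.uint8)
        plane[5:15, 5:15] = 200  # real colony, 100 px
        plane[30, 35] = 255  # hot pixel beyond the front
        pos = detect_front(plane, axis="x", direction="+", threshold=100, min_component_px=5)
        assert pos == 14.0

    def test_noisy_disc_close_to_noiseless_oracle(self):
        clean = np.where(disc_mask((64, 64), 32, 30, 12), 180, 10).astype(float)
        oracle = detect_front(clean.astype(np.uint8), axis="x", direction="+")
        rng = np.random.default_rng(0)
        for seed in range(20):
            noisy = np.clip(clean + np.random.default_rng(seed).normal(0, 15, clean.shape), 0, 255)
            pos = detect_front(noisy.astype(np.uint8), axis="x", direction="+", min_component_px=20)
            assert abs(pos - oracle) <= 2.0  # within 2 px of noiseless detection


class TestTrack:
    def test_static_colony_constant_positions(self, cal):
        pix = np.zeros((4, 1, 3, 32, 32), np.uint8)
        pix[:, 0, 1] = np.where(disc_mask((32, 32), 16, 10, 6), 200, 0)
        track = track_fronts(HyperStack.from_array(pix, cal), 0)
        np.testing.assert_allclose(track.positions, track.positions[0])

    def test_growing_synthetic_matches_ground_truth(self):
        stack, truth = generate(two_colony_config())
        track = track_fronts(stack, 0, axis="x", direction="+")
        px = stack.calibration.pixel_size_xy
        np.testing.assert_allclose(track.positions, truth.front_position_um[:, 0], atol=px)

    def test_colony_leaving_field_gives_trailing_absent(self, cal):
        pix = np.zeros((3, 1, 1, 16, 16), np.uint8)
        pix[0, 0, 0, 4:10, 4:10] = 200  # present only at t=0
        track = track_fronts(HyperStack.from_array(pix, cal), 0)
        assert np.isfinite(track.positions[0])
        assert np.isnan(track.positions[1]) and np.isnan(track.positions[2])

    def test_uncalibrated_stack_rejected(self):
        pix = np.zeros((2, 1, 1, 8, 8), np.uint8)
        stack = HyperStack.from_array(pix)  # default uncalibrated
        with pytest.raises(UncalibratedError):
            track_fronts(stack, 0)


class TestRates:
    def _track(self, positions, pixel_size=1.0):
        return FrontTrack(
            channel=0,
            positions=np.asarray(positions, float),
            advance_axis="x",
            direction="+",
            pixel_size=pixel_size,
        )

    def test_constant_speed(self, cal):
        rates = expansion_rate(self._track([0, 5, 10, 15]), cal)
        np.testing.assert_allclose(rates.raw_rates, [10, 10, 10])
        np.testing.assert_allclose(rates.smoothed_rates, [10, 10, 10])

    def test_trailing_window_arithmetic(self):
        cal = Calibration(1.0, 1.0, 60.0)  # 1 h per timepoint: rates equal diffs
        rates = expansion_rate(self._track(np.cumsum([0, 1, 2, 3, 4, 5])), cal)
        np.testing.assert_allclose(rates.raw_rates, [1, 2, 3, 4, 5])
        np.testing.assert_allclose(rates.smoothed_rates, [1, 1.5, 2, 2.5, 3.5])

    def test_gap_propagates_absent(self, cal):
        rates = expansion_rate(self._track([0, 5, np.nan, 15, 20]), cal)
        assert np.isnan(rates.raw_rates[1]) and np.isnan(rates.raw_rates[2])
        assert np.isfinite(rates.raw_rates[0]) and np.isfinite(rates.raw_rates[3])
        assert np.isnan(rates.smoothed_rates[1])

    def test_negative_rates_are_legitimate(self, cal):
        rates = expansion_rate(self._track([20, 17.5, 15]), cal)
        np.testing.assert_allclose(rates.raw_rates, [-5, -5])

    def test_all_absent_rejected(self, cal):
        with pytest.raises(ValueError):
            expansion_rate(self._track([np.nan, np.nan, 3.0]), cal)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=20), st.integers(1, 6))
    def test_smoothing_stays_within_raw_envelope(self, positions, window):
        cal = Calibration(1.0, 1.0, 30.0)
        rates = expansion_rate(self._track(positions), cal, window=window)
        lo, hi = np.min(rates.raw_rates), np.max(rates.raw_rates)
        assert np.all(rates.smoothed_rates >= lo - 1e-9)
        assert np.all(rates.smoothed_rates <= hi + 1e-9)


class TestRegions:
    def test_identical_series_zero_sd(self):
        out = average_regions([np.array([4.0, 5.0])] * 3)
        np.testing.assert_allclose(out["mean"], [4, 5])
        np.testing.assert_allclose(out["sd"], [0, 0])

    def test_sample_sd(self):
        out = average_regions([np.array([8.0]), np.array([10.0]), np.array([12.0])])
        assert out["mean"][0] == 10.0
        assert out["sd"][0] == pytest.approx(2.0)  # n-1 denominator

    def test_single_region_degenerate(self):
        out = average_regions([np.array([1.0, 2.0])])
        np.testing.assert_allclose(out["mean"], [1, 2])
        assert out["sd"].isna().all()

    def test_mismatched_timebases_rejected(self):
        with pytest.raises(ValueError, match="timebase"):
            average_regions([np.zeros(3), np.zeros(4)])


class TestDistance:
    def test_disc_gap_geometry(self):
        a = disc_mask((64, 256), 32, 20, 20)
        b = disc_mask((64, 256), 32, 220, 20)
        assert front_distance(a, b, pixel_size=1.0) == pytest.approx(160.0)

    def test_overlap_gives_zero(self):
        a = disc_mask((32, 32), 16, 14, 8)
        b = disc_mask((32, 32), 16, 18, 8)
        assert front_distance(a, b) == 0.0

    def test_empty_mask_absent(self):
        assert np.isnan(front_distance(np.zeros((8, 8), bool), disc_mask((8, 8), 4, 4, 2)))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000), px=st.floats(0.25, 4.0))
    def test_matches_brute_force_and_symmetric(self, seed, px):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) < 0.08
        b = rng.random((16, 16)) < 0.08
        if not (a.any() and b.any()):
            return
        got = front_distance(a, b, px)
        brute = min(
            np.hypot(ay - by, ax - bx)
            for ay, ax in np.argwhere(a)
            for by, bx in np.argwhere(b)
        ) * px
        assert got == pytest.approx(brute, rel=1e-12)
        assert front_distance(b, a, px) == pytest.approx(got, rel=1e-12)
        assert got >= 0
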