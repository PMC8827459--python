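"""Masks, diameters, region counting, velocity fits, profiles, outcomes."""

import math

import numpy as np
import pytest

from erythemawave import (
    Field,
    FrontTrace,
    GridSpec,
    KineticParams,
    SolverConfig,
    StimulusSpec,
    classify_outcome,
    count_regions,
    diameter_along_row,
    estimate_velocity,
    front_profile,
    inflamed_mask,
    make_initial_field,
    measure_front_velocity_1d,
    simulate,
    steady_states,
    track_front,
)
from erythemawave.front_analysis import NoFrontError


def _trace(times, diameters, areas=None, n_regions=None, valid=None):
    times = np.asarray(times, dtype=float)
    diameters = np.asarray(diameters, dtype=float)
    if areas is None:
        areas = diameters**2
    if n_regions is None:
        n_regions = np.ones_like(times, dtype=int)
    if valid is None:
        valid = np.ones_like(times, dtype=bool)
    return FrontTrace(
        times=times, diameters=diameters, areas=np.asarray(areas),
        n_regions=np.asarray(n_regions), valid=np.asarray(valid),
    )


class TestMaskAndDiameter:
    def test_uniform_fields(self, strong_ss):
        g = GridSpec(nx=10, ny=10)
        low = Field(q=np.full((10, 10), strong_ss.S_NI), grid=g)
        high = Field(q=np.full((10, 10), strong_ss.S_I), grid=g)
        assert not inflamed_mask(low, strong_ss.S_T).any()
        assert inflamed_mask(high, strong_ss.S_T).all()

    def test_empty_row_gives_zero(self):
        mask = np.zeros((5, 12), dtype=bool)
        d = diameter_along_row(mask, row=2, dx=0.5)
        assert d.value == 0.0 and d.valid

    def test_contiguous_run_length(self):
        mask = np.zeros((3, 20), dtype=bool)
        mask[1, 4:15] = True
        d = diameter_along_row(mask, row=1, dx=1.0)
        assert d.value == 11.0 and d.valid and d.n_runs == 1

    def test_two_runs_invalid(self):
        mask = np.zeros((3, 20), dtype=bool)
        mask[1, 2:5] = True
        mask[1, 10:14] = True
        d = diameter_along_row(mask, row=1, dx=1.0)
        assert not d.valid and math.isnan(d.value) and d.n_runs == 2

    def test_wrap_contact_invalid(self):
        mask = np.zeros((3, 20), dtype=bool)
        mask[1, :4] = True
        mask[1, -3:] = True
        d = diameter_along_row(mask, row=1, dx=1.0)
        assert not d.valid


class TestCountRegions:
    def test_empty_mask(self):
        assert count_regions(np.zeros((8, 8), dtype=bool)) == 0

    def test_three_spots(self):
        mask = np.zeros((20, 20), dtype=bool)
        for cx in (3, 9, 16):
            mask[9:12, cx : cx + 2] = True
        assert count_regions(mask) == 3

    def test_periodic_wrap_merges_across_seam(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, :2] = True
        mask[4:6, -2:] = True  # same blob across the x seam
        assert count_regions(mask) == 1
        mask2 = np.zeros((10, 10), dtype=bool)
        mask2[:2, 4:6] = True
        mask2[-2:, 4:6] = True  # across the y seam
        assert count_regions(mask2) == 1

    def test_diagonal_not_connected(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = True  # 4-connectivity: diagonals separate
        assert count_regions(mask) == 2

    def test_fusion_of_expanding_spots(self, strong_feedback, strong_ss):
        # three separate inflamed areas expand and fuse into one
        g = GridSpec(nx=80, ny=80)
        centers = ((20.0, 40.0), (40.0, 40.0), (60.0, 40.0))
        f0 = make_initial_field(
            g, strong_ss, StimulusSpec(centers=centers, amplitude=1.0, sigma=3.0)
        )
        res = simulate(f0, strong_feedback, SolverConfig(dt=0.05, t_end=16.0, snapshot_interval=1.0))
        tr = track_front(res, threshold=strong_ss.S_T, row=40)
        assert tr.n_regions[0] == 3
        assert tr.n_regions[-1] == 1
        assert np.all(np.diff(tr.n_regions) <= 0)  # fusion only, no splitting


class TestEstimateVelocity:
    def test_synthetic_linear_trace(self):
        t = np.linspace(0, 10, 21)
        tr = _trace(t, 2 * (0.5 + 0.2 * t))  # radius 0.5 + 0.2 t
        est = estimate_velocity(tr)
        assert est.v == pytest.approx(0.2, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0)

    def test_window_selection(self):
        t = np.linspace(0, 10, 21)
        tr = _trace(t, 2 * (0.5 + 0.2 * t))
        est = estimate_velocity(tr, window=(2.0, 8.0))
        assert est.window[0] >= 2.0 and est.window[1] <= 8.0
        assert est.v == pytest.approx(0.2, rel=1e-12)

    def test_invalid_points_excluded(self):
        t = np.linspace(0, 10, 21)
        d = 2 * (0.5 + 0.2 * t)
        valid = np.ones(21, dtype=bool)
        d[5] = 1e6  # corrupted measurement flagged invalid
        valid[5] = False
        est = estimate_velocity(_trace(t, d, valid=valid))
        assert est.v == pytest.approx(0.2, rel=1e-12)

    def test_too_few_points_raises(self):
        tr = _trace([0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="5 valid"):
            estimate_velocity(tr)

    def test_constant_radius_zero_velocity(self):
        tr = _trace(np.linspace(0, 10, 11), np.full(11, 6.0))
        est = estimate_velocity(tr)
        assert est.v == 0.0
        assert est.r_squared == 1.0

    def test_full_model_shrinkage_measured_negative(self, weak_feedback):
        run = measure_front_velocity_1d(weak_feedback)
        assert run.estimate.v < 0
        assert run.v_theory < 0


class TestFrontProfile:
    def _field_from_row(self, row):
        row = np.asarray(row, dtype=float)
        g = GridSpec(nx=len(row), ny=1)
        return Field(q=row, grid=g)

    def test_linear_ramp_width(self, strong_ss):
        # ramp from S_NI to S_I over 10 cells: 10%-90% crossings span 8 cells
        ni, si = strong_ss.S_NI, strong_ss.S_I
        row = np.concatenate([
            np.full(5, si), np.linspace(si, ni, 11), np.full(5, ni)
        ])
        prof = front_profile(self._field_from_row(row), 0, strong_ss)
        assert prof.interface_width == pytest.approx(8.0, abs=0.01)
        assert prof.gradient == pytest.approx(0.8 * (si - ni) / 8.0, rel=0.01)

    def test_step_profile_resolution_limited(self, strong_ss):
        ni, si = strong_ss.S_NI, strong_ss.S_I
        row = np.concatenate([np.full(8, si), np.full(8, ni)])
        prof = front_profile(self._field_from_row(row), 0, strong_ss)
        assert prof.interface_width <= 1.0  # one cell spacing

    def test_no_front_raises(self, strong_ss):
        row = np.full(16, strong_ss.S_NI)
        with pytest.raises(NoFrontError):
            front_profile(self._field_from_row(row), 0, strong_ss)

    def test_propagating_front_keeps_its_shape(self, moderate_feedback):
        # steadily traveling fronts: width constant and profile shape invariant
        ss = steady_states(moderate_feedback)
        g = GridSpec(nx=240, ny=1, dx=0.5)
        x = np.arange(240) * 0.5
        q0 = np.where(np.abs(x - 60) <= 8, ss.S_I, ss.S_NI)
        res = simulate(
            Field(q=q0, grid=g), moderate_feedback,
            SolverConfig(dt=0.05, t_end=60.0, snapshot_interval=30.0),
        )
        f1, f2 = res.field_at(1), res.field_at(2)
        p1 = front_profile(f1, 0, ss)
        p2 = front_profile(f2, 0, ss)
        assert p2.interface_width == pytest.approx(p1.interface_width, rel=0.05)
        # align on the mid-level crossing and compare shapes
        span = ss.S_I - ss.S_NI
        mid = ss.S_NI + 0.5 * span

        def aligned(q_row):
            above = q_row > mid
            i = np.where(above[:-1] & ~above[1:])[0][-1]
            frac = (q_row[i] - mid) / (q_row[i] - q_row[i + 1])
            x0 = (i + frac) * 0.5
            return x - x0

        xi1, xi2 = aligned(f1.q[0]), aligned(f2.q[0])
        window = np.linspace(-6, 6, 61)
        q1i = np.interp(window, xi1, f1.q[0])
        q2i = np.interp(window, xi2, f2.q[0])
        assert np.max(np.abs(q1i - q2i)) < 0.02 * span


class TestClassifyOutcome:
    def test_expanding_trace(self):
        t = np.linspace(0, 20, 21)
        assert classify_outcome(_trace(t, 4 + 0.8 * t)) == "expansion"

    def test_shrinking_trace(self):
        t = np.linspace(0, 20, 21)
        assert classify_outcome(_trace(t, np.maximum(20 - 0.8 * t, 1.0))) == "shrinkage"

    def test_stationary_trace(self):
        t = np.linspace(0, 20, 21)
        assert classify_outcome(_trace(t, np.full(21, 7.0))) == "stationary"

    def test_extinct_trace(self):
        t = np.linspace(0, 20, 21)
        d = np.maximum(10 - t, 0.0)
        areas = d**2
        assert classify_outcome(_trace(t, d, areas=areas)) == "extinct"


class TestRadialSymmetry:
    def test_expanding_disc_stays_round(self, strong_feedback, strong_ss):
        # grid anisotropy must not distort the circular front appreciably
        g = GridSpec(nx=80, ny=80)
        f0 = make_initial_field(
            g, strong_ss, StimulusSpec(centers=((40.0, 40.0),), amplitude=1.0, sigma=3.0)
        )
        res = simulate(f0, strong_feedback, SolverConfig(dt=0.05, t_end=25.0, snapshot_interval=5.0))
        for q in res.snapshots[1:]:
            mask = q > strong_ss.S_T
            xs = np.where(mask.any(axis=0))[0]
            ys = np.where(mask.any(axis=1))[0]
            wx = xs.max() - xs.min() + 1
            wy = ys.max() - ys.min() + 1
            assert abs(wx - wy) / max(wx, wy) < 0.05
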