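"""Trajectory-integration and statistics tests against closed forms and
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jamscope.dynamics import (
    TrajectorySet,
    compute_msd,
    compute_overlap,
    compute_vrms,
    default_overlap_cutoff,
    integrate_trajectories,
    trajectory_set_from_positions,
)
from jamscope.piv import VelocityField


def make_field(u, v, t=0.0, pixel_size=1.0, grid_x=None, grid_y=None, valid=None):
    u = np.asarray(u, dtype=float)
    ny, nx = u.shape
    return VelocityField(
        grid_x=np.arange(nx, dtype=float) * 10.0 if grid_x is None else grid_x,
        grid_y=np.arange(ny, dtype=float) * 10.0 if grid_y is None else grid_y,
        u=u,
        v=np.asarray(v, dtype=float),
        valid=np.ones_like(u, dtype=bool) if valid is None else valid,
        t=t,
        pixel_size=pixel_size,
        units="um/min",
    )


def uniform_fields(ux, vy, n=5, shape=(8, 8), interval=5.0):
    return [
        make_field(np.full(shape, ux), np.full(shape, vy), t=k * interval)
        for k in range(n)
    ]


class TestIntegrateTrajectories:
    def test_zero_fields_leave_tracers_in_place(self):
        traj = integrate_trajectories(uniform_fields(0.0, 0.0))
        assert np.array_equal(traj.r[-1], traj.r[0])
        assert traj.active.all()

    def test_constant_field_displaces_exactly(self):
        # u = 1 um/min for 10 intervals of 5 min -> exactly (50, 0) um for
        # every tracer that stays inside the gridded region
        traj = integrate_trajectories(uniform_fields(1.0, 0.0, n=10))
        disp = traj.r[-1] - traj.r[0]
        active = traj.active[-1]
        assert active.any()
        np.testing.assert_allclose(disp[active, 0], 50.0, atol=1e-12)
        np.testing.assert_allclose(disp[active, 1], 0.0, atol=1e-12)
        # tracers that left the field are frozen and flagged
        frozen = ~active
        assert frozen.any()
        assert np.all(np.isfinite(traj.r[-1][frozen]))

    def test_rotation_euler_error_halves_with_step(self):
        # rigid rotation: explicit Euler grows the radius by O(dt) per
        # step, so halving the field spacing halves the radius drift
        def rotation_fields(n, interval, omega=0.05, centre=100.0):
            gx = np.arange(21, dtype=float) * 10.0
            gy = np.arange(21, dtype=float) * 10.0
            mx, my = np.meshgrid(gx, gy)
            u = -omega * (my - centre)
            v = omega * (mx - centre)
            return [
                make_field(u, v, t=k * interval, grid_x=gx, grid_y=gy)
                for k in range(n)
            ]

        def radius_drift(interval, n):
            traj = integrate_trajectories(rotation_fields(n, interval))
            # tracer seeded nearest to (130, 100): radius 30
            d0 = np.linalg.norm(traj.r[0] - [100.0, 100.0], axis=1)
            idx = int(np.argmin(np.abs(d0 - 30.0)))
            r_end = np.linalg.norm(traj.r[-1, idx] - [100.0, 100.0])
            return r_end - d0[idx]

        coarse = radius_drift(2.0, 20)
        fine = radius_drift(1.0, 40)  # same total time, half the step
        assert coarse > 0 and fine > 0
        assert coarse / fine == pytest.approx(2.0, rel=0.15)

    def test_inconsistent_grids_rejected(self):
        a = make_field(np.zeros((4, 4)), np.zeros((4, 4)))
        b = make_field(
            np.zeros((4, 4)), np.zeros((4, 4)), grid_x=np.arange(4.0) * 7.0
        )
        with pytest.raises(ValueError, match="geometry"):
            integrate_trajectories([a, b])

    def test_empty_field_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            integrate_trajectories([])


class TestMSD:
    def test_static_tracks_give_zero(self):
        traj = integrate_trajectories(uniform_fields(0.0, 0.0))
        lags, msd = compute_msd(traj)
        assert np.all(msd == 0.0)
        assert msd[0] == 0.0

    @pytest.mark.parametrize("policy", ["sliding", "zero"])
    def test_uniform_drift_is_exactly_ballistic(self, policy):
        r = np.zeros((11, 20, 2))
        r[:, :, 0] = 0.7 * np.arange(11)[:, None] * 5.0  # v = 0.7 um/min
        ts = trajectory_set_from_positions(r, frame_interval=5.0)
        lags, msd = compute_msd(ts, origin_policy=policy)
        np.testing.assert_allclose(msd, (0.7 * lags) ** 2, rtol=1e-12)

    def test_random_walk_msd_matches_diffusive_law(self):
        rng = np.random.default_rng(42)
        sigma, n, t = 2.0, 10_000, 48
        steps = rng.normal(0.0, sigma, size=(t - 1, n, 2))
        r = np.concatenate([np.zeros((1, n, 2)), np.cumsum(steps, axis=0)])
        ts = trajectory_set_from_positions(r, frame_interval=1.0)
        lags, msd = compute_msd(ts)
        k = np.arange(1, 13)
        np.testing.assert_allclose(msd[1:13], 2 * sigma**2 * k, rtol=0.05)
        slope = np.polyfit(np.log(lags[1:13]), np.log(msd[1:13]), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_drift_loglog_slope_is_two(self):
        r = np.zeros((11, 5, 2))
        r[:, :, 1] = 0.3 * np.arange(11)[:, None]
        ts = trajectory_set_from_positions(r, frame_interval=1.0)
        lags, msd = compute_msd(ts)
        slope = np.polyfit(np.log(lags[1:]), np.log(msd[1:]), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_all_tracks_frozen_at_start_raises(self):
        r = np.zeros((3, 4, 2))
        ts = TrajectorySet(
            r=r,
            times=np.arange(3.0),
            active=np.zeros((3, 4), dtype=bool),
            seed_spacing=1.0,
        )
        with pytest.raises(ValueError, match="active"):
            compute_msd(ts)


class TestOverlap:
    def test_static_tracks_full_overlap(self):
        traj = integrate_trajectories(uniform_fields(0.0, 0.0))
        _, q = compute_overlap(traj, d_c=5.0)
        assert np.all(q == 1.0)

    def test_drift_beyond_cutoff_loses_all_overlap(self):
        # v dt_min = 5 um per frame, d_c = 2 um -> Q = 0 at every lag > 0
        r = np.zeros((6, 10, 2))
        r[:, :, 0] = 5.0 * np.arange(6)[:, None]
        ts = trajectory_set_from_positions(r, frame_interval=1.0)
        _, q = compute_overlap(ts, d_c=2.0)
        assert q[0] == 1.0
        assert np.all(q[1:] == 0.0)

    def test_cutoff_between_one_and_two_frames_of_drift(self):
        # d_c = 1.5 * (one-frame displacement): Q = 1 at lag 1, 0 beyond
        r = np.zeros((6, 10, 2))
        r[:, :, 0] = 4.0 * np.arange(6)[:, None]
        ts = trajectory_set_from_positions(r, frame_interval=1.0)
        _, q = compute_overlap(ts, d_c=6.0)
        assert q[1] == 1.0
        assert np.all(q[2:] == 0.0)

    def test_overlap_non_increasing_under_drift(self):
        r = np.zeros((20, 8, 2))
        r[:, :, 0] = 1.3 * np.arange(20)[:, None]
        ts = trajectory_set_from_positions(r, frame_interval=1.0)
        _, q = compute_overlap(ts, d_c=7.0)
        assert np.all(np.diff(q) <= 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), d_c=st.floats(0.1, 50.0))
    def test_overlap_bounded_with_unit_start(self, seed, d_c):
        rng = np.random.default_rng(seed)
        r = np.cumsum(rng.normal(0, 2.0, size=(8, 30, 2)), axis=0)
        ts = trajectory_set_from_positions(r, frame_interval=1.0)
        _, q = compute_overlap(ts, d_c=d_c)
        assert q[0] == 1.0
        assert np.all((0.0 <= q) & (q <= 1.0))


class TestVrms:
    def test_uniform_speed_three(self):
        fields = [make_field(np.full((6, 6), 3.0), np.zeros((6, 6)))]
        _, vrms = compute_vrms(fields)
        assert vrms[0] == pytest.approx(3.0)

    def test_half_zero_half_magnitude_a(self):
        u = np.zeros((2, 8))
        u[1] = 4.0
        fields = [make_field(u, np.zeros_like(u))]
        _, vrms = compute_vrms(fields)
        assert vrms[0] == pytest.approx(4.0 / np.sqrt(2.0))

    def test_matches_brute_force_loop_exactly(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=(7, 9))
        v = rng.normal(size=(7, 9))
        valid = rng.random((7, 9)) > 0.2
        field = make_field(u, v, valid=valid)
        _, vrms = compute_vrms([field])
        acc, n = 0.0, 0
        for iy in range(7):
            for ix in range(9):
                if valid[iy, ix]:
                    acc += u[iy, ix] ** 2 + v[iy, ix] ** 2
                    n += 1
        # equality up to float summation order
        assert vrms[0] == pytest.approx(np.sqrt(acc / n), rel=1e-12)

    def test_field_without_valid_vectors_warns_nan(self):
        field = make_field(
            np.zeros((3, 3)), np.zeros((3, 3)), valid=np.zeros((3, 3), dtype=bool)
        )
        with pytest.warns(UserWarning, match="no valid"):
            _, vrms = compute_vrms([field])
        assert np.isnan(vrms[0])

    def test_equals_tracer_rms_for_uniform_fields(self):
        # for a spatially uniform field the tracer-population RMS speed
        # equals V_RMS exactly
        fields = uniform_fields(1.2, -0.9, n=4)
        traj = integrate_trajectories(fields)
        _, vrms = compute_vrms(fields)
        step = np.diff(traj.r, axis=0) / 5.0
        speeds = np.linalg.norm(step, axis=-1)
        for k in range(len(fields) - 1):
            ok = traj.active[k + 1]
            assert np.sqrt((speeds[k][ok] ** 2).mean()) == pytest.approx(vrms[k])


def test_default_cutoff_is_one_grid_spacing_in_um():
    f = make_field(np.zeros((4, 4)), np.zeros((4, 4)), pixel_size=0.75488)
    assert default_overlap_cutoff([f]) == pytest.approx(10.0 * 0.75488)
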