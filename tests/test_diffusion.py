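"""MSD, diffusion-coefficient fits, Arrhenius regression, occupancy grids."""

import numpy as np
import pytest

from silksim.diffusion import (arrhenius_fit, default_fit_window, fit_diffusion,
                               msd, occupancy_grid)
from silksim.dynamics import DynamicsConfig, water_trajectory
from silksim.trajectory import Trajectory, UnwrapError

CELL = np.array([40.0, 35.0, 30.0])


def double_loop_msd(u, max_lag, origin_stride):
    """O(frames^2) reference MSD: explicit loops over origins and particles."""
    n_frames, n_particles, _ = u.shape
    out = {ax: [0.0] for ax in "xyz"}
    for lag in range(1, max_lag + 1):
        vals = {ax: [] for ax in "xyz"}
        for t0 in range(0, n_frames - lag, origin_stride):
            for p in range(n_particles):
                d = u[t0 + lag, p] - u[t0, p]
                vals["x"].append(d[0] ** 2)
                vals["y"].append(d[1] ** 2)
                vals["z"].append(d[2] ** 2)
        for ax in "xyz":
            out[ax].append(np.mean(np.array(vals[ax])))
    return {ax: np.array(v) for ax, v in out.items()}


def unwrapped_traj(u, dt=1.0):
    return Trajectory(positions=u, times_ps=np.arange(len(u)) * dt)


class TestMSD:
    def test_matches_double_loop_oracle_bit_for_bit(self, rng):
        u = np.cumsum(rng.normal(size=(50, 5, 3)), axis=0)
        result = msd(unwrapped_traj(u), selection="all", max_lag=25, origin_stride=3)
        oracle = double_loop_msd(u, 25, 3)
        for ax in "xyz":
            assert np.array_equal(result.axis(ax)[1:], oracle[ax][1:])

    def test_stationary_particles(self):
        u = np.ones((30, 4, 3)) * 7.5
        result = msd(unwrapped_traj(u), selection="all")
        assert np.all(result.msd_total == 0.0)

    def test_pure_drift_is_quadratic(self):
        t = np.arange(60.0)
        u = np.zeros((60, 2, 3))
        u[:, :, 0] = 0.1 * t[:, None]
        result = msd(unwrapped_traj(u), selection="all", max_lag=20, origin_stride=1)
        assert np.allclose(result.msd_total, (0.1 * result.lag_ps) ** 2, atol=1e-12)

    def test_axis_sum_identity_everywhere(self, rng):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-6, n_steps=80,
                             axis_fractions=(0.5, 0.3, 0.2), seed=4)
        traj = water_trajectory(cfg, 10, CELL)
        result = msd(traj, max_lag=40, origin_stride=2)
        assert np.array_equal(result.msd_total,
                              result.msd_x + result.msd_y + result.msd_z)
        assert result.msd_total[0] == 0.0

    def test_wrapped_without_images_refused(self):
        traj = Trajectory(positions=np.zeros((10, 3, 3)),
                          times_ps=np.arange(10.0), cell=CELL)
        with pytest.raises(UnwrapError):
            msd(traj, selection="all")

    def test_empty_selection_rejected(self):
        traj = unwrapped_traj(np.zeros((10, 3, 3)))
        with pytest.raises(ValueError):
            msd(traj, selection=np.array([], dtype=int))

    def test_origin_counts(self):
        u = np.zeros((101, 1, 3))
        result = msd(unwrapped_traj(u), selection="all", max_lag=50, origin_stride=10)
        assert result.origins_per_lag[1] == len(range(0, 100, 10))
        assert result.origins_per_lag[50] == len(range(0, 51, 10))


class TestFitDiffusion:
    def test_exact_line_recovers_d(self):
        lag = np.arange(101.0)
        d_true = 1e-6  # cm^2/s -> slope 6 * 1e-6 * 1e4 A^2/ps... in A^2/ps units
        slope = 6.0 * d_true * 1e4
        from silksim.diffusion import MSDResult
        result = MSDResult(lag_ps=lag, msd_total=slope * lag,
                           msd_x=slope / 3 * lag, msd_y=slope / 3 * lag,
                           msd_z=slope / 3 * lag,
                           origins_per_lag=np.ones_like(lag, dtype=int))
        assert fit_diffusion(result) == pytest.approx(d_true, rel=1e-12)
        assert fit_diffusion(result, dim=1, axis="x") == pytest.approx(d_true / 1,
                                                                       rel=1e-12)

    def test_default_window(self):
        from silksim.diffusion import MSDResult
        lag = np.arange(201.0)
        result = MSDResult(lag_ps=lag, msd_total=lag, msd_x=lag / 3, msd_y=lag / 3,
                           msd_z=lag / 3, origins_per_lag=np.ones_like(lag, int))
        lo, hi = default_fit_window(result)
        assert (lo, hi) == (20.0, 100.0)

    def test_axis_slopes_sum_to_total_slope(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1.6e-6, n_steps=200,
                             axis_fractions=(0.6, 0.3, 0.1), seed=7)
        traj = water_trajectory(cfg, 30, CELL)
        result = msd(traj, max_lag=100, origin_stride=5)
        d_total = fit_diffusion(result, dim=3)
        d_axes = [fit_diffusion(result, dim=1, axis=ax) for ax in "xyz"]
        # D_total = (D_x + D_y + D_z) / 3 exactly (OLS linearity)
        assert sum(d_axes) / 3 == pytest.approx(d_total, rel=1e-12)

    def test_degenerate_window(self):
        from silksim.diffusion import MSDResult
        lag = np.arange(5.0)
        result = MSDResult(lag_ps=lag, msd_total=lag, msd_x=lag, msd_y=0 * lag,
                           msd_z=0 * lag, origins_per_lag=np.ones_like(lag, int))
        with pytest.raises(ValueError):
            fit_diffusion(result, fit_window=(3.2, 3.4))


class TestArrheniusFit:
    def test_exact_inversion_machine_precision(self):
        d0, ea = 1.78e-4, 12.07
        temps = np.array([273.0, 285.0, 298.0, 310.0])
        d = d0 * np.exp(-ea * 1000 / (8.314 * temps))
        fit = arrhenius_fit(list(zip(temps, d)))
        assert fit.ea_kj_mol == pytest.approx(ea, rel=1e-12)
        assert fit.d0_cm2_s == pytest.approx(d0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_any_parameters_invert(self, rng):
        for _ in range(10):
            d0 = 10 ** rng.uniform(-8, -2)
            ea = rng.uniform(1.0, 80.0)
            temps = rng.uniform(150, 500, size=5)
            d = d0 * np.exp(-ea * 1000 / (8.314 * temps))
            fit = arrhenius_fit(list(zip(temps, d)))
            assert fit.ea_kj_mol == pytest.approx(ea, rel=1e-9)
            assert fit.d0_cm2_s == pytest.approx(d0, rel=1e-7)

    def test_two_points_exact(self):
        fit = arrhenius_fit([(273.0, 1e-6), (310.0, 3e-6)])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.predict(np.array([273.0, 310.0])), [1e-6, 3e-6])

    def test_invalid_points(self):
        with pytest.raises(ValueError):
            arrhenius_fit([(298.0, 1e-6)])
        with pytest.raises(ValueError):
            arrhenius_fit([(298.0, 1e-6), (298.0, 2e-6)])
        with pytest.raises(ValueError):
            arrhenius_fit([(273.0, -1e-6), (310.0, 1e-6)])


class TestOccupancyGrid:
    def test_stationary_particle_single_voxel(self):
        pos = np.tile(np.array([[5.2, 5.2, 5.2]]), (12, 1, 1))
        traj = Trajectory(positions=pos, times_ps=np.arange(12.0),
                          cell=np.array([10.0, 10.0, 10.0]),
                          images=np.zeros((12, 1, 3), dtype=int))
        counts, _ = occupancy_grid(traj, selection="all", voxel=1.0)
        assert counts.max() == 12
        assert counts.sum() == 12

    def test_total_conservation(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-5, n_steps=30, seed=3)
        traj = water_trajectory(cfg, 9, CELL)
        counts, _ = occupancy_grid(traj, voxel=2.0)
        assert counts.sum() == traj.n_frames * 9

    def test_x_channeling_flattens_x_profile(self):
        """Strong X-diffusion spreads occupancy along x: slab-count variance is
        lower across x than across y."""
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=5e-6,
                             axis_fractions=(0.8, 0.1, 0.1), n_steps=400, seed=11)
        traj = water_trajectory(cfg, 40, CELL)
        counts, _ = occupancy_grid(traj, voxel=2.0)
        var_x = np.var(counts.sum(axis=(1, 2)))
        var_y = np.var(counts.sum(axis=(0, 2)))
        assert var_x < var_y

    def test_voxel_larger_than_cell(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-6, n_steps=5, seed=1)
        traj = water_trajectory(cfg, 2, CELL)
        with pytest.raises(ValueError):
            occupancy_grid(traj, voxel=100.0)
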