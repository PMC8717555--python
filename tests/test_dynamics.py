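"""Synthetic dynamics: Arrhenius law, unwrap ledger, torsion ensembles."""

import numpy as np
import pytest

from silksim.dynamics import (ARRHENIUS_TEMPERATURES_K, CompositionSpec,
                              DynamicsConfig, dihedral_samples,
                              trajectory_from_dihedrals, water_trajectory)
from silksim.model import UnitCellSpec
from silksim.rama import DEFAULT_REGIONS, classify_batch, compute_dihedrals
from silksim.builder import chain_model, build_chain_from_torsions

CELL = np.array([30.0, 25.0, 20.0])


class TestArrheniusLaw:
    def test_zero_activation_energy_gives_d0(self):
        for t in (10.0, 298.0, 473.0):
            cfg = DynamicsConfig(mode="arrhenius", d0_cm2_s=3e-5, ea_kj_mol=0.0,
                                 temperature_k=t)
            assert cfg.diffusion_coefficient() == 3e-5

    def test_log_d_exactly_linear_in_inverse_t(self):
        cfg = [DynamicsConfig(d0_cm2_s=1.78e-4, ea_kj_mol=12.07, temperature_k=t)
               for t in (250, 273, 298, 310, 400)]
        x = np.array([1.0 / c.temperature_k for c in cfg])
        y = np.array([np.log(c.diffusion_coefficient()) for c in cfg])
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        assert np.allclose(y, y[0] + slope * (x - x[0]), atol=1e-12)
        # slope encodes Ea exactly
        assert -slope * 8.314 / 1000 == pytest.approx(12.07, abs=1e-9)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            DynamicsConfig(mode="nvt")
        with pytest.raises(ValueError):
            DynamicsConfig(axis_fractions=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            DynamicsConfig(dt_ps=0.0)
        with pytest.raises(ValueError):
            DynamicsConfig(mode="direct").diffusion_coefficient()
        with pytest.raises(ValueError):
            DynamicsConfig(mode="direct", d_direct_cm2_s=-1e-6).diffusion_coefficient()


class TestWaterTrajectory:
    def test_shapes_times_and_wrapping(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-6, n_steps=40,
                             sampling_stride=4, dt_ps=0.5, seed=3)
        traj = water_trajectory(cfg, 7, CELL)
        assert traj.positions.shape == (11, 7, 3)
        assert np.allclose(np.diff(traj.times_ps), 2.0)
        assert traj.positions.min() >= 0
        assert np.all(traj.positions < CELL)

    def test_unwrapped_matches_increment_ledger(self):
        """Replay the documented generator recipe as an independent ledger oracle."""
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=2e-6, n_steps=100, seed=9)
        traj = water_trajectory(cfg, 5, CELL)
        rng = np.random.default_rng(9)
        x0 = rng.uniform(0, 1, size=(5, 3)) * CELL
        d_axis = 3.0 * np.asarray(cfg.axis_fractions) * 2e-6 * 1e4
        steps = rng.normal(0, 1, size=(100, 5, 3)) * np.sqrt(2 * d_axis * cfg.dt_ps)
        expected = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
        assert np.allclose(traj.unwrapped(), expected, atol=1e-12)
        # and the image counts are exactly the wrap offsets
        assert np.array_equal(traj.positions + traj.images * CELL, traj.unwrapped())

    def test_degenerate_anisotropy_freezes_axes(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-6,
                             axis_fractions=(1.0, 0.0, 0.0), n_steps=50, seed=2)
        traj = water_trajectory(cfg, 4, CELL)
        u = traj.unwrapped()
        assert np.all(u[:, :, 1] == u[0, :, 1])
        assert np.all(u[:, :, 2] == u[0, :, 2])
        assert not np.all(u[:, :, 0] == u[0, :, 0])

    def test_seed_determinism(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-6, n_steps=20, seed=5)
        t1 = water_trajectory(cfg, 3, CELL)
        t2 = water_trajectory(cfg, 3, CELL)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.images, t2.images)

    def test_bad_inputs(self):
        cfg = DynamicsConfig(mode="direct", d_direct_cm2_s=1e-6)
        with pytest.raises(ValueError):
            water_trajectory(cfg, 0, CELL)
        with pytest.raises(ValueError):
            water_trajectory(cfg, 3, (1.0, -1.0, 1.0))


class TestDihedralSamples:
    def test_pure_composition_zero_jitter_hits_center(self):
        spec = CompositionSpec(fractions={"beta_sheet": 1.0}, sigma_deg=0.0,
                               n_residues=10, n_frames=3, seed=1)
        s = dihedral_samples(spec)
        assert np.allclose(s.phi, -60.0) and np.allclose(s.psi, 130.0)
        assert (s.labels == "beta_sheet").all()

    def test_labels_are_ground_truth_for_classifier(self):
        spec = CompositionSpec(sigma_deg=0.0, n_residues=200, n_frames=20, seed=4)
        s = dihedral_samples(spec)
        predicted = classify_batch(s.phi, s.psi, DEFAULT_REGIONS)
        assert (predicted == s.labels).all()

    def test_composition_recovery_small(self):
        spec = CompositionSpec(sigma_deg=10.0, n_residues=512, n_frames=100, seed=3)
        s = dihedral_samples(spec)
        predicted = classify_batch(s.phi, s.psi, DEFAULT_REGIONS)
        frac_310 = (predicted == "3_10_helix").mean()
        frac_beta = (predicted == "beta_sheet").mean()
        assert frac_310 == pytest.approx(0.37, abs=0.02)
        assert frac_beta == pytest.approx(0.26, abs=0.02)

    def test_unbiased_over_seeds(self):
        """Mean recovered fraction over 20 seeds within 0.5 points of the truth."""
        vals = []
        for seed in range(20):
            spec = CompositionSpec(sigma_deg=10.0, n_residues=256, n_frames=40,
                                   seed=seed)
            s = dihedral_samples(spec)
            predicted = classify_batch(s.phi, s.psi, DEFAULT_REGIONS)
            vals.append((predicted == "3_10_helix").mean())
        assert np.mean(vals) == pytest.approx(0.37, abs=0.005)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            CompositionSpec(fractions={"3_10_helix": 0.6, "coil": 0.5})
        with pytest.raises(ValueError):
            dihedral_samples(CompositionSpec(fractions={"no_such_region": 1.0}))
        with pytest.raises(ValueError):
            CompositionSpec(sigma_deg=-1.0)

    def test_seed_determinism(self):
        spec = CompositionSpec(n_residues=16, n_frames=4, seed=6)
        a, b = dihedral_samples(spec), dihedral_samples(spec)
        assert np.array_equal(a.phi, b.phi) and (a.labels == b.labels).all()


class TestTrajectoryFromDihedrals:
    def test_round_trip_interior_residues(self):
        spec = CompositionSpec(n_residues=8, n_frames=4, sigma_deg=15.0, seed=2)
        series = dihedral_samples(spec)
        traj = trajectory_from_dihedrals(series, UnitCellSpec())
        chain = build_chain_from_torsions(series.phi[0], series.psi[0],
                                          list(series.residue_names))
        measured = compute_dihedrals(traj, chain_model(chain))
        assert np.allclose(measured.phi[:, 1:], series.phi[:, 1:], atol=1e-3)
        assert np.allclose(measured.psi[:, :-1], series.psi[:, :-1], atol=1e-3)

    def test_constant_series_gives_identical_frames(self):
        spec = CompositionSpec(fractions={"3_10_helix": 1.0}, sigma_deg=0.0,
                               n_residues=8, n_frames=3, seed=1)
        traj = trajectory_from_dihedrals(dihedral_samples(spec))
        assert np.allclose(traj.positions[0], traj.positions[1])
        assert np.allclose(traj.positions[0], traj.positions[2])

    def test_single_frame(self):
        spec = CompositionSpec(n_residues=8, n_frames=1, seed=3)
        traj = trajectory_from_dihedrals(dihedral_samples(spec))
        assert traj.n_frames == 1
        assert traj.n_atoms == 4 * 17

    def test_residue_count_mismatch(self):
        spec = CompositionSpec(n_residues=6, n_frames=1, seed=3)
        with pytest.raises(ValueError, match="residues"):
            trajectory_from_dihedrals(dihedral_samples(spec), UnitCellSpec())
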