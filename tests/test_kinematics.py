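"""Superposition, RMSD/RMSF, essential-dynamics PCA and domain motion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crysdyn.io_model import Trajectory, select_atoms
from crysdyn.kinematics import (
    domain_rotation,
    kabsch_superpose,
    motion_fraction,
    pca_essential,
    project_frames,
    rmsd_series,
    rmsf_per_residue,
)
from crysdyn.synthetic_data import (
    RotationEvent,
    UnfoldingScript,
    build_toy_two_domain,
    simulate_trajectory,
)

from conftest import point_structure, static_trajectory


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(8, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_removed(self, rng):
        x = rng.normal(size=(8, 3))
        res = kabsch_superpose(x + np.array([1.0, 2.0, 3.0]), x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_known_rotation_recovered(self, rng):
        x = rng.normal(size=(5, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        res = kabsch_superpose(x @ R.T, x)
        np.testing.assert_allclose(res.rotation @ R, np.eye(3), atol=1e-9)
        assert res.rmsd < 1e-9

    def test_rigid_transform_invariance(self, rng):
        """RMSD is unchanged when either input is rigidly moved."""
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(scale=0.3, size=(10, 3))
        base = kabsch_superpose(a, b).rmsd
        R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        moved = kabsch_superpose(a @ R.T + 5.0, b).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line)


class TestRMSD:
    def test_static_trajectory_zero(self, rng):
        s = point_structure(rng.normal(size=(10, 3)))
        traj = static_trajectory(s, 4)
        assert np.allclose(rmsd_series(traj).values, 0.0)

    def test_rigid_rotation_registers_zero(self, rng):
        s = point_structure(rng.normal(size=(10, 3)))
        R = Rotation.from_euler("y", 40, degrees=True).as_matrix()
        coords = np.stack([s.coords(0), s.coords(0) @ R.T])
        traj = Trajectory(s, [0.0, 0.25], coords)
        assert rmsd_series(traj).values[1] == pytest.approx(0.0, abs=1e-10)

    def test_single_displacement_direct_formula(self, rng):
        s = point_structure(rng.normal(size=(10, 3)))
        frame1 = s.coords(0).copy()
        frame1[3, 2] += 2.0
        traj = Trajectory(s, [0.0, 0.25], np.stack([s.coords(0), frame1]))
        unfit = rmsd_series(traj, fit=False)
        assert unfit.values[1] == pytest.approx(2.0 / np.sqrt(10))
        # the fitted value can only be lower
        assert rmsd_series(traj).values[1] <= unfit.values[1] + 1e-12

    def test_empty_selection_rejected(self, rng):
        s = point_structure(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            rmsd_series(static_trajectory(s), selection=np.array([], dtype=int))


class TestRMSF:
    def test_rigid_trajectory_zero(self, toy_two_domain):
        structure, _ = toy_two_domain
        traj = static_trajectory(structure, 5)
        _, vals = rmsf_per_residue(traj)
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_gaussian_noise_calibration(self, toy_two_domain, rng):
        """Isotropic Gaussian jitter of σ gives RMSF → σ√3."""
        structure, _ = toy_two_domain
        base = structure.coords(0)
        sigma = 0.5
        frames = base[None] + rng.normal(0, sigma, size=(400, base.shape[0], 3))
        traj = Trajectory(structure, np.arange(400) * 0.25, frames)
        _, vals = rmsf_per_residue(traj)
        assert vals.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_single_mobile_residue(self, rng):
        """One residue oscillating ±a along x; RMSF follows the script.

        The mobile atom sits at the centroid of a 30-atom rigid shell, so
        the superposition fit absorbs only the ~1/N translation share.
        """
        shell = 5.0 * rng.normal(size=(30, 3))
        shell -= shell.mean(axis=0)
        base = np.vstack([shell, [0.0, 0.0, 0.0]])
        s = point_structure(base)
        a = 0.8
        n = 64
        phases = np.cos(2 * np.pi * np.arange(n) / 8)
        frames = np.repeat(base[None], n, axis=0)
        frames[:, -1, 0] += a * phases
        traj = Trajectory(s, np.arange(n) * 0.1, frames)
        _, vals = rmsf_per_residue(traj, np.arange(31))
        expected = a * np.sqrt(np.mean(phases**2))
        assert vals[-1] == pytest.approx(expected, rel=0.1)
        assert vals[-1] > 5 * vals[0]

    def test_two_frames_required(self, toy_two_domain):
        structure, _ = toy_two_domain
        with pytest.raises(ValueError):
            rmsf_per_residue(static_trajectory(structure, 1))


class TestPCA:
    def test_static_trajectory_zero_eigenvalues(self, toy_two_domain):
        structure, _ = toy_two_domain
        model = pca_essential(static_trajectory(structure, 4))
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-10)

    def test_single_oscillating_atom_spectrum(self, rng):
        shell = 5.0 * rng.normal(size=(30, 3))
        shell -= shell.mean(axis=0)
        base = np.vstack([shell, [0.0, 0.0, 0.0]])
        s = point_structure(base)
        n = 50
        disp = 0.6 * np.sin(np.arange(n))
        frames = np.repeat(base[None], n, axis=0)
        frames[:, -1, 0] += disp
        traj = Trajectory(s, np.arange(n) * 0.1, frames)
        model = pca_essential(traj, np.arange(31))
        v = np.var(disp)
        # the rigid fit absorbs only the ~1/N translation share of the motion
        assert model.eigenvalues[0] == pytest.approx(v, rel=0.15)
        assert model.eigenvalues[1:].sum() < 0.15 * model.eigenvalues[0]

    def test_spectral_identities(self, toy_two_domain, rng):
        structure, regions = toy_two_domain
        script = UnfoldingScript(seed=7, n_frames=30, noise_sigma=0.2)
        traj, _ = simulate_trajectory(structure, script, regions)
        model = pca_essential(traj)
        # eigenvector orthonormality and non-negative spectrum
        V = model.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert model.eigenvalues.min() >= -1e-10
        # projections of the generating frames reproduce the eigenvalues
        proj = project_frames(traj, model, k=2)
        np.testing.assert_allclose(
            proj.var(axis=0, ddof=0), model.eigenvalues[:2], rtol=1e-6
        )
        assert proj[:, 0].var() >= proj[:, 1].var()

    def test_mean_frame_projects_to_origin(self, toy_two_domain):
        structure, _ = toy_two_domain
        traj = static_trajectory(structure, 4)
        model = pca_essential(traj)
        proj = project_frames(traj, model, k=2)
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)

    def test_k_beyond_modes_rejected(self, toy_two_domain):
        structure, _ = toy_two_domain
        traj = static_trajectory(structure, 3)
        model = pca_essential(traj)
        with pytest.raises(ValueError):
            project_frames(traj, model, k=model.eigenvectors.shape[1] + 1)


def _rotated_two_domain(twist_fraction, angle=10.0, n_frames=10):
    structure, regions = build_toy_two_domain(4, 6)
    script = UnfoldingScript(
        seed=0,
        n_frames=n_frames,
        noise_sigma=0.0,
        rotations=[RotationEvent("domain2", "domain1", angle, twist_fraction=twist_fraction)],
    )
    traj, truth = simulate_trajectory(structure, script, regions)
    return structure, regions, traj, truth


class TestDomainRotation:
    def test_perpendicular_axis_is_pure_closure(self):
        structure, regions, traj, _ = _rotated_two_domain(0.0)
        d = domain_rotation(traj.frame(-1), traj.frame(0), traj.topology,
                            "domain1", "domain2", regions)
        assert d.angle_deg == pytest.approx(10.0, abs=0.1)
        assert d.percent_closure == pytest.approx(100.0, abs=1e-6)

    def test_interdomain_axis_is_pure_twist(self):
        structure, regions, traj, _ = _rotated_two_domain(1.0)
        d = domain_rotation(traj.frame(-1), traj.frame(0), traj.topology,
                            "domain1", "domain2", regions)
        assert d.percent_twist == pytest.approx(100.0, abs=1e-6)

    def test_45_degree_axis_splits_evenly(self):
        structure, regions, traj, truth = _rotated_two_domain(0.5)
        d = domain_rotation(traj.frame(-1), traj.frame(0), traj.topology,
                            "domain1", "domain2", regions)
        assert d.percent_twist == pytest.approx(50.0, abs=1e-6)
        assert d.percent_closure + d.percent_twist == pytest.approx(100.0)
        assert truth.rotation[0]["percent_twist"] == pytest.approx(50.0)

    def test_overlapping_domains_rejected(self, toy_two_domain):
        structure, regions = toy_two_domain
        with pytest.raises(ValueError, match="overlap"):
            domain_rotation(structure.coords(0), structure.coords(0), structure,
                            (1, 30), (25, 48))

    def test_closure_twist_sum_on_noisy_frames(self, toy_two_domain, rng):
        structure, regions = toy_two_domain
        script = UnfoldingScript(
            seed=3, n_frames=12, noise_sigma=0.1,
            rotations=[RotationEvent("domain2", "domain1", 15.0, twist_fraction=0.3)],
        )
        traj, _ = simulate_trajectory(structure, script, regions)
        for i in range(traj.n_frames):
            d = domain_rotation(traj.frame(i), traj.frame(0), traj.topology,
                                "domain1", "domain2", regions)
            assert d.percent_closure + d.percent_twist == pytest.approx(100.0)


class TestMotionFraction:
    def test_pure_twist_trajectory(self):
        structure, regions, traj, _ = _rotated_two_domain(1.0, angle=15.0, n_frames=20)
        mf = motion_fraction(traj, "domain1", "domain2", regions=regions)
        assert mf["fraction_twist"] == pytest.approx(100.0)

    def test_alternating_labels_split(self):
        structure, regions = build_toy_two_domain(4, 6)
        base = structure.coords(0)
        mov = [i for i, a in enumerate(structure.atoms) if a.author_residue_number >= 25]
        c_fix = base[[i for i in range(len(base)) if i not in mov]].mean(axis=0)
        c_mov = base[mov].mean(axis=0)
        dvec = (c_mov - c_fix) / np.linalg.norm(c_mov - c_fix)
        perp = np.cross(dvec, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        frames = [base]
        for k in range(1, 11):
            axis = dvec if k % 2 else perp
            R = Rotation.from_rotvec(np.radians(8.0) * axis).as_matrix()
            f = base.copy()
            f[mov] = (f[mov] - c_mov) @ R.T + c_mov
            frames.append(f)
        traj = Trajectory(structure, np.arange(11) * 0.25, np.stack(frames))
        mf = motion_fraction(traj, "domain1", "domain2", regions=regions)
        assert mf["fraction_twist"] == pytest.approx(50.0)
        assert mf["fraction_closure"] == pytest.approx(50.0)

    def test_static_trajectory_undefined_with_warning(self, toy_two_domain):
        structure, regions = toy_two_domain
        traj = static_trajectory(structure, 5)
        with pytest.warns(UserWarning, match="angle floor"):
            mf = motion_fraction(traj, "domain1", "domain2", regions=regions)
        assert np.isnan(mf["fraction_closure"])
        assert mf["n_excluded"] == 5
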