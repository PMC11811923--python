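"""Distances, torsions, superposition, RMSD/RMSF, PCA and helix angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nacdyn import geometry, synthdata
from nacdyn.geometry import (
    GeometryError,
    dihedral,
    dihedral_batch,
    distance,
    helix_axis,
    interhelix_angle,
    kabsch_superpose,
    min_pairwise_distance,
    pca_modes,
    rmsd_series,
    rmsf,
)
from nacdyn.structio import Trajectory

from conftest import random_rotation, random_structure


def oracle_dihedral(p1, p2, p3, p4):
    """Independent route: atan2 of the norm of the cross product of the two
    plane normals (signed by its projection on the central bond) vs their dot."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cross = np.cross(n1, n2)
    sign = np.where(np.sum(cross * b2, axis=-1) >= 0, 1.0, -1.0)
    y = sign * np.linalg.norm(cross, axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


class TestDistance:
    def test_basic(self):
        assert distance((0, 0, 0), (0, 0, 0)) == 0.0
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_matches_closed_form_on_random_pairs(self, rng):
        A = rng.uniform(-50, 50, (10_000, 3))
        B = rng.uniform(-50, 50, (10_000, 3))
        expected = np.sqrt(np.sum((A - B) ** 2, axis=1))
        got = np.array([distance(a, b) for a, b in zip(A[:200], B[:200])])
        np.testing.assert_allclose(got, expected[:200], rtol=1e-12)

    def test_min_pairwise(self, rng):
        A = rng.uniform(-10, 10, (30, 3))
        B = rng.uniform(-10, 10, (40, 3))
        d, (i, j) = min_pairwise_distance(A, B)
        brute = min(
            (np.linalg.norm(a - b), (ia, ib))
            for ia, a in enumerate(A)
            for ib, b in enumerate(B)
        )
        assert d == pytest.approx(brute[0])
        assert (i, j) == brute[1]

    def test_min_pairwise_shared_point_and_empty(self):
        A = np.array([[1.0, 2.0, 3.0], [9, 9, 9]])
        d, pair = min_pairwise_distance(A, A[:1])
        assert d == 0.0 and pair == (0, 0)
        with pytest.raises(ValueError):
            min_pairwise_distance(np.empty((0, 3)), A)


class TestDihedral:
    def test_planar_cis_and_trans(self):
        p1, p2, p3 = np.array([1.0, 1, 0]), np.array([0.0, 0, 0]), np.array([2.0, 0, 0])
        cis = np.array([3.0, 1, 0])
        trans = np.array([3.0, -1, 0])
        assert dihedral(p1, p2, p3, cis) == pytest.approx(0.0, abs=1e-12)
        assert dihedral(p1, p2, p3, trans) == pytest.approx(180.0, abs=1e-12)

    def test_agrees_with_oracle_on_random_quadruples(self, rng):
        P = rng.uniform(-10, 10, size=(100_000, 4, 3))
        got = dihedral_batch(P[:, 0], P[:, 1], P[:, 2], P[:, 3])
        exp = oracle_dihedral(P[:, 0], P[:, 1], P[:, 2], P[:, 3])
        err = np.abs(got - exp)
        err = np.minimum(err, 360 - err)
        assert err.max() <= 1e-9
        assert got.min() > -180.0 and got.max() <= 180.0

    def test_constructed_plus_90_rotation(self):
        # start cis, rotate p4 by +90 deg about the p2->p3 axis (right-handed)
        p1, p2, p3 = np.array([1.0, 1, 0]), np.array([0.0, 0, 0]), np.array([2.0, 0, 0])
        cis = np.array([3.0, 1.0, 0])
        rot = Rotation.from_rotvec(np.radians(90) * np.array([1.0, 0, 0]))
        p4 = p3 + rot.apply(cis - p3)
        assert dihedral(p1, p2, p3, p4) == pytest.approx(90.0, abs=1e-9)

    def test_degenerate_raises(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            dihedral(p, p, (1, 0, 0), (2, 0, 0))
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0))  # collinear

    def test_rigid_invariance(self, rng):
        P = rng.uniform(-10, 10, size=(500, 4, 3))
        base = dihedral_batch(P[:, 0], P[:, 1], P[:, 2], P[:, 3])
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        Q = P @ R.T + t
        moved = dihedral_batch(Q[:, 0], Q[:, 1], Q[:, 2], Q[:, 3])
        err = np.abs(moved - base)
        assert np.minimum(err, 360 - err).max() <= 1e-6


class TestKabsch:
    def test_identity(self, rng):
        X = rng.uniform(-5, 5, (20, 3))
        res = kabsch_superpose(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_constructed_transform(self, rng):
        X = rng.uniform(-5, 5, (25, 3))
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        Y = X @ R.T + t
        res = kabsch_superpose(X, Y)
        assert res.rmsd <= 1e-8
        np.testing.assert_allclose(res.rotation, R, atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)

    def test_optimality_against_random_rotations(self, rng):
        X = rng.uniform(-5, 5, (15, 3))
        Y = X + rng.normal(0, 0.5, X.shape)
        best = kabsch_superpose(X, Y).rmsd
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        rots = Rotation.random(1000, random_state=4).as_matrix()
        trial = np.sqrt(np.mean(np.sum((Xc @ rots.transpose(0, 2, 1) - Yc) ** 2, axis=2), axis=1))
        assert best <= trial.min() + 1e-12

    def test_symmetry(self, rng):
        X = rng.uniform(-5, 5, (12, 3))
        Y = X + rng.normal(0, 0.8, X.shape)
        assert kabsch_superpose(X, Y).rmsd == pytest.approx(kabsch_superpose(Y, X).rmsd, abs=1e-9)

    def test_agrees_with_mdanalysis(self, rng):
        align = pytest.importorskip("MDAnalysis.analysis.align")
        X = rng.uniform(-5, 5, (30, 3))
        Y = X @ random_rotation(rng).T + rng.normal(0, 0.4, X.shape)
        res = kabsch_superpose(X, Y)
        R_md, rmsd_md = align.rotation_matrix(X - X.mean(axis=0), Y - Y.mean(axis=0))
        assert res.rmsd == pytest.approx(rmsd_md, abs=1e-6)
        np.testing.assert_allclose(res.rotation, R_md, atol=1e-6)

    def test_collinear_raises(self):
        X = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(X, X + 1.0)


class TestTrajectoryStats:
    def _jitter_traj(self, rng, n_frames, sigma, n_atoms=20):
        ref = random_structure(rng, n_res=2, chains=("A",))
        ref_coords = ref.coords[:n_atoms]
        from nacdyn.structio import Structure

        top = Structure(atoms=ref.atoms[: len(ref_coords)])
        frames = ref_coords[None] + rng.normal(0, sigma, (n_frames, len(ref_coords), 3))
        return top, Trajectory(topology=top, frames=frames, dt=10.0)

    def test_rmsd_series_static_is_zero(self, rng):
        top, traj = self._jitter_traj(rng, 5, 0.0)
        series = rmsd_series(traj, traj.topology)
        np.testing.assert_allclose(series, 0.0, atol=1e-6)

    def test_rmsd_series_rigid_motion_removed(self, rng):
        top, traj = self._jitter_traj(rng, 20, 0.0)
        frames = np.stack([traj.frames[i] @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
                           for i in range(traj.n_frames)])
        moved = Trajectory(topology=top, frames=frames, dt=10.0)
        np.testing.assert_allclose(rmsd_series(moved, top), 0.0, atol=1e-6)

    def test_rmsd_series_jitter_matches_monte_carlo_oracle(self, rng):
        """Mean best-fit RMSD of jittered frames vs an independent scipy
        align_vectors estimate of the same quantity."""
        sigma = 0.3
        top, traj = self._jitter_traj(rng, 10_000, sigma)
        mean_rmsd = rmsd_series(traj, top).mean()
        ref = top.coords
        refc = ref - ref.mean(axis=0)
        oracle = []
        rng2 = np.random.default_rng(12345)
        for _ in range(3000):
            Y = ref + rng2.normal(0, sigma, ref.shape)
            Yc = Y - Y.mean(axis=0)
            _, rssd = Rotation.align_vectors(Yc, refc)
            oracle.append(rssd / np.sqrt(len(ref)))
        assert mean_rmsd == pytest.approx(np.mean(oracle), rel=0.02)

    def test_rmsf_static_zero_and_single_frame_error(self, rng):
        top, traj = self._jitter_traj(rng, 4, 0.0)
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)
        _, one = self._jitter_traj(rng, 1, 0.0)
        with pytest.raises(ValueError):
            rmsf(one)

    def test_rmsf_isotropic_noise_closed_form(self, rng):
        """Isotropic per-axis jitter sigma gives RMSF = sigma*sqrt(3)."""
        sigma = 0.25
        top, traj = self._jitter_traj(rng, 100_000, sigma, n_atoms=5)
        vals = rmsf(traj)
        np.testing.assert_allclose(vals, sigma * np.sqrt(3), rtol=0.02)

    def test_rmsf_scaling_law(self, rng):
        top1, t1 = self._jitter_traj(rng, 20_000, 0.2, n_atoms=5)
        top2, t2 = self._jitter_traj(rng, 20_000, 0.4, n_atoms=5)
        ratio = rmsf(t2).mean() / rmsf(t1).mean()
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestHelix:
    def test_ideal_helix_axis_along_z(self):
        h = synthdata.make_ideal_helix(15)
        res = helix_axis(h)
        assert not res.ill_defined
        assert np.degrees(np.arccos(np.clip(res.axis @ [0, 0, 1], -1, 1))) < 1.0

    def test_reversed_order_flips_axis(self):
        h = synthdata.make_ideal_helix(15)
        fwd = helix_axis(h.ca_coords)
        rev = helix_axis(h.ca_coords[::-1])
        assert fwd.axis @ rev.axis == pytest.approx(-1.0, abs=1e-6)

    def test_minimal_4_residue_helix(self):
        h = synthdata.make_ideal_helix(4)
        res = helix_axis(h)
        assert np.isfinite(res.axis).all()

    def test_interhelix_parallel_antiparallel(self):
        z = np.array([0.0, 0, 1])
        assert interhelix_angle(z, z) == pytest.approx(0.0)
        assert interhelix_angle(z, -z) == pytest.approx(180.0)

    @pytest.mark.parametrize("theta", range(10, 180, 10))
    def test_interhelix_recovery_sweep(self, theta):
        s = synthdata.make_helix_pair(float(theta))
        ca = s.coords
        n = len(ca) // 2
        a1 = helix_axis(ca[:n])
        a2 = helix_axis(ca[n:])
        assert interhelix_angle(a1, a2) == pytest.approx(theta, abs=1.0)

    def test_interhelix_rotation_invariance(self, rng):
        s = synthdata.make_helix_pair(60.0)
        ca = s.coords
        n = len(ca) // 2
        base = interhelix_angle(helix_axis(ca[:n]), helix_axis(ca[n:]))
        for _ in range(50):
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            moved = ca @ R.T + t
            ang = interhelix_angle(helix_axis(moved[:n]), helix_axis(moved[n:]))
            assert abs(ang - base) <= 1e-6


class TestPCA:
    def test_static_trajectory_zero_eigenvalues(self, rng):
        s = random_structure(rng, n_res=2, chains=("A",))
        traj = Trajectory(topology=s, frames=np.repeat(s.coords[None], 5, axis=0), dt=1.0)
        res = pca_modes(traj, k=2)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_1d_harmonic_motion(self, rng):
        s = random_structure(rng, n_res=2, chains=("A",))
        n_atoms = len(s)
        direction = rng.normal(size=3 * n_atoms)
        direction /= np.linalg.norm(direction)
        amp = np.sin(np.linspace(0, 20 * np.pi, 500))
        frames = (s.coords.ravel()[None] + 2.0 * amp[:, None] * direction[None]).reshape(500, n_atoms, 3)
        frames += rng.normal(0, 0.01, frames.shape)
        traj = Trajectory(topology=s, frames=frames, dt=1.0)
        res = pca_modes(traj, k=2)
        assert abs(res.modes[0] @ direction) > 0.99
        assert res.eigenvalues[0] / res.eigenvalues[1] > 100
        np.testing.assert_allclose(res.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        s = random_structure(rng, n_res=2, chains=("A",))
        frames = s.coords[None] + rng.normal(0, 0.5, (50, len(s), 3))
        traj = Trajectory(topology=s, frames=frames, dt=1.0)
        res = pca_modes(traj, k=3 * len(s) if 3 * len(s) < 50 else 49)
        X = frames.reshape(50, -1)
        total_var = np.sum(np.var(X, axis=0))
        full = pca_modes(traj, k=min(3 * len(s), 50 - 1))
        # all nonzero eigenvalues are captured when k >= rank
        assert np.sum(full.eigenvalues) == pytest.approx(total_var, rel=1e-8)

    def test_k_too_large_raises(self, rng):
        s = random_structure(rng, n_res=1, chains=("A",))
        traj = Trajectory(topology=s, frames=s.coords[None].repeat(3, axis=0), dt=1.0)
        with pytest.raises(ValueError):
            pca_modes(traj, k=3 * len(s) + 1)
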