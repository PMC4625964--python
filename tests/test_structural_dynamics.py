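import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from mmsie.model_io import Trajectory
from mmsie.structural_dynamics import (
    covariance_pca,
    dccm,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
)
from mmsie.synthetic_data import (
    CorrelatedMotionSpec,
    ToyComplexSpec,
    make_toy_complex,
    sample_correlated_trajectory,
)


def random_rigid_motion(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-5, 5, 3)
    return R.as_matrix(), t


def brute_force_min_rmsd(P, Q):
    """Oracle: minimize RMSD over rotation space (grid + local refinement)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def f(angles):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for a in grid:
        for b in grid:
            for c in grid:
                res = scipy_minimize(f, [a, b, c], method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-14})
                best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 3))
        res = kabsch_superpose(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = X @ Rz.T + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(moved, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        P = np.array([[0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0.3, 0.2, 2.2]])
        Q = P + 0.2 * rng.standard_normal(P.shape)
        res = kabsch_superpose(P, Q)
        assert res.rmsd == pytest.approx(brute_force_min_rmsd(P, Q), abs=1e-6)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 3))
        mirrored = X * np.array([-1.0, 1.0, 1.0])
        res = kabsch_superpose(mirrored, X)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestRMSD:
    def test_identical_frames_zero(self, static_traj):
        res = rmsd_series(static_traj, static_traj.coordinates[0])
        np.testing.assert_allclose(res["rmsd"], 0.0, atol=1e-12)

    def test_rigid_motions_zero(self, small_complex):
        topo, frame = small_complex
        rng = np.random.default_rng(5)
        frames = []
        for _ in range(4):
            R, t = random_rigid_motion(rng)
            frames.append(frame @ R.T + t)
        traj = Trajectory(np.array(frames), np.arange(4.0), topo)
        res = rmsd_series(traj, frame)
        np.testing.assert_allclose(res["rmsd"], 0.0, atol=1e-9)

    def test_single_displaced_atom_hand_value(self):
        # 4 atoms, one displaced 1 A; fit pinned on the other three
        ref = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [1, 1, 1.0]])
        frame2 = ref.copy()
        frame2[3, 2] += 1.0
        traj = Trajectory(np.array([ref, frame2]), np.arange(2.0))
        res = rmsd_series(traj, ref, fit_selection=np.array([0, 1, 2]))
        assert res["rmsd"][0] == pytest.approx(0.0, abs=1e-12)
        assert res["rmsd"][1] == pytest.approx(0.5, abs=1e-10)

    def test_superposition_never_increases_rmsd(self, small_complex):
        topo, frame = small_complex
        rng = np.random.default_rng(11)
        frames = frame[None] + 0.3 * rng.standard_normal((6, topo.n_atoms, 3))
        traj = Trajectory(frames, np.arange(6.0), topo)
        fitted = rmsd_series(traj, frame)["rmsd"]
        raw = np.sqrt(np.mean(np.sum((frames - frame) ** 2, axis=2), axis=1))
        assert np.all(fitted <= raw + 1e-12)


class TestRMSF:
    def test_identical_frames_zero_profile(self, static_traj):
        prof = rmsf_profile(static_traj)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_single_frame_rejected(self, small_complex):
        topo, frame = small_complex
        traj = Trajectory(frame[None], np.array([0.0]), topo)
        with pytest.raises(ValueError, match="single-frame"):
            rmsf_profile(traj)

    def test_two_point_oscillation_closed_form(self):
        # one atom oscillating +/- d along x in a rigid 5-atom body:
        # RMSF = d for that atom (two-point distribution variance d^2)
        base = np.array([
            [0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [3, 3, 3.0]
        ])
        d = 0.4
        up, down = base.copy(), base.copy()
        up[4, 0] += d
        down[4, 0] -= d
        coords = np.array([up, down] * 10)
        traj = Trajectory(coords, np.arange(20.0))
        prof = rmsf_profile(traj, fit_selection=np.arange(4))
        assert prof.values[4] == pytest.approx(d, abs=1e-10)
        np.testing.assert_allclose(prof.values[:4], 0.0, atol=1e-10)

    def test_gaussian_variance_recovery(self):
        # designed per-axis variance s^2 -> RMSF = s*sqrt(3), within 5%
        topo, frame = make_toy_complex(ToyComplexSpec(
            n_receptor_residues=6, atoms_per_residue=2, ligand_atoms=4
        ))
        n = topo.n_atoms
        anchors = np.arange(8)
        mobile = np.arange(8, n)
        sigma = 0.3
        var = tuple(1e-8 if i < 8 else sigma**2 for i in range(n))
        spec = CorrelatedMotionSpec(
            block_partition=tuple(range(n)),
            target_block_correlations=tuple(
                tuple(float(i == j) for j in range(n)) for i in range(n)
            ),
            per_atom_variance=var, n_frames=2000, seed=21,
        )
        traj = sample_correlated_trajectory(frame, spec, topo)
        prof = rmsf_profile(traj, selection=mobile, fit_selection=anchors)
        expected = sigma * np.sqrt(3)
        assert np.abs(prof.values.mean() - expected) / expected < 0.05


class TestDCCM:
    def test_unit_diagonal(self, small_complex):
        topo, frame = small_complex
        rng = np.random.default_rng(4)
        coords = frame[None] + 0.2 * rng.standard_normal((50, topo.n_atoms, 3))
        m = dccm(Trajectory(coords, np.arange(50.0), topo))
        np.testing.assert_allclose(np.diag(m.values), 1.0)

    def test_perfect_anticorrelation(self):
        # two atoms moving exactly oppositely around fixed anchors
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [8, 0, 0], [8, 4, 0.0]])
        frames = []
        rng = np.random.default_rng(9)
        for _ in range(40):
            d = rng.standard_normal(3) * 0.3
            f = base.copy()
            f[3] += d
            f[4] -= d
            frames.append(f)
        traj = Trajectory(np.array(frames), np.arange(40.0))
        m = dccm(traj, selection=np.array([3, 4]), fit_selection=np.arange(3))
        assert m.values[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_block_correlation_recovery(self):
        # designed inter-block correlation 0.8 recovered within 0.05
        topo, frame = make_toy_complex(ToyComplexSpec(
            n_receptor_residues=10, atoms_per_residue=2, ligand_atoms=4
        ))
        n = topo.n_atoms
        part = tuple(0 if i < 12 else (1 if i < 18 else 2) for i in range(n))
        B = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.8), (0.0, 0.8, 1.0))
        var = tuple(1e-8 if i < 12 else 0.25 for i in range(n))
        spec = CorrelatedMotionSpec(part, B, per_atom_variance=var,
                                    n_frames=5000, seed=42)
        traj = sample_correlated_trajectory(frame, spec, topo)
        m = dccm(traj, selection=np.arange(12, n), fit_selection=np.arange(12))
        inter = m.values[:6, 6:]
        assert abs(inter.mean() - 0.8) < 0.05

    def test_zero_variance_atom_convention(self, small_complex):
        # frozen atom: off-diagonal 0, diagonal 1, with a warning
        topo, frame = small_complex
        rng = np.random.default_rng(12)
        coords = np.array([frame] * 30)
        coords[:, 3:, :] += 0.2 * rng.standard_normal((30, topo.n_atoms - 3, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            m = dccm(Trajectory(coords, np.arange(30.0), topo),
                     fit_selection=np.array([0, 1, 2]))
        np.testing.assert_allclose(m.values[0, 1:], 0.0, atol=1e-12)
        assert m.values[0, 0] == 1.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariants_on_random_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        n_atoms = int(rng.integers(4, 9))
        n_frames = int(rng.integers(3, 20))
        coords = rng.standard_normal((n_frames, n_atoms, 3)) * rng.uniform(0.1, 2)
        coords += rng.uniform(-10, 10, (1, n_atoms, 3))
        m = dccm(Trajectory(coords, np.arange(float(n_frames)))).values
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert m.min() >= -1.0 - 1e-12 and m.max() <= 1.0 + 1e-12

    def test_rigid_motion_invariance(self, small_complex):
        topo, frame = small_complex
        rng = np.random.default_rng(3)
        coords = frame[None] + 0.2 * rng.standard_normal((30, topo.n_atoms, 3))
        traj = Trajectory(coords, np.arange(30.0), topo)
        m1 = dccm(traj).values
        R, t = random_rigid_motion(rng)
        moved = coords @ R.T + t
        m2 = dccm(Trajectory(moved, np.arange(30.0), topo)).values
        np.testing.assert_allclose(m1, m2, atol=1e-8)


class TestPCA:
    def test_rigid_trajectory_zero_spectrum(self, static_traj):
        spec = covariance_pca(static_traj, k=3)
        np.testing.assert_allclose(spec.eigenvalues, 0.0, atol=1e-12)

    def test_k_exceeding_3n_rejected(self, static_traj):
        with pytest.raises(ValueError, match="exceeds"):
            covariance_pca(static_traj, k=3 * static_traj.n_atoms + 1)

    def test_eigenvalue_sum_equals_trace(self, small_complex):
        topo, frame = small_complex
        rng = np.random.default_rng(8)
        coords = frame[None] + 0.3 * rng.standard_normal((200, topo.n_atoms, 3))
        traj = Trajectory(coords, np.arange(200.0), topo)
        from mmsie.structural_dynamics import _fit_to_mean
        fitted = _fit_to_mean(traj.coordinates, None)
        X = fitted.reshape(200, -1)
        X = X - X.mean(axis=0)
        cov_trace = np.trace(X.T @ X) / 200
        spec = covariance_pca(traj, k=6)
        assert spec.eigenvalues.sum() == pytest.approx(cov_trace, rel=1e-10)
        assert spec.cumulative_fraction[-1] == pytest.approx(1.0, rel=1e-12)

    def test_isotropic_noise_eigenvalues_cluster(self):
        # independent isotropic per-atom noise: spectrum flat at sigma^2
        topo, frame = make_toy_complex(ToyComplexSpec(
            n_receptor_residues=10, atoms_per_residue=2, ligand_atoms=4
        ))
        n = topo.n_atoms
        anchors, mobile = np.arange(4), np.arange(4, n)
        var = tuple(1e-8 if i < 4 else 0.25 for i in range(n))
        spec_in = CorrelatedMotionSpec(
            block_partition=tuple(range(n)),
            target_block_correlations=tuple(
                tuple(float(i == j) for j in range(n)) for i in range(n)
            ),
            per_atom_variance=var, n_frames=5000, seed=5,
        )
        traj = sample_correlated_trajectory(frame, spec_in, topo)
        spec = covariance_pca(traj, selection=mobile, k=6, fit_selection=anchors)
        evals = spec.eigenvalues
        assert np.abs(evals.mean() - 0.25) / 0.25 < 0.05
        assert evals.std() / evals.mean() < 0.15

    def test_dominant_mode_fraction_matches_design(self):
        topo, frame = make_toy_complex(ToyComplexSpec(
            n_receptor_residues=10, atoms_per_residue=2, ligand_atoms=4
        ))
        n = topo.n_atoms
        part = tuple(0 if i < 12 else (1 if i < 18 else 2) for i in range(n))
        B = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.9), (0.0, 0.9, 1.0))
        var = tuple(1e-8 if i < 12 else 0.25 for i in range(n))
        spec_in = CorrelatedMotionSpec(part, B, per_atom_variance=var,
                                       n_frames=5000, seed=13)
        traj = sample_correlated_trajectory(frame, spec_in, topo)
        sel = np.arange(12, n)
        # analytic: per-axis covariance S triplicated over x,y,z
        C = np.asarray(B)[np.ix_([part[i] for i in sel], [part[i] for i in sel])]
        np.fill_diagonal(C, 1.0)
        S = 0.25 * C
        lam = np.sort(np.linalg.eigvalsh(S))[::-1]
        expected = lam[0] / (3 * np.trace(S))
        got = covariance_pca(traj, selection=sel, k=1,
                             fit_selection=np.arange(12))
        frac = got.eigenvalues[0] / got.eigenvalues.sum()
        assert abs(frac - expected) / expected < 0.05

    def test_rigid_motion_invariance(self, small_complex):
        topo, frame = small_complex
        rng = np.random.default_rng(17)
        coords = frame[None] + 0.2 * rng.standard_normal((40, topo.n_atoms, 3))
        traj1 = Trajectory(coords, np.arange(40.0), topo)
        R, t = random_rigid_motion(rng)
        traj2 = Trajectory(coords @ R.T + t, np.arange(40.0), topo)
        e1 = covariance_pca(traj1, k=3).eigenvalues
        e2 = covariance_pca(traj2, k=3).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-8)
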