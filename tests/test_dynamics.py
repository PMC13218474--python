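"""Superposition and backbone RMSF."""

import numpy as np
import pytest

from rhpdimer.dynamics import backbone_rmsf, partition_rmsf, superpose

from conftest import build_topology, build_trajectory


def quaternion_rmsd(mobile, reference):
    """Independent oracle: optimal RMSD via the Horn quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    M = x.T @ y
    K = np.empty((4, 4))
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K[0] = [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx]
    K[1] = [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz]
    K[2] = [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy]
    K[3] = [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]
    lam = np.linalg.eigvalsh(K).max()
    e0 = float((x**2).sum() + (y**2).sum())
    msd = max(0.0, (e0 - 2.0 * lam) / len(x))
    return np.sqrt(msd)


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        R, t, moved, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_pure_rotation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90° about z
        mobile = ref @ Rz.T
        R, t, moved, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved, ref, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_quaternion_oracle_on_perturbed_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ref = rng.normal(size=(15, 3))
            ang = rng.uniform(0, np.pi)
            c, s = np.cos(ang), np.sin(ang)
            Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            mobile = ref @ Rz.T + rng.normal(0, 0.3, (15, 3)) + rng.uniform(-5, 5, 3)
            pre = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
            _, _, _, rmsd = superpose(mobile, ref)
            assert rmsd <= pre + 1e-12
            assert rmsd == pytest.approx(quaternion_rmsd(mobile, ref), abs=1e-9)

    def test_rejects_degenerate_selection(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _jitter_chain_topology(n_res=4):
    atoms = []
    for r in range(1, n_res + 1):
        atoms.append(("A", r, "M", "C1", "C", True))
    atoms.append(("B", 1, "O", "C1", "C", True))
    return build_topology(atoms, box=(100.0, 100.0, 100.0))


class TestBackboneRMSF:
    def test_static_chain_is_zero(self):
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        traj = build_trajectory(topo, [base] * 10)
        rep = backbone_rmsf(traj, "A")
        np.testing.assert_allclose(rep.rmsf, 0.0, atol=1e-5)

    def test_two_point_fluctuation_equals_half_gap(self):
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        lo, hi = base.copy(), base.copy()
        d = 0.5
        lo[0, 0] -= d
        hi[0, 0] += d
        traj = build_trajectory(topo, [lo, hi] * 20)
        rep = backbone_rmsf(traj, "A", superposition=False)
        assert rep.rmsf[0] == pytest.approx(d, abs=1e-5)
        np.testing.assert_allclose(rep.rmsf[1:], 0.0, atol=1e-6)

    def test_gaussian_jitter_approaches_sigma_sqrt3(self):
        rng = np.random.default_rng(3)
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        sigma = 0.4
        n = 20000
        frames = np.tile(base, (n, 1, 1))
        frames[:, 0, :] += rng.normal(0, sigma, (n, 3))
        traj = build_trajectory(topo, frames, times=np.arange(n) * 0.01)
        rep = backbone_rmsf(traj, "A", superposition=False)
        assert rep.rmsf[0] == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_doubling_sigma_doubles_rmsf(self):
        rng = np.random.default_rng(4)
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        vals = []
        for sigma in (0.2, 0.4):
            n = 8000
            frames = np.tile(base, (n, 1, 1))
            frames[:, 0, :] += rng.normal(0, sigma, (n, 3))
            traj = build_trajectory(topo, frames, times=np.arange(n) * 0.01)
            vals.append(backbone_rmsf(traj, "A", superposition=False).rmsf[0])
        assert vals[1] / vals[0] == pytest.approx(2.0, rel=0.05)

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(5)
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        n = 60
        frames = np.tile(base, (n, 1, 1))
        frames[:, :4, :] += rng.normal(0, 0.3, (n, 4, 3))
        rep0 = backbone_rmsf(build_trajectory(topo, frames), "A", superposition=True)
        moved = frames.copy()
        for f in range(n):
            ang = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(ang), np.sin(ang)
            Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            moved[f] = frames[f] @ Rz.T + rng.uniform(-3, 3, 3)
        rep1 = backbone_rmsf(build_trajectory(topo, moved), "A", superposition=True)
        np.testing.assert_allclose(rep1.rmsf, rep0.rmsf, atol=1e-4)

    def test_trailing_window_selection(self):
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        # big jitter early, static in the last 4 ns
        frames = [base + (5.0 if t < 6 else 0.0) * ((t % 2) * 2 - 1) for t in range(11)]
        traj = build_trajectory(topo, frames, times=np.arange(11.0))
        rep = backbone_rmsf(traj, "A", window_ns=4.0, superposition=False)
        assert rep.window_ns == (6.0, 10.0)
        np.testing.assert_allclose(rep.rmsf, 0.0, atol=1e-5)

    def test_short_trajectory_warns_and_uses_all(self):
        topo = _jitter_chain_topology()
        base = np.array([[10.0, 10, 10], [13, 10, 10], [13, 13, 10], [10, 13, 10], [50, 50, 50]])
        traj = build_trajectory(topo, [base] * 5, times=np.arange(5.0))
        with pytest.warns(UserWarning, match="shorter"):
            rep = backbone_rmsf(traj, "A", window_ns=40.0)
        assert rep.window_ns == (0.0, 4.0)


class TestPartitionRMSF:
    def _report(self, rmsf_vals):
        from rhpdimer.dynamics import RMSFReport

        n = len(rmsf_vals)
        return RMSFReport(
            chain="A",
            residues=np.arange(1, n + 1),
            monomer_codes=np.asarray(["M"] * n, dtype=object),
            rmsf=np.asarray(rmsf_vals, dtype=float),
            window_ns=(0.0, 1.0),
            atom_ids=np.arange(n),
            atom_rmsf=np.asarray(rmsf_vals, dtype=float),
        )

    def test_group_means(self):
        mi, mn = partition_rmsf(self._report([1, 1, 2, 2]), {3, 4})
        assert (mi, mn) == (2.0, 1.0)

    def test_empty_group_undefined(self):
        mi, mn = partition_rmsf(self._report([1, 2]), {1, 2})
        assert mn is None and mi == pytest.approx(1.5)

    def test_overall_mean_is_weighted_combination(self):
        rep = self._report([0.5, 1.5, 2.5, 3.5, 4.0])
        inter = {2, 5}
        mi, mn = partition_rmsf(rep, inter)
        combined = (len(inter) * mi + 3 * mn) / 5
        assert combined == pytest.approx(float(rep.rmsf.mean()))

    def test_interface_jitter_raises_interacting_rmsf(self, assoc_scenario):
        _, traj, truth = assoc_scenario
        rep = backbone_rmsf(traj, "A", window_ns=40.0)
        mi, mn = partition_rmsf(rep, truth.interface_residues["A"])
        assert mi > mn

    def test_rejects_foreign_residues(self):
        with pytest.raises(ValueError, match="outside"):
            partition_rmsf(self._report([1, 2]), {7})
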