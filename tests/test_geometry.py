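import numpy as np
import pytest

from gpcrdimer.errors import SelectionError
from gpcrdimer.geometry import (dihedral, kabsch_superpose, min_pair_distance,
                                rmsd_trace)
from gpcrdimer.model_io import Trajectory

from _oracles import brute_min_distance, dihedral_oracle, quaternion_rmsd
from conftest import make_structure


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_motion_fully_removed(self, rng):
        pts = rng.normal(size=(5, 3))
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        moved = pts @ rot90.T + np.array([5.0, 0.0, 0.0])
        _r, _t, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_always_proper(self, rng):
        for _ in range(20):
            a = rng.normal(size=(4, 3))
            b = rng.normal(size=(4, 3))
            rot, _t, _r = kabsch_superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_oracle_on_random_instances(self, rng):
        for _ in range(120):
            m = rng.integers(4, 12)
            ref = rng.normal(size=(m, 3)) * rng.uniform(0.5, 5.0)
            mob = ref + rng.normal(scale=rng.uniform(0.01, 1.0), size=(m, 3))
            mob = mob @ random_rotation(rng).T + rng.normal(size=3) * 10
            _r, _t, rmsd = kabsch_superpose(mob, ref)
            assert rmsd == pytest.approx(quaternion_rmsd(mob, ref), abs=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line + 1.0, line)


def _traj_from_coords(coords, chain="A"):
    n = coords.shape[1]
    atoms = [(f"C{i+1}", "C", "GLY", 1 + i, chain, coords[0, i])
             for i in range(n)]
    s = make_structure(atoms)
    return Trajectory(s, coords, np.arange(coords.shape[0], dtype=float))


class TestRmsdTrace:
    def test_zero_at_reference_frame(self, rng):
        coords = rng.normal(size=(4, 5, 3))
        trace = rmsd_trace(_traj_from_coords(coords), "all", reference=2,
                           superpose=False)
        assert trace.values[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_closed_form(self, rng):
        base = rng.normal(size=(1, 8, 3))
        coords = np.concatenate([base, base])
        d = 1.7
        coords[1, 3, 0] += d
        trace = rmsd_trace(_traj_from_coords(coords), "all", reference=0,
                           superpose=False)
        assert trace.values[1] == pytest.approx(d / np.sqrt(8), abs=1e-12)

    def test_matches_per_frame_kabsch_oracle(self, rng):
        coords = np.cumsum(rng.normal(scale=0.3, size=(12, 6, 3)), axis=0) \
            + rng.normal(size=(1, 6, 3)) * 3
        trace = rmsd_trace(_traj_from_coords(coords), "all", reference=0,
                           superpose=True)
        for t in range(12):
            assert trace.values[t] == pytest.approx(
                quaternion_rmsd(coords[t], coords[0]), abs=1e-6)

    def test_superposed_rmsd_invariant_under_rigid_motion(self, rng):
        coords = rng.normal(size=(6, 7, 3))
        moved = coords.copy()
        for t in range(6):
            moved[t] = coords[t] @ random_rotation(rng).T + rng.normal(size=3)
        a = rmsd_trace(_traj_from_coords(coords), "all", 0, superpose=True)
        b = rmsd_trace(_traj_from_coords(moved), "all", 0, superpose=True)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_superposition_never_increases_rmsd(self, rng):
        coords = rng.normal(size=(5, 6, 3))
        traj = _traj_from_coords(coords)
        fit = rmsd_trace(traj, "all", 0, superpose=True)
        raw = rmsd_trace(traj, "all", 0, superpose=False)
        assert np.all(fit.values <= raw.values + 1e-9)

    def test_empty_selection_rejected(self, rng):
        traj = _traj_from_coords(rng.normal(size=(2, 4, 3)))
        with pytest.raises(SelectionError):
            rmsd_trace(traj, "chain Z")


class TestDihedral:
    def test_planar_reference_geometries(self):
        # eclipsed (cis, same side) and anti-periplanar (trans)
        assert dihedral((1, 1, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0)) \
            == pytest.approx(0.0, abs=1e-10)
        assert dihedral((1, 1, 0), (1, 0, 0), (0, 0, 0), (0, -1, 0)) \
            == pytest.approx(180.0, abs=1e-10)

    def test_right_angle_example_lands_at_270(self):
        assert dihedral((1, 1, 0), (1, 0, 0), (0, 0, 0), (0, 0, 1)) \
            == pytest.approx(270.0, abs=1e-10)

    def test_matches_independent_atan2_oracle(self, rng):
        for _ in range(150):
            pts = rng.normal(size=(4, 3)) * rng.uniform(0.5, 4.0)
            try:
                got = dihedral(*pts)
            except ValueError:
                continue
            want = dihedral_oracle(*pts)
            assert abs((got - want + 180) % 360 - 180) < 1e-6

    def test_matches_mdanalysis_convention(self, rng):
        """Field-standard library as a second, fully independent oracle."""
        mda = pytest.importorskip("MDAnalysis.lib.distances")
        for _ in range(50):
            pts = rng.normal(size=(4, 3)).astype(np.float64) * 3
            got = dihedral(*pts)
            ref = np.degrees(mda.calc_dihedrals(
                pts[0][None], pts[1][None], pts[2][None], pts[3][None]))[0]
            assert abs((got - ref % 360 + 180) % 360 - 180) < 1e-4

    def test_invariant_under_order_reversal(self, rng):
        # the torsion sign does not depend on the viewing direction
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2
            try:
                fwd = dihedral(*pts)
            except ValueError:
                continue
            rev = dihedral(*pts[::-1])
            assert abs((fwd - rev + 180) % 360 - 180) < 1e-8

    def test_collinear_triple_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_vectorized_matches_scalar(self, rng):
        pts = rng.normal(size=(4, 10, 3))
        vec = dihedral(pts[0], pts[1], pts[2], pts[3])
        for t in range(10):
            assert vec[t] == pytest.approx(
                dihedral(pts[0, t], pts[1, t], pts[2, t], pts[3, t]))


class TestMinPairDistance:
    def test_two_single_atoms(self):
        assert min_pair_distance([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)

    def test_identical_groups_zero(self, rng):
        g = rng.normal(size=(4, 3))
        assert min_pair_distance(g, g) == pytest.approx(0.0)

    def test_matches_double_loop_oracle_and_symmetry(self, rng):
        for _ in range(100):
            a = rng.normal(size=(10, 3)) * 5
            b = rng.normal(size=(10, 3)) * 5 + 3
            got = min_pair_distance(a, b)
            assert got == pytest.approx(brute_min_distance(a, b), abs=1e-10)
            assert got == pytest.approx(min_pair_distance(b, a), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            min_pair_distance(np.empty((0, 3)), [[0, 0, 0]])
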