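"""Dihedrals, superposition, and the scalar shape/flexibility series."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gagtraj.geometry import (
    GeometryError,
    dihedral,
    dihedral_batch,
    eed_series,
    kabsch_superpose,
    linkage_series,
    pool_linkages_by_type,
    rgyr_series,
    rmsd_series,
    wrap_angle,
)
from gagtraj.model import DescriptorSeries, Trajectory


def dihedral_oracle(p1, p2, p3, p4):
    """Independent projection-based torsion (atan2 of in-plane components)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    bh = b / np.linalg.norm(b)
    w1 = (p1 - p2) - np.dot(p1 - p2, bh) * bh
    w2 = (p4 - p3) - np.dot(p4 - p3, bh) * bh
    ang = np.degrees(np.arctan2(np.dot(np.cross(w1, w2), bh), np.dot(w1, w2)))
    return np.mod(ang + 180.0, 360.0) - 180.0


def rmsd_oracle(ref, mob, n_starts=24, seed=0):
    """Global best-fit RMSD by multi-start optimisation over rotations,
    independent of the SVD route."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((mob_c @ r.T - ref_c) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        res = minimize(cost, rng.normal(size=3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_wraps_to_minus_180(self):
        ang = dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0))
        assert ang == pytest.approx(-180.0, abs=1e-12)

    def test_matches_independent_oracle_on_random_quadruples(self, rng):
        for _ in range(300):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                got = dihedral(*pts)
            except GeometryError:
                continue
            want = dihedral_oracle(*pts)
            assert abs(wrap_angle(got - want)) < 1e-10

    def test_rigid_motion_invariance_and_mirror_sign_flip(self, rng):
        pts = rng.normal(size=(4, 3)) * 2.0
        base = dihedral(*pts)
        rot = Rotation.random(random_state=5).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 7.0])
        assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-base, abs=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_batch_equals_scalar(self, rng):
        p = rng.normal(size=(4, 5, 3))
        batch = dihedral_batch(p[0], p[1], p[2], p[3])
        for i in range(5):
            assert batch[i] == pytest.approx(dihedral(p[0, i], p[1, i], p[2, i], p[3, i]))


class TestKabsch:
    def test_identity_gives_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        assert kabsch_superpose(pts, pts)[2] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_gives_zero(self, rng):
        pts = rng.normal(size=(12, 3)) * 4.0
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 5.0, 5.0])
        assert kabsch_superpose(pts, moved)[2] == pytest.approx(0.0, abs=1e-10)

    def test_rotation_is_proper(self, rng):
        # near-planar configurations tempt reflections; determinant must stay +1
        pts = rng.normal(size=(8, 3)) * np.array([3.0, 3.0, 0.05])
        mob = -pts + rng.normal(size=(8, 3)) * 0.1
        rot, _, _ = kabsch_superpose(pts, mob)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_multistart_oracle(self, rng):
        ref = rng.normal(size=(10, 3)) * 2.0
        mob = ref + rng.normal(size=(10, 3)) * 0.4
        got = kabsch_superpose(ref, mob)[2]
        want = rmsd_oracle(ref, mob)
        assert got == pytest.approx(want, abs=1e-6)
        assert got <= want + 1e-9   # SVD result is the global minimum

    def test_errors(self, rng):
        with pytest.raises(GeometryError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)


def _mini_traj(frames):
    frames = np.asarray(frames, dtype=float)
    return Trajectory(frames, solute_indices=np.arange(frames.shape[1]))


class TestSeries:
    def test_rmsd_zero_for_rigid_motion_trajectory(self, rng, dp2_run):
        _, topo, traj, _, _ = dp2_run
        base = traj.coordinates[0]
        frames = [base]
        for k in range(1, 6):
            rot = Rotation.random(random_state=k).as_matrix()
            frames.append(base @ rot.T + k)
        rigid = Trajectory(np.stack(frames), traj.solute_indices,
                           traj.ion_indices, traj.water_indices)
        values = rmsd_series(rigid, topo).values
        assert values[0] == 0.0
        assert np.all(values < 1e-9)

    def test_rmsd_two_state_modes_match_oracle(self, rng):
        base = rng.normal(size=(15, 3)) * 3.0
        other = base + rng.normal(size=(15, 3)) * 0.8
        planted = rmsd_oracle(base, other)
        frames = [base]
        for k in range(1, 40):
            rot = Rotation.random(random_state=100 + k).as_matrix()
            state = base if k % 2 == 0 else other
            frames.append(state @ rot.T + rng.normal(size=3))
        values = rmsd_series(_mini_traj(np.stack(frames)), topology=None).values
        lo, hi = values[2::2], values[1::2]
        assert np.all(np.abs(lo) < 1e-8)
        assert np.allclose(hi, planted, atol=1e-6)

    def test_rgyr_cube_and_single_atom(self):
        cube = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                        dtype=float)
        v = rgyr_series(_mini_traj(cube[None]), topology=None).values
        assert v[0] == pytest.approx(np.sqrt(3.0), abs=1e-12)
        single = _mini_traj(np.zeros((1, 1, 3)))
        assert rgyr_series(single, topology=None).values[0] == 0.0

    def test_rgyr_direct_formula_and_invariances(self, rng):
        pts = rng.normal(size=(50, 3)) * 2.0
        got = rgyr_series(_mini_traj(pts[None]), topology=None).values[0]
        centred = pts - pts.mean(axis=0)
        want = np.sqrt((centred**2).sum() / len(pts))
        assert got == pytest.approx(want, abs=1e-12)
        rot = Rotation.random(random_state=0).as_matrix()
        moved = pts @ rot.T + 11.0
        assert rgyr_series(_mini_traj(moved[None]), topology=None).values[0] == \
            pytest.approx(got, abs=1e-9)
        assert rgyr_series(_mini_traj((pts * 2.5)[None]), topology=None).values[0] == \
            pytest.approx(2.5 * got, abs=1e-9)

    def test_eed_345_triangle(self, dp2_run):
        _, topo, traj, _, _ = dp2_run
        coords = traj.coordinates[:1].copy()
        i, j = topo.eed_atoms
        coords[0, i] = (0.0, 0.0, 0.0)
        coords[0, j] = (3.0, 4.0, 0.0)
        t = Trajectory(coords, traj.solute_indices, traj.ion_indices, traj.water_indices)
        assert eed_series(t, topo).values[0] == pytest.approx(5.0, abs=1e-12)
        coords[0, j] = coords[0, i]
        t = Trajectory(coords, traj.solute_indices, traj.ion_indices, traj.water_indices)
        assert eed_series(t, topo).values[0] == 0.0

    def test_series_lengths_and_variance_identity(self, dp2_run):
        _, topo, traj, _, _ = dp2_run
        for series in (rmsd_series(traj, topo), rgyr_series(traj, topo),
                       eed_series(traj, topo)):
            assert isinstance(series, DescriptorSeries)
            assert len(series) == traj.n_frames
            v = series.values
            two_pass = float(np.mean((v - v.mean()) ** 2))
            assert series.summary["variance"] == pytest.approx(two_pass, rel=1e-10)

    def test_linkage_counts_and_pooling(self, dp2_run, dp6_run):
        _, topo2, traj2, _, _ = dp2_run
        assert len(linkage_series(traj2, topo2)) == 1
        _, topo6, traj6, _, _ = dp6_run
        series = linkage_series(traj6, topo6)
        assert len(series) == 5
        assert [s.linkage_type for s in series] == [1, 2, 1, 2, 1]
        pooled = pool_linkages_by_type(series)
        assert set(pooled) == {1, 2}
        assert len(pooled[1][0]) == 3 * traj6.n_frames
        assert len(pooled[2][0]) == 2 * traj6.n_frames

    def test_angles_in_range(self, dp6_run):
        _, topo, traj, _, _ = dp6_run
        for s in linkage_series(traj, topo):
            for a in (s.phi, s.psi):
                assert np.all(a >= -180.0) and np.all(a < 180.0)
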