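"""Torsions, superposition, trajectory statistics, poses and slerp."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopstring.geometry import (
    AlignmentError,
    DegenerateGeometryError,
    RigidPose,
    UndefinedDihedralError,
    angular_difference,
    dihedral,
    dynamic_cross_correlation,
    hbond_distance_series,
    kabsch_superpose,
    layer_thickness,
    lerp_center,
    per_residue_displacement,
    pose_of,
    apply_pose,
    quat_rotation_angle,
    rmsd,
    rmsd_series,
    slerp,
    torsion_deviation_profile,
)
from loopstring.structures import AtomRecord, AtomSelection, Conformation, Trajectory


def _rot(axis, deg):
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.radians(deg) * axis / np.linalg.norm(axis)).as_matrix()


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(
            180.0
        )

    def test_planar_cis_is_0(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_constructed_twist_matches_normal_vector_oracle(self, rng):
        # independent oracle: explicit plane normals + signed atan2
        for _ in range(20):
            p = rng.normal(size=(4, 3)) * 2
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            m1 = np.cross(b2 / np.linalg.norm(b2), n1)
            oracle = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
            assert dihedral(*p) == pytest.approx(oracle, abs=1e-6)

    def test_explicit_90_degree_twist(self):
        # p4 rotated +90 deg about the p2->p3 axis from the trans position
        p1, p2, p3 = np.array([0, 1, 0.0]), np.zeros(3), np.array([1, 0, 0.0])
        trans = np.array([1.0, -1.0, 0.0])
        p4 = p3 + _rot([1, 0, 0], 90.0) @ (trans - p3)
        assert dihedral(p1, p2, p3, p4) == pytest.approx(-90.0, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(UndefinedDihedralError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestDeviationProfile:
    def test_identical_states_give_zero(self, endpoint_pair):
        prof = torsion_deviation_profile(
            endpoint_pair.state_a, endpoint_pair.state_a
        )
        assert all(p.combined == pytest.approx(0.0, abs=1e-9) for p in prof)

    def test_three_four_five(self):
        assert np.hypot(3.0, 4.0) == pytest.approx(5.0)
        assert angular_difference(10.0, 13.0) == pytest.approx(3.0)

    def test_periodic_wrap(self):
        assert angular_difference(179.0, -179.0) == pytest.approx(2.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-180, 180))
    def test_full_turn_has_zero_deviation(self, x):
        assert angular_difference(x, x + 360.0) == pytest.approx(0.0, abs=1e-9)

    def test_sequence_mismatch_raises(self, endpoint_pair):
        other = Conformation(
            [AtomRecord(a.atom_name, "XXX", a.residue_index) for a in
             endpoint_pair.state_a.atoms],
            endpoint_pair.state_a.coords,
        )
        with pytest.raises(AlignmentError):
            torsion_deviation_profile(endpoint_pair.state_a, other)

    def test_flipped_residues_peak(self, endpoint_pair):
        prof = torsion_deviation_profile(
            endpoint_pair.state_a, endpoint_pair.state_b
        )
        by_res = sorted(prof, key=lambda p: -p.combined)
        assert {p.residue_index for p in by_res[:2]} == {5, 6}


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        pose, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert quat_rotation_angle(pose.orientation) == pytest.approx(0.0, abs=1e-6)

    def test_pure_translation(self, rng):
        x = rng.normal(size=(10, 3))
        pose, r = kabsch_superpose(x + np.array([5.0, 0, 0]), x)
        assert r == pytest.approx(0.0, abs=1e-10)
        shift = pose.center - x.mean(axis=0)
        np.testing.assert_allclose(shift, [5.0, 0, 0], atol=1e-10)

    def test_rotation_recovered_vs_angle_grid_oracle(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        x = rng.normal(size=(20, 3)) * 3
        y = (x - x.mean(0)) @ _rot(axis, 37.0).T + x.mean(0)
        y_noisy = y + rng.normal(scale=0.1, size=y.shape)
        pose, r = kabsch_superpose(y_noisy, x)
        # brute-force search over the rotation angle about the known axis
        best_angle, best_r = None, np.inf
        for ang in np.arange(0.0, 90.0, 0.5):
            cand = (x - x.mean(0)) @ _rot(axis, ang).T
            rr = np.sqrt(np.mean(np.sum((cand - (y_noisy - y_noisy.mean(0))) ** 2, 1)))
            if rr < best_r:
                best_angle, best_r = ang, rr
        fitted_angle = quat_rotation_angle(pose.orientation)
        assert fitted_angle == pytest.approx(best_angle, abs=1.0)
        # rmsd close to sigma*sqrt(3) less the 6 fitted rigid-body d.o.f.
        expected = 0.1 * np.sqrt(3.0) * np.sqrt(1.0 - 6.0 / 60.0)
        assert r == pytest.approx(expected, rel=0.15)

    def test_degenerate_raises(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_superposed_never_worse_than_raw(self, rng):
        for _ in range(10):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            assert rmsd(a, b) <= rmsd(a, b, superpose=False) + 1e-12


class TestRMSDSeries:
    def _traj(self, frames):
        return Trajectory(frames, np.arange(len(frames), dtype=float))

    def test_copies_of_reference_are_zero(self, endpoint_pair, rep_selection):
        ref = endpoint_pair.state_a
        traj = self._traj([ref.coords.copy() for _ in range(3)])
        out = rmsd_series(traj, ref, rep_selection)
        assert all(v == pytest.approx(0.0, abs=1e-6) for _, v in out)

    def test_translation_removed_by_superposition(self, endpoint_pair, rep_selection):
        ref = endpoint_pair.state_a
        traj = self._traj([ref.coords + np.array([1.0, 2.0, 3.0])])
        assert rmsd_series(traj, ref, rep_selection, superpose=True)[0][1] == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_uniform_shift_without_superposition(self, endpoint_pair, rep_selection):
        ref = endpoint_pair.state_a
        traj = self._traj([ref.coords + np.array([1.0, 0.0, 0.0])])
        assert rmsd_series(traj, ref, rep_selection, superpose=False)[0][1] == (
            pytest.approx(1.0, abs=1e-12)
        )


def _ca_chain(n):
    atoms = [AtomRecord("CA", "GLY", i + 1) for i in range(n)]
    base = np.stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)], axis=1)
    base[:, 1] = np.sin(np.arange(n))  # break collinearity
    return atoms, base


class TestCrossCorrelation:
    def test_diagonal_is_one_and_mirror_is_minus_one(self, rng):
        atoms, base = _ca_chain(6)
        frames = []
        for _ in range(200):
            d = rng.normal(scale=0.1, size=3)
            f = base.copy()
            f[3] += d  # residue 4 moves
            f[4] -= d  # residue 5 mirrors it
            frames.append(f)
        traj = Trajectory(frames, np.arange(200.0))
        cm = dynamic_cross_correlation(traj, atoms, [4, 5], [4, 5])
        np.testing.assert_allclose(np.diag(cm.values), 1.0, atol=1e-10)
        assert cm.values[0, 1] == pytest.approx(-1.0, abs=0.05)
        np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-10)

    def test_independent_motion_uncorrelated(self, rng):
        # enough residues that the shared alignment frame induces < 0.05
        atoms, base = _ca_chain(30)
        frames = base[None] + rng.normal(scale=0.1, size=(10_000, 30, 3))
        traj = Trajectory(list(frames), np.arange(10_000.0))
        cm = dynamic_cross_correlation(traj, atoms, [2, 3], [20, 25])
        assert np.all(np.abs(cm.values) < 0.05)

    def test_zero_fluctuation_marked_nan(self):
        atoms, base = _ca_chain(6)
        traj = Trajectory([base.copy(), base.copy()], np.arange(2.0))
        cm = dynamic_cross_correlation(traj, atoms, [1, 2], [5, 6])
        assert np.all(np.isnan(cm.values))


class TestDistancesAndThickness:
    def test_two_fixed_atoms(self):
        atoms = [AtomRecord("O", "GLY", 1), AtomRecord("H", "GLY", 2)]
        conf = Conformation(atoms, np.array([[0.0, 0, 0], [0, 0, 2.0]]))
        assert hbond_distance_series(conf, (2, "H"), (1, "O"))[0] == pytest.approx(2.0)

    def test_missing_atom_suggests_hydrogen_placement(self):
        atoms = [AtomRecord("O", "GLY", 1), AtomRecord("N", "GLY", 2)]
        conf = Conformation(atoms, np.zeros((2, 3)) + [[0, 0, 0], [0, 0, 2]])
        with pytest.raises(KeyError, match="place_amide_hydrogens"):
            hbond_distance_series(conf, (2, "H"), (1, "O"))

    def test_layer_thickness_fixed_planes(self):
        frames = [np.array([[0.0, 0, 19.0], [1, 0, 19.0], [0, 0, -19.0], [1, 0, -19.0]])]
        traj = Trajectory(frames, [0.0])
        up, lo = AtomSelection((0, 1)), AtomSelection((2, 3))
        assert layer_thickness(traj, up, lo)[0][1] == pytest.approx(38.0)

    def test_layer_thickness_noisy_mean(self, rng):
        z = rng.normal(scale=1.0, size=(1000, 2))
        frames = [
            np.array([[0.0, 0, 19 + a], [0, 0, -19 + b]]) for a, b in z
        ]
        traj = Trajectory(frames, np.arange(1000.0))
        vals = [v for _, v in layer_thickness(traj, AtomSelection((0,)), AtomSelection((1,)))]
        assert np.mean(vals) == pytest.approx(38.0, abs=0.2)

    def test_empty_group_rejected(self):
        traj = Trajectory([np.zeros((2, 3))], [0.0])
        with pytest.raises(ValueError):
            layer_thickness(traj, AtomSelection(()), AtomSelection((0,)))


class TestPerResidueDisplacement:
    def test_identity_gives_zero(self, endpoint_pair, rep_selection):
        out = per_residue_displacement(
            endpoint_pair.state_a, endpoint_pair.state_a, rep_selection
        )
        assert all(d == pytest.approx(0.0, abs=1e-9) for _, d in out)

    def test_displacement_outside_alignment_set(self, endpoint_pair):
        conf = endpoint_pair.state_a
        moved = conf.copy()
        i_last = conf.index_of(11, "CA")
        moved.coords[i_last] += np.array([2.0, 0.0, 0.0])
        align = AtomSelection(
            tuple(
                i
                for i, a in enumerate(conf.atoms)
                if a.atom_name == "CA" and a.residue_index <= 9
            )
        )
        out = dict(per_residue_displacement(moved, conf, align))
        assert out[11] == pytest.approx(2.0, abs=0.05)
        assert out[5] < 0.05

    def test_invariant_under_rigid_motion(self, endpoint_pair, rep_selection, rng):
        final = endpoint_pair.state_b
        target = endpoint_pair.state_a
        base = per_residue_displacement(final, target, rep_selection)
        moved = final.copy()
        moved.coords = (final.coords - final.coords.mean(0)) @ _rot(
            rng.normal(size=3), 73.0
        ).T + np.array([4.0, -2.0, 9.0])
        shifted = per_residue_displacement(moved, target, rep_selection)
        np.testing.assert_allclose(
            [d for _, d in base], [d for _, d in shifted], atol=1e-8
        )


class TestPosesAndSlerp:
    def test_slerp_fixed_point(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        for t in (0.0, 0.3, 1.0):
            np.testing.assert_allclose(np.abs(slerp(q, q, t)), np.abs(q), atol=1e-12)

    def test_slerp_halfway_of_90_about_z(self):
        q0 = np.array([1.0, 0, 0, 0])
        q90 = np.array([np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)])
        mid = slerp(q0, q90, 0.5)
        q45 = np.array([np.cos(np.pi / 8), 0, 0, np.sin(np.pi / 8)])
        np.testing.assert_allclose(mid, q45, atol=1e-8)

    def test_constant_angular_velocity(self, rng):
        q0 = rng.normal(size=4)
        q1 = rng.normal(size=4)
        q0 /= np.linalg.norm(q0)
        q1 /= np.linalg.norm(q1)
        ts = np.linspace(0, 1, 100)
        qs = [slerp(q0, q1, t) for t in ts]
        steps = [quat_rotation_angle(a, b) for a, b in zip(qs[1:], qs[:-1])]
        assert np.ptp(steps) < 1e-6

    def test_antipodal_resolved_to_shortest_arc(self):
        q0 = np.array([1.0, 0, 0, 0])
        q1 = -np.array([np.cos(0.1), 0, 0, np.sin(0.1)])
        mid = slerp(q0, q1, 0.5)
        assert quat_rotation_angle(mid, q0) < 6.0  # short way, not 170+ deg

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            slerp(np.zeros(4), np.array([1.0, 0, 0, 0]), 0.5)

    def test_lerp_center_is_affine(self):
        c = lerp_center([0.0, 0, 0], [2.0, 4.0, 6.0], 0.25)
        np.testing.assert_allclose(c, [0.5, 1.0, 1.5])

    def test_pose_roundtrip_identity(self, endpoint_pair, rep_selection, rng):
        ref = endpoint_pair.state_a
        conf = ref.copy()
        conf.coords = (ref.coords - ref.coords.mean(0)) @ _rot(
            rng.normal(size=3), 25.0
        ).T + np.array([3.0, 1.0, -2.0])
        pose = pose_of(conf, ref, rep_selection)
        idx = rep_selection.array()
        rebuilt = apply_pose(ref.coords[idx], pose)
        np.testing.assert_allclose(rebuilt, conf.coords[idx], atol=1e-8)
        pose2 = pose_of(
            Conformation([conf.atoms[i] for i in idx], rebuilt),
            Conformation([ref.atoms[i] for i in idx], ref.coords[idx]),
            AtomSelection(tuple(range(len(idx)))),
        )
        assert quat_rotation_angle(pose2.orientation, pose.orientation) < 1e-6

    def test_quaternion_canonical_sign(self):
        pose = RigidPose(np.zeros(3), np.array([-1.0, 0, 0, 0]))
        assert pose.orientation[0] > 0
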