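"""Collective variables: values, analytic gradients, restraints."""

import numpy as np
import pytest

from mabp import (
    AtomGroup,
    DynamicReference,
    HostGuest3D,
    RestraintSet,
    RMSDistanceCV,
    dihedral_cv,
    restraint_energy_force,
    rms_distance_cv,
    rms_distance_gradient,
)
from mabp.cvs import DihedralCV, dihedral_gradient


class TestAtomGroup:
    def test_rejects_empty_duplicate_negative(self):
        with pytest.raises(ValueError):
            AtomGroup(())
        with pytest.raises(ValueError):
            AtomGroup((1, 1, 2))
        with pytest.raises(ValueError):
            AtomGroup((-1, 0))


class TestRMSDistance:
    def test_atom_at_reference_is_zero(self):
        assert rms_distance_cv([[1.0, 2.0, 3.0]], [1.0, 2.0, 3.0]) == 0.0

    def test_two_atoms_equidistant(self):
        coords = [[3.0, 0.0, 0.0], [-3.0, 0.0, 0.0]]
        assert np.isclose(rms_distance_cv(coords, [0.0, 0.0, 0.0]), 3.0)

    def test_matches_bruteforce_recomputation(self, rng):
        for _ in range(20):
            coords = rng.normal(size=(5, 3)) * 4
            ref = rng.normal(size=3)
            expect = np.sqrt(
                sum(np.sum((c - ref) ** 2) for c in coords) / len(coords)
            )
            assert abs(rms_distance_cv(coords, ref) - expect) < 1e-12

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(size=(6, 3)) * 3
        ref = rng.normal(size=3)
        base = rms_distance_cv(coords, ref)
        for _ in range(10):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(size=3) * 10
            assert np.isclose(
                rms_distance_cv(rot.apply(coords) + shift, rot.apply(ref) + shift),
                base,
            )

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(100):
            coords = rng.normal(size=(4, 3)) * 3
            ref = rng.normal(size=3)
            _, grad, _ = rms_distance_gradient(coords, ref)
            for i in range(4):
                for d in range(3):
                    cp = coords.copy()
                    cp[i, d] += h
                    cm = coords.copy()
                    cm[i, d] -= h
                    fd = (rms_distance_cv(cp, ref) - rms_distance_cv(cm, ref)) / (
                        2 * h
                    )
                    assert abs(grad[i, d] - fd) < 1e-6 * max(1.0, abs(fd))

    def test_gradient_zero_at_singular_origin(self):
        cv, grad, gref = rms_distance_gradient(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]], [1.0, 1.0, 1.0]
        )
        assert cv == 0.0
        assert np.all(grad == 0) and np.all(gref == 0)

    def test_single_atom_gradient_is_unit_vector(self):
        _, grad, _ = rms_distance_gradient([[2.0, 0.0, 0.0]], [0.0, 0.0, 0.0])
        assert np.allclose(grad, [[1.0, 0.0, 0.0]])

    def test_total_gradient_sums_to_zero_with_dynamic_reference(self, rng):
        # equal-and-opposite contract: ligand plus reference-atom gradients
        system = HostGuest3D()
        coords = system.initial_coords(rng) + rng.normal(size=(10, 3)) * 0.3
        for cv in system.default_cvs():
            _, grad = cv.gradient(coords)
            assert np.allclose(grad.sum(axis=0), 0.0, atol=1e-12)

    def test_dynamic_reference_gradient_finite_difference(self, rng):
        system = HostGuest3D()
        coords = system.initial_coords(rng) + rng.normal(size=(10, 3)) * 0.3
        cv = system.default_cvs()[0]
        _, grad = cv.gradient(coords)
        h = 1e-6
        for i in (0, 1, 4, 5, 6):  # ligand and reference atoms
            for d in range(3):
                cp = coords.copy()
                cp[i, d] += h
                cm = coords.copy()
                cm[i, d] -= h
                fd = (cv.value(cp) - cv.value(cm)) / (2 * h)
                assert abs(grad[i, d] - fd) < 1e-6 * max(1.0, abs(fd))

    def test_swap_symmetry_permutes_cv_pair(self, rng):
        # exchanging the two reference selections exchanges (CV1, CV2)
        # when the ligand groups are also swapped
        system = HostGuest3D()
        coords = system.initial_coords(rng) + rng.normal(size=(10, 3)) * 0.5
        ref1 = DynamicReference(AtomGroup(system.ref1_indices))
        ref2 = DynamicReference(AtomGroup(system.ref2_indices))
        g1 = AtomGroup(system.group1_indices)
        g2 = AtomGroup(system.group2_indices)
        cv12 = (RMSDistanceCV(g1, ref1), RMSDistanceCV(g2, ref2))
        cv21 = (RMSDistanceCV(g2, ref2), RMSDistanceCV(g1, ref1))
        a = [c.value(coords) for c in cv12]
        b = [c.value(coords) for c in cv21]
        assert a == b[::-1]


class TestDihedral:
    def test_planar_trans_is_pi(self):
        p = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        assert np.isclose(dihedral_cv(*p), np.pi)

    def test_planar_cis_is_zero(self):
        p = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]
        assert np.isclose(dihedral_cv(*p) % (2 * np.pi), 0.0)

    def test_range_is_wrapped(self, rng):
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 2
            try:
                phi = dihedral_cv(*p)
            except ValueError:
                continue
            assert 0.0 <= phi < 2 * np.pi

    def test_matches_independent_plane_angle_oracle(self, rng):
        # oracle: angle between the two bond planes via projections onto
        # the plane normal to the central bond (no cross-of-crosses)
        def oracle(p1, p2, p3, p4):
            b2 = p3 - p2
            b2 /= np.linalg.norm(b2)
            u = (p1 - p2) - np.dot(p1 - p2, b2) * b2
            v = (p4 - p3) - np.dot(p4 - p3, b2) * b2
            cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = np.arccos(np.clip(cos, -1, 1))
            if np.dot(np.cross(u, v), b2) < 0:
                ang = 2 * np.pi - ang
            return ang % (2 * np.pi)

        for _ in range(100):
            p = rng.normal(size=(4, 3)) * 2
            try:
                phi = dihedral_cv(*p)
            except ValueError:
                continue
            diff = (phi - oracle(*p)) % (2 * np.pi)
            assert min(diff, 2 * np.pi - diff) < 1e-10

    def test_collinear_geometry_raises(self):
        p = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        with pytest.raises(ValueError, match="collinear"):
            dihedral_cv(*p)

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        checked = 0
        while checked < 100:
            p = rng.normal(size=(4, 3)) * 2
            try:
                phi, grad = dihedral_gradient(*p)
            except ValueError:
                continue
            if min(phi, 2 * np.pi - phi) < 0.05:  # avoid the branch cut
                continue
            checked += 1
            for i in range(4):
                for d in range(3):
                    pp = p.copy()
                    pp[i, d] += h
                    pm = p.copy()
                    pm[i, d] -= h
                    a, b = dihedral_cv(*pp), dihedral_cv(*pm)
                    fd = ((a - b + np.pi) % (2 * np.pi) - np.pi) / (2 * h)
                    assert abs(grad[i, d] - fd) < 1e-5 * max(1.0, abs(fd))

    def test_dihedral_cv_object_gradient_shape(self, rng):
        coords = rng.normal(size=(6, 3))
        cv = DihedralCV(atoms=(0, 2, 3, 5))
        phi, grad = cv.gradient(coords)
        assert grad.shape == coords.shape
        assert np.all(grad[1] == 0) and np.all(grad[4] == 0)


class TestRestraints:
    def test_axis_normalized_and_validation(self):
        r = RestraintSet(cylinder_axis=(0.0, 0.0, 2.0))
        assert np.isclose(np.linalg.norm(r.cylinder_axis), 1.0)
        with pytest.raises(ValueError):
            RestraintSet(cylinder_axis=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            RestraintSet(cylinder_radius=-1.0)

    def test_zero_inside_flat_bottom(self):
        r = RestraintSet()  # radius 18, cap 22
        e, f, dcv = restraint_energy_force(
            [10.0, 0.0, 5.0], [15.0, 20.0], r, [0.0, 0.0, 0.0]
        )
        assert e == 0.0
        assert np.all(f == 0) and np.all(dcv == 0)

    def test_boundary_continuity(self):
        r = RestraintSet()
        e, f, dcv = restraint_energy_force(
            [18.0, 0.0, 3.0], [22.0, 22.0], r, [0.0, 0.0, 0.0]
        )
        assert e == 0.0 and np.all(f == 0) and np.all(dcv == 0)

    def test_radial_excess_closed_form(self):
        r = RestraintSet(cylinder_radius=18.0, k_cyl=10.0)
        e, f, _ = restraint_energy_force(
            [20.0, 0.0, -7.0], [5.0, 5.0], r, [0.0, 0.0, 0.0]
        )
        assert np.isclose(e, 0.5 * 10.0 * 2.0**2)  # 20 kcal/mol
        assert np.allclose(f, [-10.0 * 2.0, 0.0, 0.0])  # inward, radial only

    def test_cv_cap_term(self):
        r = RestraintSet(cv_cap=22.0, k_cap=10.0)
        e, _, dcv = restraint_energy_force(
            [0.0, 0.0, 0.0], [23.0, 21.0], r, [0.0, 0.0, 0.0]
        )
        assert np.isclose(e, 0.5 * 10.0 * 1.0)
        assert np.isclose(dcv[0], 10.0 * 1.0) and dcv[1] == 0.0

    def test_force_is_negative_gradient(self, rng):
        r = RestraintSet(cylinder_radius=3.0, k_cyl=7.0)
        h = 1e-6
        for _ in range(20):
            cog = rng.normal(size=3) * 5
            e0, f, _ = restraint_energy_force(cog, [1.0], r, np.zeros(3))
            for d in range(3):
                cp = cog.copy()
                cp[d] += h
                cm = cog.copy()
                cm[d] -= h
                ep = restraint_energy_force(cp, [1.0], r, np.zeros(3))[0]
                em = restraint_energy_force(cm, [1.0], r, np.zeros(3))[0]
                assert abs(f[d] + (ep - em) / (2 * h)) < 1e-5
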