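"""Dihedrals, Kabsch superposition and displacement measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from abiface.geometry import (
    GeometryError,
    backbone_dihedrals,
    dihedral,
    kabsch,
    kabsch_superpose,
    point_distance,
    ring_centroid,
)
from abiface.structure_io import SelectionSpec, select
from abiface.synthetic_data import FixtureSpec, build_backbone, build_fixture

from conftest import identity_pairing, random_rotation


def oracle_dihedral(p1, p2, p3, p4):
    """Independent formula: atan2 on the two plane normals projected onto a
    frame aligned with the central bond."""
    b1, b2, b3 = p1 - p2, p3 - p2, p4 - p3
    b2u = b2 / np.linalg.norm(b2)
    v = b1 - np.dot(b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    x = np.dot(v, w)
    y = np.dot(np.cross(b2u, v), w)
    return math.degrees(math.atan2(y, x))


class TestDihedral:
    def test_cis_is_zero(self):
        pts = map(np.array, ([0, 1, 0.0], [0, 0, 0], [1, 0, 0], [1, 1, 0]))
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        pts = map(np.array, ([0, 1, 0.0], [0, 0, 0], [1, 0, 0], [1, -1, 0]))
        assert dihedral(*pts) == pytest.approx(180.0)

    def test_matches_independent_formula_on_random_quadruples(self, rng):
        for _ in range(200):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            expected = oracle_dihedral(*pts)
            circular_diff = abs((ours - expected + 180.0) % 360.0 - 180.0)
            assert circular_diff < 1e-9

    def test_collinear_raises(self):
        pts = map(np.array, ([0, 0, 0.0], [1, 0, 0], [2, 0, 0], [3, 1, 0]))
        with pytest.raises(GeometryError):
            dihedral(*pts)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=3.0, size=(4, 3))
        try:
            base = dihedral(*pts)
        except GeometryError:
            return
        R = random_rotation(rng)
        t = rng.normal(scale=10.0, size=3)
        moved = pts @ R.T + t
        assert dihedral(*moved) == pytest.approx(base, abs=1e-6)


class TestBackboneDihedrals:
    def test_terminal_angles_absent(self):
        dsets = backbone_dihedrals(build_backbone([(-60, -45)] * 4), "A")
        assert dsets[0].phi is None and dsets[0].omega is None
        assert dsets[-1].psi is None

    @pytest.mark.parametrize("phi,psi", [(-60, -30), (-120, 130), (60, 30), (-90, 0)])
    def test_build_then_measure_round_trip(self, phi, psi):
        dsets = backbone_dihedrals(build_backbone([(phi, psi)] * 5), "A")
        for d in dsets[1:-1]:
            assert d.phi == pytest.approx(phi, abs=0.5)
            assert d.psi == pytest.approx(psi, abs=0.5)
            assert abs(d.omega) == pytest.approx(180.0, abs=1.0)

    def test_numbering_gap_breaks_consecutiveness(self):
        st1 = build_backbone([(-60, -45)] * 3, start_seq=1)
        st2 = build_backbone([(-60, -45)] * 3, start_seq=10)
        merged = st1
        merged.chains["A"] = st1.chains["A"] + st2.chains["A"]
        dsets = backbone_dihedrals(merged, "A")
        by_seq = {d.residue[1]: d for d in dsets}
        assert by_seq[10].phi is None  # no dihedral across the 3 -> 10 gap
        assert by_seq[3].psi is None


class TestKabsch:
    def test_identity_superposition(self):
        stq, _ = build_fixture(FixtureSpec("ideal_backbone"))
        res = kabsch_superpose(stq, stq, identity_pairing(stq))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        assert all(d == pytest.approx(0.0, abs=1e-9) for _, d in res.displacement_table)

    def test_recovers_known_transform(self):
        (mobile, reference), gt = build_fixture(
            FixtureSpec("perturbed_copy", {"angle": 37.0, "axis": (1, 2, 2),
                                           "translation": (5.0, -1.0, 2.0)})
        )
        res = kabsch_superpose(mobile, reference, identity_pairing(reference))
        R_applied = np.array(gt["rotation"])
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(res.rotation, R_applied.T, atol=1e-6)

    def test_agrees_with_scipy_rotation_fit(self, rng):
        X = rng.normal(size=(20, 3))
        R = random_rotation(rng)
        Y = X @ R.T + np.array([1.0, 2.0, 3.0]) + rng.normal(scale=0.1, size=(20, 3))
        R_ours, t_ours, rmsd_ours = kabsch(X, Y)
        rot, rssd = Rotation.align_vectors(Y - Y.mean(0), X - X.mean(0))
        np.testing.assert_allclose(R_ours, rot.as_matrix(), atol=1e-8)
        assert rmsd_ours == pytest.approx(rssd / math.sqrt(len(X)), abs=1e-8)

    def test_rmsd_symmetric_and_rotation_invariant(self, rng):
        X = rng.normal(size=(15, 3))
        Y = X + rng.normal(scale=0.5, size=(15, 3))
        _, _, fwd = kabsch(X, Y)
        _, _, rev = kabsch(Y, X)
        assert fwd == pytest.approx(rev, abs=1e-6)
        pre = X @ random_rotation(rng).T
        _, _, pre_rmsd = kabsch(pre, Y)
        assert pre_rmsd == pytest.approx(fwd, abs=1e-6)

    def test_never_returns_reflection_for_near_planar_sets(self, rng):
        for _ in range(20):
            X = rng.normal(size=(10, 3))
            X[:, 2] *= 1e-6  # nearly planar
            Y = rng.normal(size=(10, 3))
            R, _, _ = kabsch(X, Y)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-6)

    def test_rmsd_bounded_by_max_displacement(self, rng):
        stq, _ = build_fixture(FixtureSpec("ideal_backbone"))
        noisy = stq.transformed(np.eye(3), np.zeros(3))
        for res in noisy.residues():
            res.atoms = [
                type(a)(a.serial, a.name, a.element, a.altloc, a.occupancy,
                        a.coords + rng.normal(scale=0.3, size=3), a.is_hetero, a.bfactor)
                for a in res.atoms
            ]
        fit = kabsch_superpose(noisy, stq, identity_pairing(stq))
        assert fit.rmsd <= max(d for _, d in fit.displacement_table) + 1e-9

    def test_too_few_pairs_raises(self):
        stq, _ = build_fixture(FixtureSpec("ideal_backbone"))
        with pytest.raises(GeometryError):
            kabsch_superpose(stq, stq, identity_pairing(stq)[:2])


class TestDistances:
    def test_three_four_five(self):
        stq, _ = build_fixture(FixtureSpec("sphere_pair", {"distance": 5.0}))
        key1 = ("A", 1, "", "C1")
        key2 = ("A", 1, "", "C2")
        assert point_distance(stq, key1, key2) == pytest.approx(5.0)

    def test_missing_atom_raises(self):
        stq, _ = build_fixture(FixtureSpec("sphere_pair"))
        with pytest.raises(GeometryError):
            point_distance(stq, ("A", 1, "", "C1"), ("A", 1, "", "ZZ"))

    def test_ring_centroid_of_hexagon_is_center(self):
        stq, _ = build_fixture(FixtureSpec("cation_pi_pair", {"distance": 4.0}))
        c = ring_centroid(stq, "B", 1)
        np.testing.assert_allclose(c, [0.0, 0.0, 0.0], atol=1e-9)
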