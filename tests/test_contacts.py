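"""Contact detectors against constructed ground truths and invariances."""

import numpy as np
import pytest

from abiface.contacts import (
    ContactInventory,
    contact_diff,
    find_cation_pi,
    find_disulfides,
    find_hbonds,
    find_salt_bridges,
    find_water_bridges,
)
from abiface.structure_io import Atom, Residue, SelectionSpec, Structure
from abiface.synthetic_data import FixtureSpec, build_fixture

from conftest import random_rotation

GROUP_A = SelectionSpec(chain_ids=frozenset({"A"}))
GROUP_B = SelectionSpec(chain_ids=frozenset({"B"}))


def residue_with(chain, seq, name, atom_specs):
    atoms = [Atom(i + 1, n, el, "", 1.0, np.asarray(c, float))
             for i, (n, el, c) in enumerate(atom_specs)]
    return Residue(chain, seq, "", name, atoms)


class TestHbonds:
    def test_far_apart_atoms_give_empty_list(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair", {"distance": 10.0}))
        assert find_hbonds(st, GROUP_A, GROUP_B) == []

    def test_ideal_pair_detected_with_constructed_geometry(self):
        st, gt = build_fixture(FixtureSpec("hbond_pair", {"distance": 2.9, "angle": 165.0}))
        (c,) = find_hbonds(st, GROUP_A, GROUP_B)
        expected = gt["contacts"][0]
        assert c.kind == "hbond"
        assert c.partner_a == tuple(expected["partner_a"])
        assert c.partner_b == tuple(expected["partner_b"])
        assert c.distance == pytest.approx(expected["distance"], abs=1e-9)
        assert c.angle == pytest.approx(expected["angle"], abs=1e-6)

    def test_bent_donor_geometry_rejected(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair", {"distance": 2.9, "angle": 60.0}))
        assert find_hbonds(st, GROUP_A, GROUP_B) == []

    def test_symmetric_under_group_swap(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair"))
        fwd = find_hbonds(st, GROUP_A, GROUP_B)
        rev = find_hbonds(st, GROUP_B, GROUP_A)
        assert {frozenset({c.partner_a, c.partner_b}) for c in fwd} == {
            frozenset({c.partner_a, c.partner_b}) for c in rev
        }

    def test_count_monotone_in_cutoff(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair", {"distance": 3.2}))
        counts = [len(find_hbonds(st, GROUP_A, GROUP_B, d_max=d))
                  for d in (2.0, 3.0, 3.3, 4.0)]
        assert counts == sorted(counts)


class TestSaltBridges:
    def _asp(self, chain="A", x=0.0):
        return residue_with(chain, 1, "ASP", [
            ("CG", "C", (x - 1.2, 0, 0)), ("OD1", "O", (x, 0, 0)), ("OD2", "O", (x - 1.0, 1.0, 0)),
        ])

    def _arg(self, chain="B", x=3.0):
        return residue_with(chain, 1, "ARG", [
            ("CZ", "C", (x + 1.2, 0, 0)), ("NH1", "N", (x, 0, 0)),
            ("NH2", "N", (x + 2.0, 1.0, 0)), ("NE", "N", (x + 2.0, -1.0, 0)),
        ])

    def test_asp_arg_pair_detected(self):
        st = Structure(chains={"A": [self._asp()], "B": [self._arg(x=3.0)]})
        contacts = find_salt_bridges(st, GROUP_A, GROUP_B)
        pairs = {(c.partner_a[3], c.partner_b[3]) for c in contacts}
        assert ("OD1", "NH1") in pairs or ("NH1", "OD1") in pairs
        assert min(c.distance for c in contacts) == pytest.approx(3.0)

    def test_like_charges_do_not_pair(self):
        st = Structure(chains={"A": [self._asp("A", 0.0)], "B": [self._asp("B", 3.0)]})
        assert find_salt_bridges(st, GROUP_A, GROUP_B) == []

    def test_his_positive_flag(self):
        his = residue_with("B", 1, "HIS", [("ND1", "N", (3.0, 0, 0))])
        st = Structure(chains={"A": [self._asp()], "B": [his]})
        assert len(find_salt_bridges(st, GROUP_A, GROUP_B, his_positive=True)) == 1
        assert find_salt_bridges(st, GROUP_A, GROUP_B, his_positive=False) == []


class TestCationPi:
    def test_fixture_ground_truth(self):
        st, gt = build_fixture(FixtureSpec("cation_pi_pair", {"distance": 4.0}))
        (c,) = find_cation_pi(st, GROUP_A, GROUP_B)
        expected = gt["contacts"][0]
        assert (c.kind, c.partner_a, c.partner_b) == (
            "cation_pi", tuple(expected["partner_a"]), tuple(expected["partner_b"])
        )
        assert c.distance == pytest.approx(4.0, abs=1e-9)

    def test_beyond_cutoff_empty(self):
        st, _ = build_fixture(FixtureSpec("cation_pi_pair", {"distance": 8.0}))
        assert find_cation_pi(st, GROUP_A, GROUP_B) == []

    def test_incomplete_ring_skipped_with_warning(self):
        st, _ = build_fixture(FixtureSpec("cation_pi_pair", {"distance": 4.0}))
        ring = st.chains["B"][0]
        ring.atoms = ring.atoms[:-1]  # drop one ring atom
        with pytest.warns(UserWarning, match="incomplete"):
            assert find_cation_pi(st, GROUP_A, GROUP_B) == []


class TestWaterBridges:
    def test_fixture_bridge_detected(self):
        st, gt = build_fixture(FixtureSpec("water_bridge", {"distance": 2.8}))
        (c,) = find_water_bridges(st, GROUP_A, GROUP_B)
        expected = gt["contacts"][0]
        assert c.water == tuple(expected["water"])
        assert {c.partner_a, c.partner_b} == {
            tuple(expected["partner_a"]), tuple(expected["partner_b"])
        }
        assert c.distance == pytest.approx(2.8, abs=1e-9)

    def test_one_sided_water_is_not_a_bridge(self):
        st, _ = build_fixture(FixtureSpec("water_bridge", {"distance": 2.8}))
        st.chains["B"][0].atoms = [
            Atom(a.serial, a.name, a.element, a.altloc, a.occupancy,
                 a.coords + np.array([20.0, 0, 0]), a.is_hetero, a.bfactor)
            for a in st.chains["B"][0].atoms
        ]
        assert find_water_bridges(st, GROUP_A, GROUP_B) == []

    def test_no_waters_warns_and_returns_empty(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair"))
        with pytest.warns(UserWarning, match="no waters"):
            assert find_water_bridges(st, GROUP_A, GROUP_B) == []


class TestDisulfides:
    def _cys_pair(self, d):
        a = residue_with("A", 1, "CYS", [("SG", "S", (0, 0, 0))])
        b = residue_with("A", 2, "CYS", [("SG", "S", (d, 0, 0))])
        return Structure(chains={"A": [a, b]})

    def test_bonded_pair(self):
        (c,) = find_disulfides(self._cys_pair(2.05))
        assert c.kind == "disulfide" and c.distance == pytest.approx(2.05)

    def test_distant_pair_empty(self):
        assert find_disulfides(self._cys_pair(4.0)) == []


class TestInvariances:
    @pytest.mark.parametrize("kind,finder", [
        ("hbond_pair", find_hbonds),
        ("cation_pi_pair", find_cation_pi),
        ("water_bridge", find_water_bridges),
    ])
    def test_rigid_transform_invariance(self, kind, finder, rng):
        st, _ = build_fixture(FixtureSpec(kind))
        base = finder(st, GROUP_A, GROUP_B)
        moved = st.transformed(random_rotation(rng), rng.normal(scale=20.0, size=3))
        after = finder(moved, GROUP_A, GROUP_B)
        assert [(c.partner_a, c.partner_b) for c in base] == [
            (c.partner_a, c.partner_b) for c in after
        ]
        for c0, c1 in zip(base, after):
            assert c1.distance == pytest.approx(c0.distance, abs=1e-9)

    def test_brute_force_and_grid_scan_agree(self, rng):
        # random polar soup across two chains
        residues_a, residues_b = [], []
        for i in range(25):
            xyz = rng.normal(scale=6.0, size=3)
            residues_a.append(residue_with("A", i + 1, "SER",
                                           [("CB", "C", xyz + [1.4, 0, 0]), ("OG", "O", xyz)]))
            xyz = rng.normal(scale=6.0, size=3)
            residues_b.append(residue_with("B", i + 1, "SER",
                                           [("CB", "C", xyz + [1.4, 0, 0]), ("OG", "O", xyz)]))
        st = Structure(chains={"A": residues_a, "B": residues_b})
        grid = find_hbonds(st, GROUP_A, GROUP_B, method="grid")
        brute = find_hbonds(st, GROUP_A, GROUP_B, method="brute")
        assert [(c.partner_a, c.partner_b, c.distance) for c in grid] == [
            (c.partner_a, c.partner_b, c.distance) for c in brute
        ]


class TestContactDiff:
    def test_identical_inventories_diff_empty(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair"))
        contacts = find_hbonds(st, GROUP_A, GROUP_B)
        diff = contact_diff(contacts, list(contacts))
        assert diff.lost == [] and diff.gained == []
        assert len(diff.retained) == 1

    def test_removed_contact_reported_lost(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair"))
        contacts = find_hbonds(st, GROUP_A, GROUP_B)
        diff = contact_diff(contacts, [])
        assert diff.lost == contacts and diff.gained == []

    def test_mismatched_fingerprints_rejected(self):
        inv_a = ContactInventory([], {"hbond_d_max": 3.5})
        inv_b = ContactInventory([], {"hbond_d_max": 3.2})
        with pytest.raises(ValueError, match="different parameters"):
            contact_diff(inv_a, inv_b)

    def test_retained_contacts_annotated_with_distance_change(self):
        st, _ = build_fixture(FixtureSpec("hbond_pair", {"distance": 2.9}))
        st2, _ = build_fixture(FixtureSpec("hbond_pair", {"distance": 3.1}))
        diff = contact_diff(find_hbonds(st, GROUP_A, GROUP_B),
                            find_hbonds(st2, GROUP_A, GROUP_B))
        ((_, _, delta),) = diff.retained
        assert delta == pytest.approx(0.2, abs=1e-9)
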