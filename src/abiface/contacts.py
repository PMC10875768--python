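"""Geometric contact detection between atom groups.

Detectors cover hydrogen bonds, salt bridges, cation-pi pairs,
water-mediated bridges and disulfides, using heavy-atom criteria only --
crystal structures at ~2.4 Angstrom carry no hydrogens, so a hydrogen bond
is declared from donor/acceptor chemistry, a distance cutoff, and (when the
donor's covalent antecedent is present) the antecedent-donor-acceptor angle.

All detectors are purely geometric and therefore invariant under rigid-body
motion of the whole structure.  A brute-force O(n^2) scan and a KD-tree
accelerated scan are both provided; they return identical contact sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

from .geometry import AROMATIC_RING_ATOMS, TRP_5RING, angle
from .structure_io import Atom, AtomKey, Residue, ResidueKey, SelectionSpec, Structure

__all__ = [
    "Contact",
    "ContactInventory",
    "ContactDiff",
    "find_hbonds",
    "find_salt_bridges",
    "find_cation_pi",
    "find_water_bridges",
    "find_disulfides",
    "contact_diff",
]

# -- polar-atom chemistry ----------------------------------------------------
# donor heavy atom -> covalent antecedent used for the angle test
_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "HIS": {"ND1": "CG", "NE2": "CE1"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "TRP": {"NE1": "CD1"},
}

_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

_POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),  # pH-dependent; see his_positive flag
}
_NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class Contact:
    kind: Literal["hbond", "salt_bridge", "cation_pi", "water_bridge", "disulfide"]
    partner_a: AtomKey
    partner_b: AtomKey
    distance: float
    angle: float | None = None
    water: ResidueKey | None = None

    @property
    def residue_pair(self) -> frozenset[ResidueKey]:
        return frozenset({self.partner_a[:3], self.partner_b[:3]})

    @property
    def identity(self) -> tuple:
        """Match key for diffs: kind + unordered (residue, atom-name) pair."""
        ends = frozenset({(self.partner_a[:3], self.partner_a[3]),
                          (self.partner_b[:3], self.partner_b[3])})
        return (self.kind, ends, self.water)


@dataclass
class ContactInventory:
    """A contact list plus the parameter fingerprint it was produced under."""

    contacts: list[Contact]
    params: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.contacts)

    def __len__(self):
        return len(self.contacts)


def _group_atoms(structure: Structure, spec: SelectionSpec):
    """(residue, atom) pairs matching the selection, heavy atoms only."""
    out: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        if not spec.matches_residue(res):
            continue
        for a in res.atoms:
            if not a.is_hydrogen and spec.matches_atom(res, a):
                out.append((res, a))
    return out


def _akey(res: Residue, atom: Atom) -> AtomKey:
    return (res.chain_id, res.seq_num, res.icode, atom.name)


def _near_pairs(pts_a: np.ndarray, pts_b: np.ndarray, cutoff: float,
                method: str = "grid") -> Iterable[tuple[int, int]]:
    """Index pairs (i, j) with |a_i - b_j| <= cutoff."""
    if len(pts_a) == 0 or len(pts_b) == 0:
        return []
    if method == "brute":
        d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(axis=2)
        ii, jj = np.nonzero(d2 <= cutoff**2)
        return list(zip(ii.tolist(), jj.tolist()))
    tree = cKDTree(pts_b)
    pairs = []
    for i, hits in enumerate(cKDTree(pts_a).query_ball_tree(tree, cutoff)):
        pairs.extend((i, j) for j in hits)
    return pairs


def _donors(res: Residue) -> list[tuple[Atom, Atom | None]]:
    """(donor, antecedent) heavy-atom pairs for one residue."""
    out = []
    if res.is_water:
        o = res.atom("O")
        if o is not None:
            out.append((o, None))
        return out
    n = res.atom("N")
    if n is not None and res.res_name != "PRO":
        out.append((n, res.atom("CA")))
    for donor_name, ante_name in _SIDECHAIN_DONORS.get(res.res_name, {}).items():
        d = res.atom(donor_name)
        if d is not None:
            out.append((d, res.atom(ante_name)))
    return out


def _acceptors(res: Residue) -> list[Atom]:
    if res.is_water:
        o = res.atom("O")
        return [o] if o is not None else []
    out = []
    for name in ("O", "OXT"):
        a = res.atom(name)
        if a is not None:
            out.append(a)
    for name in _SIDECHAIN_ACCEPTORS.get(res.res_name, ()):
        a = res.atom(name)
        if a is not None:
            out.append(a)
    return out


def _sorted_contacts(found: dict[tuple, Contact]) -> list[Contact]:
    return sorted(found.values(), key=lambda c: (c.distance, c.partner_a, c.partner_b))


def find_hbonds(
    structure: Structure,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    d_max: float = 3.5,
    angle_min: float = 90.0,
    method: str = "grid",
) -> list[Contact]:
    """Hydrogen bonds between two groups (heavy-atom criteria).

    A donor-acceptor pair qualifies when the heavy-atom distance is at most
    ``d_max`` and, if the donor's antecedent atom is present, the
    antecedent-donor-acceptor angle is at least ``angle_min`` degrees.  The
    same atom pair is reported once even if it qualifies in both donor
    directions; the result is symmetric under swapping the groups.
    """
    atoms_a = _group_atoms(structure, group_a)
    atoms_b = _group_atoms(structure, group_b)
    found: dict[tuple, Contact] = {}
    for (side_a, side_b, flip) in ((atoms_a, atoms_b, False), (atoms_b, atoms_a, True)):
        donors = [(res, d, ante) for res, _ in _unique_residues(side_a) for d, ante in _donors(res)]
        acceptors = [(res, a) for res, _ in _unique_residues(side_b) for a in _acceptors(res)]
        if not donors or not acceptors:
            continue
        pts_d = np.array([d.coords for _, d, _ in donors])
        pts_a = np.array([a.coords for _, a in acceptors])
        for i, j in _near_pairs(pts_d, pts_a, d_max, method):
            res_d, donor, ante = donors[i]
            res_a, acceptor = acceptors[j]
            if res_d.key == res_a.key:
                continue
            dist = float(np.linalg.norm(donor.coords - acceptor.coords))
            if dist <= 0:
                continue
            theta = None
            if ante is not None:
                theta = angle(ante.coords, donor.coords, acceptor.coords)
                if theta < angle_min:
                    continue
            ka, kb = _akey(res_d, donor), _akey(res_a, acceptor)
            if flip:
                ka, kb = kb, ka
            ident = frozenset({ka, kb})
            if ident not in found or (theta is not None and found[ident].angle is None):
                found[ident] = Contact("hbond", ka, kb, dist, theta)
    return _sorted_contacts(found)


def _unique_residues(atoms: list[tuple[Residue, Atom]]) -> list[tuple[Residue, None]]:
    seen: dict[ResidueKey, Residue] = {}
    for res, _ in atoms:
        seen.setdefault(res.key, res)
    return [(r, None) for r in seen.values()]


def find_salt_bridges(
    structure: Structure,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    d_max: float = 4.0,
    his_positive: bool = True,
    method: str = "grid",
) -> list[Contact]:
    """Oppositely charged heavy-atom pairs within ``d_max``.

    Positive: Arg NH1/NH2/NE, Lys NZ, and His ND1/NE2 when ``his_positive``
    (structures solved at acidic pH).  Negative: Asp OD1/OD2, Glu OE1/OE2,
    and any C-terminal OXT.
    """

    def charged(side: list[tuple[Residue, Atom]], sign: int):
        out = []
        for res, _ in _unique_residues(side):
            pos_names = _POSITIVE_ATOMS.get(res.res_name, ())
            if res.res_name == "HIS" and not his_positive:
                pos_names = ()
            names = pos_names if sign > 0 else _NEGATIVE_ATOMS.get(res.res_name, ())
            for name in names:
                a = res.atom(name)
                if a is not None:
                    out.append((res, a))
            if sign < 0:
                oxt = res.atom("OXT")
                if oxt is not None:
                    out.append((res, oxt))
        return out

    atoms_a = _group_atoms(structure, group_a)
    atoms_b = _group_atoms(structure, group_b)
    found: dict[tuple, Contact] = {}
    for sign in (+1, -1):
        pos = charged(atoms_a, sign)
        neg = charged(atoms_b, -sign)
        if not pos or not neg:
            continue
        pa = np.array([a.coords for _, a in pos])
        pb = np.array([a.coords for _, a in neg])
        for i, j in _near_pairs(pa, pb, d_max, method):
            res_p, ap = pos[i]
            res_n, an = neg[j]
            if res_p.key == res_n.key:
                continue
            dist = float(np.linalg.norm(ap.coords - an.coords))
            ka, kb = _akey(res_p, ap), _akey(res_n, an)
            found[frozenset({ka, kb})] = Contact("salt_bridge", ka, kb, dist)
    return _sorted_contacts(found)


def _cations(side: list[tuple[Residue, Atom]]):
    """(key, point) cationic-group centers: Arg guanidinium centroid, Lys NZ."""
    out = []
    for res, _ in _unique_residues(side):
        if res.res_name == "ARG":
            pts = [res.atom(n) for n in ("CZ", "NH1", "NH2", "NE")]
            if all(p is not None for p in pts):
                center = np.mean([p.coords for p in pts], axis=0)
                out.append(((res.chain_id, res.seq_num, res.icode, "guanidinium"), center))
        elif res.res_name == "LYS":
            nz = res.atom("NZ")
            if nz is not None:
                out.append((_akey(res, nz), nz.coords))
    return out


def _rings(side: list[tuple[Residue, Atom]]):
    out = []
    for res, _ in _unique_residues(side):
        ring_sets = []
        if res.res_name in ("PHE", "TYR", "HIS"):
            ring_sets.append(("ring", AROMATIC_RING_ATOMS[res.res_name]))
        elif res.res_name == "TRP":
            ring_sets.append(("ring6", AROMATIC_RING_ATOMS["TRP"]))
            ring_sets.append(("ring5", TRP_5RING))
        for label, names in ring_sets:
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                warnings.warn(f"incomplete aromatic ring in {res.res_name} {res.key}; skipped",
                              stacklevel=3)
                continue
            center = np.mean([a.coords for a in atoms], axis=0)
            out.append(((res.chain_id, res.seq_num, res.icode, label), center))
    return out


def find_cation_pi(
    structure: Structure,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    d_max: float = 6.0,
    method: str = "grid",
) -> list[Contact]:
    """Cation-to-aromatic-ring-centroid pairs within ``d_max`` Angstrom."""
    atoms_a = _group_atoms(structure, group_a)
    atoms_b = _group_atoms(structure, group_b)
    found: dict[tuple, Contact] = {}
    for side_c, side_r, flip in ((atoms_a, atoms_b, False), (atoms_b, atoms_a, True)):
        cations = _cations(side_c)
        rings = _rings(side_r)
        if not cations or not rings:
            continue
        pc = np.array([p for _, p in cations])
        pr = np.array([p for _, p in rings])
        for i, j in _near_pairs(pc, pr, d_max, method):
            kc, cpt = cations[i]
            kr, rpt = rings[j]
            if kc[:3] == kr[:3]:
                continue
            dist = float(np.linalg.norm(cpt - rpt))
            ka, kb = (kr, kc) if flip else (kc, kr)
            found[frozenset({kc, kr})] = Contact("cation_pi", ka, kb, dist)
    return _sorted_contacts(found)


def find_water_bridges(
    structure: Structure,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    d_max: float = 3.5,
    method: str = "grid",
) -> list[Contact]:
    """Water-mediated bridges: a water oxygen simultaneously hydrogen-bond
    close (<= ``d_max`` per leg) to a polar atom in each group yields one
    contact per bridged protein-atom pair.  ``distance`` is the longer leg.
    """
    waters = [res for res in structure.residues() if res.is_water and res.atom("O") is not None]
    if not waters:
        warnings.warn("structure contains no waters; no bridges detectable", stacklevel=2)
        return []

    def polar(side):
        out = {}
        for res, _ in _unique_residues(side):
            if res.is_water:
                continue
            for d, _ante in _donors(res):
                out[_akey(res, d)] = d.coords
            for a in _acceptors(res):
                out[_akey(res, a)] = a.coords
        return list(out.items())

    polar_a = polar(_group_atoms(structure, group_a))
    polar_b = polar(_group_atoms(structure, group_b))
    if not polar_a or not polar_b:
        return []
    found: dict[tuple, Contact] = {}
    for wat in waters:
        w = wat.atom("O").coords
        # legs measured from the water oxygen
        legs_a = [(k, float(np.linalg.norm(w - p))) for k, p in polar_a
                  if np.linalg.norm(w - p) <= d_max]
        legs_b = [(k, float(np.linalg.norm(w - p))) for k, p in polar_b
                  if np.linalg.norm(w - p) <= d_max]
        for ka, da in legs_a:
            for kb, db in legs_b:
                if ka[:3] == kb[:3]:
                    continue
                found[(frozenset({ka, kb}), wat.key)] = Contact(
                    "water_bridge", ka, kb, max(da, db), water=wat.key
                )
    return _sorted_contacts(found)


def find_disulfides(structure: Structure, d_max: float = 2.5) -> list[Contact]:
    """Cystine SG-SG pairs within ``d_max`` (default 2.5 Angstrom)."""
    sgs = []
    for res in structure.residues():
        if res.res_name == "CYS":
            sg = res.atom("SG")
            if sg is not None:
                sgs.append((res, sg))
    found: dict[tuple, Contact] = {}
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1].coords - sgs[j][1].coords))
            if 0 < d <= d_max:
                ka, kb = _akey(*sgs[i]), _akey(*sgs[j])
                found[frozenset({ka, kb})] = Contact("disulfide", ka, kb, d)
    return _sorted_contacts(found)


@dataclass
class ContactDiff:
    lost: list[Contact]
    gained: list[Contact]
    retained: list[tuple[Contact, Contact, float]]  # (in A, in B, delta distance)

    @property
    def counts(self) -> dict[str, int]:
        return {"lost": len(self.lost), "gained": len(self.gained),
                "retained": len(self.retained)}


def contact_diff(
    contacts_a: list[Contact] | ContactInventory,
    contacts_b: list[Contact] | ContactInventory,
    match_rule: str = "atom_pair",
) -> ContactDiff:
    """Difference of two contact inventories produced under the same
    parameters.

    Contacts are matched by identity (kind + unordered residue/atom-name
    pairs), deliberately ignoring distance: a bond that lengthened counts
    as lost only if it fell out of the inventory in B.
    """
    if match_rule != "atom_pair":
        raise ValueError(f"unknown match rule {match_rule!r}")
    if isinstance(contacts_a, ContactInventory) and isinstance(contacts_b, ContactInventory):
        if contacts_a.params != contacts_b.params:
            raise ValueError(
                "contact inventories were produced under different parameters: "
                f"{contacts_a.params} vs {contacts_b.params}"
            )
    list_a = list(contacts_a)
    list_b = list(contacts_b)
    index_b = {c.identity: c for c in list_b}
    index_a = {c.identity: c for c in list_a}
    lost = [c for c in list_a if c.identity not in index_b]
    gained = [c for c in list_b if c.identity not in index_a]
    retained = [
        (c, index_b[c.identity], index_b[c.identity].distance - c.distance)
        for c in list_a
        if c.identity in index_b
    ]
    return ContactDiff(lost, gained, retained)
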