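"""Coordinate and sequence fixtures with analytically known properties.

Each fixture is a small :class:`~abiface.structure_io.Structure` built from
construction parameters, paired with a machine-readable ground-truth record
computed by construction arithmetic (closed forms, placed distances, the
requested transform) -- never by the analysis code under test.  Backbones
are grown by natural-extension-of-reference-frame placement from ideal bond
lengths and angles, so requested (phi, psi, omega) are reproduced to within
a small fraction of a degree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .structure_io import Atom, Residue, Structure, write_pdb

__all__ = ["FixtureSpec", "build_backbone", "build_fixture", "materialize_suite"]

# ideal peptide geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |cd| = length, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion (degrees, IUPAC sign)."""
    theta = math.radians(bond_angle)
    chi = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(theta),
        length * math.sin(theta) * math.cos(chi),
        length * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _mkatom(name: str, element: str, coords, serial: int = 1, hetero: bool = False) -> Atom:
    return Atom(serial=serial, name=name, element=element, altloc="",
                occupancy=1.0, coords=np.asarray(coords, float), is_hetero=hetero)


def build_backbone(
    phi_psi_list: list[tuple[float, float]],
    omega: float = 180.0,
    chain_id: str = "A",
    res_name: str = "ALA",
    start_seq: int = 1,
) -> Structure:
    """Poly-alanine backbone (N, CA, C, O) at the requested torsions.

    ``phi_psi_list[i]`` supplies (phi, psi) for residue i; the first phi is
    geometrically unused and the last psi only orients the terminal carbonyl.
    """
    if len(phi_psi_list) < 2:
        raise ValueError("need at least 2 residues")
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, len(phi_psi_list)):
        prev = coords[i - 1]
        psi_prev = phi_psi_list[i - 1][1]
        phi_i = phi_psi_list[i][0]
        n_i = _place(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = _place(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = _place(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: anti to the next amide nitrogen (or to psi for the C-terminus)
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            torsion = None  # place O anti to N(i+1) in the peptide plane
            o_i = _place(coords[i + 1]["N"], res["CA"], res["C"], BOND_C_O,
                         ANGLE_CA_C_O, 180.0)
        else:
            psi = phi_psi_list[i][1]
            o_i = _place(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res["O"] = o_i

    residues = []
    serial = 0
    for i, res in enumerate(coords):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            serial += 1
            element = "N" if name == "N" else ("O" if name == "O" else "C")
            atoms.append(_mkatom(name, element, res[name], serial))
        residues.append(Residue(chain_id, start_seq + i, "", res_name, atoms))
    return Structure(id="backbone", chains={chain_id: residues})


# ---------------------------------------------------------------------------
# fixture kinds

def _fx_single_atom(p: dict, rng) -> tuple[Structure, dict]:
    element = p.get("element", "C")
    radius = float(p.get("radius", 1.70))
    probe = float(p.get("probe_radius", 1.4))
    res = Residue("A", 1, "", "UNK", [_mkatom(element, element, (0, 0, 0))])
    gt = {
        "sasa_total": 4.0 * math.pi * (radius + probe) ** 2,
        "radius": radius,
        "probe_radius": probe,
    }
    return Structure(id="single_atom", chains={"A": [res]}), gt


def _two_sphere_sasa(r1: float, r2: float, d: float) -> tuple[float, float]:
    """Closed-form accessible areas of two spheres (radii already expanded)."""
    if d >= r1 + r2:
        return 4 * math.pi * r1**2, 4 * math.pi * r2**2

    def accessible(ra, rb):
        if d + ra <= rb:
            return 0.0  # fully engulfed
        x = (d * d + ra * ra - rb * rb) / (2 * d)
        cap_h = ra - x
        return 4 * math.pi * ra**2 - 2 * math.pi * ra * cap_h

    return accessible(r1, r2), accessible(r2, r1)


def _fx_sphere_pair(p: dict, rng) -> tuple[Structure, dict]:
    r1 = float(p.get("radius_a", 1.70))
    r2 = float(p.get("radius_b", 1.70))
    d = float(p.get("distance", 3.0))
    probe = float(p.get("probe_radius", 1.4))
    res = Residue("A", 1, "", "UNK", [
        _mkatom("C1", "C", (0, 0, 0), 1),
        _mkatom("C2", "C", (d, 0, 0), 2),
    ])
    a1, a2 = _two_sphere_sasa(r1 + probe, r2 + probe, d)
    gt = {"sasa_per_atom": [a1, a2], "sasa_total": a1 + a2,
          "radii": [r1, r2], "probe_radius": probe, "distance": d}
    return Structure(id="sphere_pair", chains={"A": [res]}), gt


def _fx_hbond_pair(p: dict, rng) -> tuple[Structure, dict]:
    d = float(p.get("distance", 2.9))
    theta = float(p.get("angle", 165.0))
    # donor N at origin with antecedent CA at the requested angle to the acceptor
    n = np.zeros(3)
    o = np.array([d, 0.0, 0.0])
    t = math.radians(theta)
    ca = BOND_N_CA * np.array([math.cos(t), math.sin(t), 0.0])
    donor = Residue("A", 1, "", "ALA", [_mkatom("N", "N", n, 1), _mkatom("CA", "C", ca, 2)])
    c = o + np.array([BOND_C_O, 0.0, 0.0])
    acceptor = Residue("B", 1, "", "ALA", [_mkatom("C", "C", c, 3), _mkatom("O", "O", o, 4)])
    st = Structure(id="hbond_pair", chains={"A": [donor], "B": [acceptor]})
    gt = {"contacts": [{"kind": "hbond", "distance": d, "angle": theta,
                        "partner_a": ["A", 1, "", "N"], "partner_b": ["B", 1, "", "O"]}]}
    return st, gt


def _phe_ring(center: np.ndarray, chain_id: str, seq: int, serial0: int) -> Residue:
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = []
    for k, name in enumerate(names):
        ang = math.radians(60.0 * k)
        pos = center + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
        atoms.append(_mkatom(name, "C", pos, serial0 + k))
    return Residue(chain_id, seq, "", "PHE", atoms)


def _fx_cation_pi_pair(p: dict, rng) -> tuple[Structure, dict]:
    d = float(p.get("distance", 4.0))
    ring = _phe_ring(np.zeros(3), "B", 1, 10)
    nz = _mkatom("NZ", "N", (0.0, 0.0, d), 1)
    lys = Residue("A", 1, "", "LYS", [nz])
    st = Structure(id="cation_pi_pair", chains={"A": [lys], "B": [ring]})
    gt = {"contacts": [{"kind": "cation_pi", "distance": d,
                        "partner_a": ["A", 1, "", "NZ"], "partner_b": ["B", 1, "", "ring"]}]}
    return st, gt


def _fx_water_bridge(p: dict, rng) -> tuple[Structure, dict]:
    d = float(p.get("distance", 2.8))
    # acceptor O in chain A and donor N in chain B, water equidistant between
    half = d * math.cos(math.radians(30.0))
    h = d * math.sin(math.radians(30.0))
    o = _mkatom("O", "O", (-half, 0.0, 0.0), 1)
    c = _mkatom("C", "C", (-half - BOND_C_O, 0.0, 0.0), 2)
    res_a = Residue("A", 1, "", "ALA", [c, o])
    n = _mkatom("N", "N", (half, 0.0, 0.0), 3)
    ca = _mkatom("CA", "C", (half + BOND_N_CA, 0.0, 0.0), 4)
    res_b = Residue("B", 1, "", "ALA", [n, ca])
    wat = Residue("W", 1, "", "HOH", [_mkatom("O", "O", (0.0, h, 0.0), 5, hetero=True)])
    st = Structure(id="water_bridge", chains={"A": [res_a], "B": [res_b], "W": [wat]})
    gt = {"contacts": [{"kind": "water_bridge", "distance": d, "water": ["W", 1, ""],
                        "partner_a": ["A", 1, "", "O"], "partner_b": ["B", 1, "", "N"]}]}
    return st, gt


def _fx_ideal_backbone(p: dict, rng) -> tuple[Structure, dict]:
    phi_psi = [tuple(x) for x in p.get("phi_psi", [(-60.0, -45.0)] * 6)]
    omega = float(p.get("omega", 180.0))
    st = build_backbone(phi_psi, omega)
    gt = {"phi_psi": [list(x) for x in phi_psi], "omega": omega}
    return st, gt


def _fx_ideal_turn(p: dict, rng) -> tuple[Structure, dict]:
    phi1, psi1, phi2, psi2 = p.get("angles", (-60.0, -30.0, -90.0, 0.0))
    turn_type = p.get("turn_type", "I")
    phi_psi = [(-120.0, 130.0), (phi1, psi1), (phi2, psi2), (-120.0, 130.0)]
    st = build_backbone(phi_psi)
    gt = {"turn_type": turn_type, "angles": [phi1, psi1, phi2, psi2],
          "residues": [1, 2, 3, 4]}
    return st, gt


def _fx_ideal_hairpin(p: dict, rng) -> tuple[Structure, dict]:
    d = float(p.get("distance", 2.9))
    span = 3.3  # N->O offset along the strand direction

    def strand_res(seq: int, origin, direction, serial0) -> Residue:
        ox, oy = origin
        s = 1.0 if direction > 0 else -1.0
        n = _mkatom("N", "N", (ox, oy, 0.0), serial0)
        ca = _mkatom("CA", "C", (ox + s * span / 2, oy - s * 1.0, 0.0), serial0 + 1)
        c = _mkatom("C", "C", (ox + s * (span - BOND_C_O), oy - s * 0.2, 0.0), serial0 + 2)
        o = _mkatom("O", "O", (ox + s * span, oy, 0.0), serial0 + 3)
        return Residue("A", seq, "", "ALA", [n, ca, c, o])

    residues = [
        strand_res(1, (-8.0, 0.0), +1, 1),
        strand_res(2, (0.0, 0.0), +1, 5),
        strand_res(3, (8.0, 0.0), +1, 9),
        Residue("A", 4, "", "GLY", [_mkatom("CA", "C", (13.0, 1.4, 0.0), 13)]),
        Residue("A", 5, "", "GLY", [_mkatom("CA", "C", (13.0, 2.8, 0.0), 14)]),
        strand_res(6, (8.0 + span, d, 0.0)[:2], -1, 15),
        strand_res(7, (span, d), -1, 19),
        strand_res(8, (span - 8.0, d), -1, 23),
    ]
    st = Structure(id="ideal_hairpin", chains={"A": residues})
    # by construction every strand residue pair (i, 9 - i) carries the
    # reciprocal N..O / O..N bond pair at the designed distance
    gt = {
        "strand_a": [1, 3],
        "strand_b": [6, 8],
        "n_cross_strand_bonds": 6,
        "bond_distance": d,
        "bonds": [
            {"partner_a": ["A", i, "", "N"], "partner_b": ["A", 9 - i, "", "O"],
             "distance": d}
            for i in (1, 2, 3, 6, 7, 8)
        ],
    }
    return st, gt


def _fx_two_chain_interface(p: dict, rng) -> tuple[Structure, dict]:
    gap = float(p.get("gap", 12.0))
    n_side = int(p.get("n_side", 2))
    spacing = 3.5

    def wall(chain_id: str, x: float, serial0: int) -> list[Residue]:
        atoms = []
        k = 0
        for iy in range(n_side):
            for iz in range(n_side):
                atoms.append(_mkatom(f"C{k + 1}", "C", (x, iy * spacing, iz * spacing),
                                     serial0 + k))
                k += 1
        return [Residue(chain_id, 1, "", "UNK", atoms)]

    st = Structure(id="two_chain_interface",
                   chains={"A": wall("A", 0.0, 1), "B": wall("B", gap, 100)})
    contact_free = gap >= 2 * (1.87 + 1.4)
    gt = {"gap": gap, "buried_total": 0.0 if contact_free else None,
          "contacts": [] if contact_free else None}
    return st, gt


def _fx_perturbed_copy(p: dict, rng) -> tuple[Structure, dict]:
    axis = np.asarray(p.get("axis", (0.0, 0.0, 1.0)), float)
    axis = axis / np.linalg.norm(axis)
    angle_deg = float(p.get("angle", 30.0))
    translation = np.asarray(p.get("translation", (5.0, 0.0, 0.0)), float)
    noise_sd = float(p.get("noise_sd", 0.0))
    base, _ = _fx_ideal_backbone({"phi_psi": p.get("phi_psi", [(-60.0, -45.0)] * 8)}, rng)

    t = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
    moved = base.transformed(R, translation)
    if noise_sd > 0:
        chains = {}
        for cid, residues in moved.chains.items():
            new_rs = []
            for res in residues:
                atoms = [
                    _mkatom(a.name, a.element, a.coords + rng.normal(0.0, noise_sd, 3),
                            a.serial)
                    for a in res.atoms
                ]
                new_rs.append(Residue(res.chain_id, res.seq_num, res.icode, res.res_name, atoms))
            chains[cid] = new_rs
        moved = Structure(moved.id, chains)
    gt = {
        "rotation": R.tolist(),
        "translation": translation.tolist(),
        "noise_sd": noise_sd,
        "expected_rmsd": 0.0 if noise_sd == 0 else None,
        "expected_rmsd_sq_mean": 3 * noise_sd**2 if noise_sd > 0 else 0.0,
    }
    return (moved, gt), {"__pair__": True, "reference": base, "ground_truth": gt}


_BUILDERS = {
    "single_atom": _fx_single_atom,
    "sphere_pair": _fx_sphere_pair,
    "hbond_pair": _fx_hbond_pair,
    "cation_pi_pair": _fx_cation_pi_pair,
    "water_bridge": _fx_water_bridge,
    "ideal_backbone": _fx_ideal_backbone,
    "ideal_turn": _fx_ideal_turn,
    "ideal_hairpin": _fx_ideal_hairpin,
    "two_chain_interface": _fx_two_chain_interface,
}


def build_fixture(spec: FixtureSpec):
    """Build a fixture structure and its ground-truth record.

    Returns ``(Structure, dict)`` for most kinds; ``perturbed_copy``
    returns ``((mobile, reference), dict)`` where the record holds the
    applied transform.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "perturbed_copy":
        (moved, gt), extra = _fx_perturbed_copy(dict(spec.parameters), rng)
        return (moved, extra["reference"]), gt
    try:
        builder = _BUILDERS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    return builder(dict(spec.parameters), rng)


DEFAULT_SUITE: tuple[FixtureSpec, ...] = (
    FixtureSpec("single_atom"),
    FixtureSpec("sphere_pair", {"distance": 3.0}),
    FixtureSpec("hbond_pair", {"distance": 2.9, "angle": 165.0}),
    FixtureSpec("cation_pi_pair", {"distance": 4.0}),
    FixtureSpec("water_bridge", {"distance": 2.8}),
    FixtureSpec("ideal_backbone"),
    FixtureSpec("ideal_turn"),
    FixtureSpec("ideal_hairpin"),
    FixtureSpec("two_chain_interface", {"gap": 12.0}),
    FixtureSpec("perturbed_copy", {"angle": 30.0, "translation": (5.0, 0.0, 0.0)}),
)


def materialize_suite(out_dir: str | Path, specs=DEFAULT_SUITE) -> list[Path]:
    """Write every fixture as a PDB file with a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for spec in specs:
        built, gt = build_fixture(spec)
        if spec.kind == "perturbed_copy":
            mobile, reference = built
            write_pdb(mobile, out_dir / f"{spec.kind}_mobile.pdb")
            write_pdb(reference, out_dir / f"{spec.kind}_reference.pdb")
            written.append(out_dir / f"{spec.kind}_mobile.pdb")
        else:
            write_pdb(built, out_dir / f"{spec.kind}.pdb")
            written.append(out_dir / f"{spec.kind}.pdb")
        sidecar = out_dir / f"{spec.kind}.json"
        sidecar.write_text(json.dumps({"spec": {"kind": spec.kind,
                                                "parameters": spec.parameters,
                                                "seed": spec.seed},
                                       "ground_truth": gt}, indent=2, default=str))
        written.append(sidecar)
    return written
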