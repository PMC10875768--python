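"""Vector geometry: distances, backbone dihedrals, Kabsch superposition.

Angles are reported in degrees on the half-open interval (-180, 180], with
ties at the branch cut reported as +180.  Superposition solves the orthogonal
Procrustes problem by SVD with the usual determinant correction so that a
proper rotation (det = +1) is always returned, never a reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomKey, ResidueKey, Structure

__all__ = [
    "DihedralSet",
    "SuperpositionResult",
    "GeometryError",
    "dihedral",
    "backbone_dihedrals",
    "kabsch_superpose",
    "atom_displacement",
    "point_distance",
    "ring_centroid",
]

#: heavy atoms of the six-membered aromatic ring, per residue type
AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),  # 6-ring
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

TRP_5RING = ("CG", "CD1", "NE1", "CE2", "CD2")


class GeometryError(Exception):
    pass


def _wrap_angle(deg: float) -> float:
    """Map to (-180, 180]; exact -180 becomes +180."""
    wrapped = ((deg + 180.0) % 360.0) - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Zero for a cis (eclipsed) arrangement, +/-180 for trans; the sign
    follows the right-hand rule about the p2->p3 axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or b2_norm < 1e-9:
        raise GeometryError("dihedral undefined: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2_norm)
    return _wrap_angle(np.degrees(np.arctan2(y, x)))


def angle(p1, p2, p3) -> float:
    """Planar angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass(frozen=True)
class DihedralSet:
    residue: ResidueKey
    res_name: str
    phi: float | None
    psi: float | None
    omega: float | None


def backbone_dihedrals(structure: Structure, chain: str) -> list[DihedralSet]:
    """Phi/psi/omega per residue of one chain.

    phi(i)   = C(i-1)-N(i)-CA(i)-C(i);  absent for the chain-initial residue.
    psi(i)   = N(i)-CA(i)-C(i)-N(i+1);  absent for the chain-terminal residue.
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i), the peptide bond preceding residue i.

    A gap in author numbering (next seq_num != seq_num + 1 with empty icodes)
    breaks consecutiveness; no dihedral is computed across a gap.  A missing
    backbone atom marks the affected angles absent with a warning.
    """
    residues = [r for r in structure.chains.get(chain, []) if not r.is_water]
    if len(residues) < 2:
        raise GeometryError(f"chain {chain!r}: need >= 2 residues for backbone dihedrals")

    def consecutive(a, b) -> bool:
        if a.icode or b.icode:
            return True  # insertion codes: trust file order
        return b.seq_num == a.seq_num + 1

    out: list[DihedralSet] = []
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 and consecutive(residues[i - 1], res) else None
        next_res = (
            residues[i + 1] if i + 1 < len(residues) and consecutive(res, residues[i + 1]) else None
        )
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = omega = None
        try:
            if None in (n, ca, c):
                warnings.warn(f"residue {res.key}: incomplete backbone, angles marked absent",
                              stacklevel=2)
            else:
                if prev_res is not None:
                    pc, pca = prev_res.atom("C"), prev_res.atom("CA")
                    if pc is not None:
                        phi = dihedral(pc.coords, n.coords, ca.coords, c.coords)
                        if pca is not None:
                            omega = dihedral(pca.coords, pc.coords, n.coords, ca.coords)
                if next_res is not None:
                    nn = next_res.atom("N")
                    if nn is not None:
                        psi = dihedral(n.coords, ca.coords, c.coords, nn.coords)
        except GeometryError:
            warnings.warn(f"residue {res.key}: degenerate backbone geometry", stacklevel=2)
        out.append(DihedralSet(res.key, res.res_name, phi, psi, omega))
    return out


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det=+1
    translation: np.ndarray  # 3-vector
    rmsd: float
    fitted_atom_count: int
    displacement_table: list[tuple[AtomKey, float]] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def displacement(self, key: AtomKey) -> float:
        for k, d in self.displacement_table:
            if k == key:
                return d
        raise GeometryError(f"atom {key} not in displacement table")


def kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (R, t) minimising |R x + t - y|.

    Returns the proper rotation, translation and the residual RMSD.
    """
    X = np.asarray(mobile_xyz, float)
    Y = np.asarray(ref_xyz, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError("superposition needs matching (n, 3) coordinate arrays")
    n = X.shape[0]
    if n < 3:
        raise GeometryError("superposition needs >= 3 atom pairs")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-8) < 2:
        raise GeometryError("superposition degenerate: collinear point set")
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = X0 @ R.T - Y0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    pairing: list[tuple[AtomKey, AtomKey]],
) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    ``pairing`` lists (mobile_key, reference_key) atom pairs used for the
    fit; RMSD is computed over the pairing.  The displacement table covers
    every atom key present in both structures, measured after applying the
    fitted transform to the mobile structure.
    """
    mob_pts, ref_pts = [], []
    for mk, rk in pairing:
        ma, ra = mobile.atom(mk), reference.atom(rk)
        if ma is None or ra is None:
            raise GeometryError(f"pairing atom missing: {mk if ma is None else rk}")
        mob_pts.append(ma.coords)
        ref_pts.append(ra.coords)
    R, t, rmsd = kabsch(np.array(mob_pts), np.array(ref_pts))

    table: list[tuple[AtomKey, float]] = []
    ref_index = {(res.chain_id, res.seq_num, res.icode, a.name): a for res, a in reference.atoms()}
    for res, a in mobile.atoms():
        key = (res.chain_id, res.seq_num, res.icode, a.name)
        mate = ref_index.get(key)
        if mate is not None:
            moved = R @ a.coords + t
            table.append((key, float(np.linalg.norm(moved - mate.coords))))
    return SuperpositionResult(R, t, rmsd, len(pairing), table)


def atom_displacement(result: SuperpositionResult, atom_key: AtomKey) -> float:
    """Displacement (Angstrom) of one atom after superposition."""
    return result.displacement(atom_key)


def ring_centroid(structure: Structure, chain_id: str, seq_num: int, icode: str = "",
                  five_ring: bool = False) -> np.ndarray:
    """Centroid of an aromatic side-chain ring (Tyr/Phe/Trp/His heavy atoms)."""
    res = structure.residue(chain_id, seq_num, icode)
    if res is None:
        raise GeometryError(f"no residue {(chain_id, seq_num, icode)}")
    names = TRP_5RING if (five_ring and res.res_name == "TRP") else AROMATIC_RING_ATOMS.get(res.res_name)
    if names is None:
        raise GeometryError(f"residue {res.res_name} {res.key} has no aromatic ring")
    pts = []
    for name in names:
        a = res.atom(name)
        if a is None:
            raise GeometryError(f"incomplete ring in {res.res_name} {res.key}: missing {name}")
        pts.append(a.coords)
    return np.mean(pts, axis=0)


def ring_displacement(
    result: SuperpositionResult,
    mobile: Structure,
    reference: Structure,
    chain_id: str,
    seq_num: int,
    icode: str = "",
) -> float:
    """Displacement of an aromatic ring, measured between ring centroids
    after applying the fitted transform to the mobile structure."""
    c_mob = ring_centroid(mobile, chain_id, seq_num, icode)
    c_ref = ring_centroid(reference, chain_id, seq_num, icode)
    moved = result.rotation @ c_mob + result.translation
    return float(np.linalg.norm(moved - c_ref))


def point_distance(structure: Structure, atom_key_a: AtomKey, atom_key_b: AtomKey) -> float:
    """Euclidean distance (Angstrom) between two addressed atoms."""
    a, b = structure.atom(atom_key_a), structure.atom(atom_key_b)
    if a is None:
        raise GeometryError(f"missing atom {atom_key_a}")
    if b is None:
        raise GeometryError(f"missing atom {atom_key_b}")
    return float(np.linalg.norm(a.coords - b.coords))
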