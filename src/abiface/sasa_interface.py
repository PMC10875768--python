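"""Shrake-Rupley solvent-accessible surface area and buried interface area.

The accessible surface of each atom is traced by a probe sphere (default
1.4 Angstrom) rolled over van der Waals spheres and integrated numerically
over a deterministic spherical Fibonacci point set, so repeated runs are
bit-identical.  Interface (buried) area between two atom groups A and B is

    BSA = SASA(A) + SASA(B) - SASA(A u B)

with the PISA-style "interface area" convention reporting BSA / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structure_io import (
    Residue,
    ResidueKey,
    SelectionSpec,
    Structure,
    merge,
    select,
)

__all__ = [
    "RadiiTable",
    "InterfaceReport",
    "shrake_rupley",
    "interface_report",
    "sphere_points",
]

# Chothia-style protein van der Waals radii (Angstrom).  Tetrahedral carbon
# 1.87; trigonal (carbonyl / carboxyl / amide / aromatic / guanidinium)
# carbon 1.76.
ELEMENT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
}

#: side-chain carbons treated as trigonal (sp2), radius 1.76
_TRIGONAL_SC: dict[str, frozenset[str]] = {
    "ASP": frozenset({"CG"}),
    "ASN": frozenset({"CG"}),
    "GLU": frozenset({"CD"}),
    "GLN": frozenset({"CD"}),
    "ARG": frozenset({"CZ"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
}

TRIGONAL_C_RADIUS = 1.76


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii plus probe and quadrature settings.

    ``overrides`` maps ``"ELEMENT"`` or ``"RES:ATOM"`` keys to radii and
    takes precedence over the built-in Chothia-style set.
    """

    overrides: dict[str, float] = field(default_factory=dict)
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be >= 60")
        for key, r in self.overrides.items():
            if r <= 0:
                raise ValueError(f"radius for {key!r} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "RadiiTable":
        data = yaml.safe_load(Path(path).read_text()) or {}
        probe = data.pop("probe_radius", kwargs.pop("probe_radius", 1.4))
        npts = data.pop("n_sphere_points", kwargs.pop("n_sphere_points", 960))
        return cls(overrides={str(k).upper(): float(v) for k, v in data.items()},
                   probe_radius=probe, n_sphere_points=npts)

    def radius(self, res_name: str, atom_name: str, element: str) -> float:
        specific = self.overrides.get(f"{res_name}:{atom_name}".upper())
        if specific is not None:
            return specific
        by_element = self.overrides.get(element.upper())
        if by_element is not None:
            return by_element
        if element == "C":
            if atom_name == "C":  # backbone carbonyl
                return TRIGONAL_C_RADIUS
            if atom_name in _TRIGONAL_SC.get(res_name, ()):
                return TRIGONAL_C_RADIUS
            return ELEMENT_RADII["C"]
        try:
            return ELEMENT_RADII[element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for atom {atom_name!r} ({res_name}), "
                f"element {element!r}; add an override"
            ) from None


def sphere_points(n: int) -> np.ndarray:
    """Deterministic spherical Fibonacci point set, shape (n, 3), unit norm."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _collect_atoms(structure: Structure, radii: RadiiTable, strip_waters: bool):
    keys, centers, rads = [], [], []
    for res, atom in structure.atoms():
        if atom.is_hydrogen:
            continue
        if strip_waters and res.is_water:
            continue
        keys.append((res.chain_id, res.seq_num, res.icode, atom.name))
        centers.append(atom.coords)
        rads.append(radii.radius(res.res_name, atom.name, atom.element))
    return keys, np.array(centers, float), np.array(rads, float)


def shrake_rupley(
    structure: Structure,
    radii: RadiiTable | None = None,
    strip_waters: bool = True,
) -> dict[tuple, float]:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Heavy atoms only; waters are excluded by default (protein-protein
    interface convention).  Deterministic for a fixed point count.
    """
    radii = radii or RadiiTable()
    keys, centers, rads = _collect_atoms(structure, radii, strip_waters)
    if len(keys) == 0:
        raise ValueError("structure has no heavy atoms to compute SASA over")
    expanded = rads + radii.probe_radius
    unit = sphere_points(radii.n_sphere_points)

    tree = cKDTree(centers)
    max_r = expanded.max()
    areas = np.empty(len(keys))
    for i in range(len(keys)):
        pts = centers[i] + expanded[i] * unit
        accessible = np.ones(len(unit), dtype=bool)
        for j in tree.query_ball_point(centers[i], expanded[i] + max_r):
            if j == i:
                continue
            d = centers[j] - centers[i]
            if np.dot(d, d) >= (expanded[i] + expanded[j]) ** 2:
                continue
            within = ((pts - centers[j]) ** 2).sum(axis=1) < expanded[j] ** 2
            accessible &= ~within
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.sum() / len(unit)
    return dict(zip(keys, areas))


@dataclass
class InterfaceReport:
    group_a: SelectionSpec
    group_b: SelectionSpec
    sasa_a: float
    sasa_b: float
    sasa_ab: float
    per_residue_burial: list[tuple[ResidueKey, float]]
    burial_threshold: float = 0.1

    @property
    def buried_total(self) -> float:
        return self.sasa_a + self.sasa_b - self.sasa_ab

    @property
    def interface_area_pisa(self) -> float:
        """Half the buried area: the convention PISA prints as interface area."""
        return self.buried_total / 2.0

    @property
    def interface_residues(self) -> list[ResidueKey]:
        return [k for k, d in self.per_residue_burial if d > self.burial_threshold]


def interface_report(
    structure: Structure,
    group_a: SelectionSpec,
    group_b: SelectionSpec,
    radii: RadiiTable | None = None,
) -> InterfaceReport:
    """Buried-area report between two disjoint atom groups.

    SASA is evaluated three times (A alone, B alone, A u B); per-residue
    burial is the drop in that residue's SASA on complex formation, so the
    burials sum to ``buried_total`` exactly up to float rounding.
    """
    radii = radii or RadiiTable()
    sub_a = select(structure, group_a)
    sub_b = select(structure, group_b)
    if sub_a.n_atoms() == 0 or sub_b.n_atoms() == 0:
        raise ValueError("interface groups must both be non-empty")
    keys_a = {(r.chain_id, r.seq_num, r.icode, a.name) for r, a in sub_a.atoms()}
    keys_b = {(r.chain_id, r.seq_num, r.icode, a.name) for r, a in sub_b.atoms()}
    if keys_a & keys_b:
        raise ValueError("interface groups overlap")

    per_atom_a = shrake_rupley(sub_a, radii)
    per_atom_b = shrake_rupley(sub_b, radii)
    per_atom_ab = shrake_rupley(merge(sub_a, sub_b, id=structure.id), radii)

    burial: dict[ResidueKey, float] = {}
    for key, alone in {**per_atom_a, **per_atom_b}.items():
        delta = alone - per_atom_ab[key]
        rkey = key[:3]
        burial[rkey] = burial.get(rkey, 0.0) + delta

    return InterfaceReport(
        group_a=group_a,
        group_b=group_b,
        sasa_a=float(sum(per_atom_a.values())),
        sasa_b=float(sum(per_atom_b.values())),
        sasa_ab=float(sum(per_atom_ab.values())),
        per_residue_burial=sorted(burial.items(), key=lambda kv: kv[0]),
    )
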