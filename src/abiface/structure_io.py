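"""Hierarchical coordinate model and PDB/mmCIF input.

Parsing is delegated to :mod:`gemmi`; the in-memory model here is a thin,
validated hierarchy (``Structure`` -> chains -> ``Residue`` -> ``Atom``)
tailored to interface analysis: alternate conformers are resolved to a
single conformer at parse time, waters are retained but flagged, and every
residue is addressable by its author-assigned ``(chain_id, seq_num, icode)``
key.  A minimal fixed-width PDB writer supports round-tripping and fixture
generation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "SelectionSpec",
    "StructureError",
    "EmptyStructureError",
    "ParseError",
    "parse_structure",
    "select",
    "write_pdb",
]

WATER_NAMES = frozenset({"HOH", "WAT"})
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

ResidueKey = tuple[str, int, str]
AtomKey = tuple[str, int, str, str]


class StructureError(Exception):
    """Base class for coordinate-model errors."""


class EmptyStructureError(StructureError):
    """Raised when a file or selection yields no atoms where atoms are required."""


class ParseError(StructureError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    occupancy: float
    coords: np.ndarray  # shape (3,), Angstrom
    is_hetero: bool = False
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise StructureError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


@dataclass
class Structure:
    """Ordered chain -> residue -> atom hierarchy in author numbering."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None
    source_format: str | None = None

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for cid, residues in self.chains.items():
            for res in residues:
                if res.chain_id != cid:
                    raise StructureError(f"residue {res.key} filed under chain {cid!r}")
                if res.key in seen:
                    raise StructureError(f"duplicate residue key {res.key}")
                seen.add(res.key)

    # -- traversal ---------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain_id, ()):
            if res.seq_num == seq_num and res.icode == icode:
                return res
        return None

    def atom(self, key: AtomKey) -> Atom | None:
        res = self.residue(key[0], key[1], key[2])
        return res.atom(key[3]) if res is not None else None

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n, 3) array, traversal order."""
        pts = [a.coords for _, a in self.atoms()]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with all coordinates mapped x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains: dict[str, list[Residue]] = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(
                    res.chain_id,
                    res.seq_num,
                    res.icode,
                    res.res_name,
                    [replace(a, coords=R @ a.coords + t) for a in res.atoms],
                )
                for res in residues
            ]
        return Structure(self.id, chains, self.resolution, self.source_format)


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection in author numbering.

    ``None`` for :attr:`chain_ids` or :attr:`residue_ranges` means
    "no restriction"; ranges are inclusive on both ends.
    """

    chain_ids: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    include_waters: bool = True
    include_hetero: bool = True
    atom_classes: Literal["all", "backbone", "heavy", "sidechain"] = "all"

    def __post_init__(self) -> None:
        if self.chain_ids is not None:
            object.__setattr__(self, "chain_ids", frozenset(self.chain_ids))
        if self.residue_ranges is not None:
            ranges = tuple(tuple(r) for r in self.residue_ranges)
            for start, end in ranges:
                if start > end:
                    raise ValueError(f"residue range ({start}, {end}) not well-ordered")
            object.__setattr__(self, "residue_ranges", ranges)

    def matches_residue(self, res: Residue) -> bool:
        if self.chain_ids is not None and res.chain_id not in self.chain_ids:
            return False
        if res.is_water and not self.include_waters:
            return False
        if self.residue_ranges is not None and not any(
            lo <= res.seq_num <= hi for lo, hi in self.residue_ranges
        ):
            return False
        return True

    def matches_atom(self, res: Residue, atom: Atom) -> bool:
        if not self.matches_residue(res):
            return False
        if atom.is_hetero and not res.is_water and not self.include_hetero:
            return False
        if self.atom_classes == "backbone":
            return atom.name in BACKBONE_ATOMS
        if self.atom_classes == "heavy":
            return not atom.is_hydrogen
        if self.atom_classes == "sidechain":
            return not atom.is_hydrogen and atom.name not in BACKBONE_ATOMS
        return True


# ---------------------------------------------------------------------------
# parsing

def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Collapse alternate conformers: per atom name keep the highest-occupancy
    conformer, breaking ties toward altloc 'A' (then alphabetically)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for atom in raw_atoms:
        if atom.name not in by_name:
            order.append(atom.name)
        by_name.setdefault(atom.name, []).append(atom)
    resolved = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "A"))
        resolved.append(best)
    return resolved


def parse_structure(path: str | Path, format: str = "auto") -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is read.  Alternate conformers are resolved to a
    single conformer; waters are kept and flagged; chain order follows the
    file.  ``format`` is one of ``auto``, ``pdb``, ``mmcif``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such coordinate file: {path}")
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    try:
        fmt = fmt_map[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected auto/pdb/mmcif") from None
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    source = "mmcif" if (format == "mmcif" or path.suffix.lower() in {".cif", ".mmcif"}) else "pdb"

    chains: dict[str, list[Residue]] = {}
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            raw: list[Atom] = []
            for atom in res:
                element = atom.element.name if atom.element.name else "C"
                raw.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=element.upper(),
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_hetero=res.het_flag == "H",
                        bfactor=atom.b_iso,
                    )
                )
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name,
                    atoms=_resolve_altlocs(raw),
                )
            )
        if residues:
            chains.setdefault(chain.name, []).extend(residues)

    structure = Structure(
        id=st.name or path.stem,
        chains=chains,
        resolution=st.resolution if st.resolution > 0 else None,
        source_format=source,
    )
    if structure.n_atoms() == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return structure


def select(structure: Structure, spec: SelectionSpec) -> Structure:
    """Return the sub-structure whose atoms match ``spec`` (idempotent)."""
    chains: dict[str, list[Residue]] = {}
    for cid, residues in structure.chains.items():
        kept_residues = []
        for res in residues:
            if not spec.matches_residue(res):
                continue
            atoms = [a for a in res.atoms if spec.matches_atom(res, a)]
            if atoms:
                kept_residues.append(Residue(res.chain_id, res.seq_num, res.icode, res.res_name, atoms))
        if kept_residues:
            chains[cid] = kept_residues
    out = Structure(structure.id, chains, structure.resolution, structure.source_format)
    if out.n_atoms() == 0:
        warnings.warn(f"selection matched no atoms in structure {structure.id!r}", stacklevel=2)
    return out


def merge(a: Structure, b: Structure, id: str = "") -> Structure:
    """Union of two structures with disjoint residue keys."""
    chains: dict[str, list[Residue]] = {cid: list(rs) for cid, rs in a.chains.items()}
    for cid, residues in b.chains.items():
        chains.setdefault(cid, [])
        chains[cid] = chains[cid] + list(residues)
    return Structure(id or a.id, chains, a.resolution, a.source_format)


# ---------------------------------------------------------------------------
# writing

def _pdb_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    record = "HETATM" if (atom.is_hetero or res.is_water) else "ATOM"
    name = atom.name
    # wwPDB v3.3 alignment: element symbols of one char start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{res.res_name:>3} {res.chain_id[:1]:1}"
        f"{res.seq_num:>4}{res.icode or '':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element:>2}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as PDB ATOM/HETATM/TER/END records."""
    lines: list[str] = []
    serial = 0
    for cid, residues in structure.chains.items():
        last_res: Residue | None = None
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_pdb_atom_line(serial, atom, res))
            last_res = res
        if last_res is not None and not last_res.is_water:
            serial += 1
            lines.append(
                f"TER   {serial:>5}      {last_res.res_name:>3} {cid[:1]:1}{last_res.seq_num:>4}"
                f"{last_res.icode or '':1}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
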