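"""Backbone motifs and sequence scans.

Beta-turns are four-residue chain reversals with CA(i)-CA(i+3) <= 7.0 A,
typed from the (phi, psi) of the two central residues against the canonical
Hutchinson-Thornton centres, each angle within +/-30 deg with one angle
allowed +/-45 deg; windows whose central residues are both helical are
excluded.  Beta-hairpins are antiparallel strand pairs validated by
reciprocal cross-strand backbone hydrogen bonds.  Sequence-level scans
cover the N-glycosylation sequon N-X-[S/T] (X != P) and pairwise percent
identity of aligned sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contacts import Contact, find_hbonds
from .geometry import backbone_dihedrals
from .structure_io import ResidueKey, SelectionSpec, Structure

__all__ = [
    "TurnAssignment",
    "HairpinAssignment",
    "SequonHit",
    "TURN_CENTERS",
    "detect_beta_turns",
    "classify_turn_type",
    "detect_beta_hairpins",
    "scan_nglyc_sequons",
    "percent_identity",
]

#: canonical (phi_{i+1}, psi_{i+1}, phi_{i+2}, psi_{i+2}) turn centres, degrees
TURN_CENTERS: dict[str, tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
}

MIRROR_PAIRS = {"I": "I'", "I'": "I", "II": "II'", "II'": "II"}

CA_DISTANCE_MAX = 7.0
_HELIX_CENTER = (-60.0, -45.0)
_HELIX_WINDOW = 30.0


def _angdiff(a: float, b: float) -> float:
    """Absolute circular difference in degrees."""
    return abs(((a - b) + 180.0) % 360.0 - 180.0)


def classify_turn_type(phi1: float, psi1: float, phi2: float, psi2: float) -> str:
    """Nearest canonical turn type, or ``"IV"`` when no centre fits.

    A type matches when all four angles lie within 30 deg of its centre,
    with a single angle allowed to stray to 45 deg; among matching types
    the one with the smallest summed circular deviation wins.
    """
    for v in (phi1, psi1, phi2, psi2):
        if v is None:
            raise ValueError("turn typing needs all four central dihedrals")
    best: tuple[float, str] | None = None
    for name, center in TURN_CENTERS.items():
        devs = [_angdiff(v, c) for v, c in zip((phi1, psi1, phi2, psi2), center)]
        over30 = [d for d in devs if d > 30.0]
        if len(over30) > 1 or any(d > 45.0 for d in devs):
            continue
        score = sum(devs)
        if best is None or score < best[0]:
            best = (score, name)
    return best[1] if best else "IV"


@dataclass(frozen=True)
class TurnAssignment:
    residues: tuple[ResidueKey, ResidueKey, ResidueKey, ResidueKey]
    ca_distance_i_i3: float
    phi_psi: tuple[float, float, float, float]
    turn_type: str
    stabilizing_hbond: Contact | None = None


def detect_beta_turns(structure: Structure, chain: str,
                      hbond_d_max: float = 3.5) -> list[TurnAssignment]:
    """All four-residue windows qualifying as beta-turns in one chain.

    A window i..i+3 of consecutive residues qualifies when CA(i)-CA(i+3)
    <= 7.0 A and the two central residues are not both alpha-helical
    ((phi, psi) within 30 deg of (-60, -45)).  The CO(i)..N(i+3) hydrogen
    bond is attached when present but is not required.
    """
    residues = [r for r in structure.chains.get(chain, []) if not r.is_water]
    if len(residues) < 4:
        return []
    dihedrals = {d.residue: d for d in backbone_dihedrals(structure, chain)}
    turns: list[TurnAssignment] = []
    for i in range(len(residues) - 3):
        window = residues[i : i + 4]
        if any(b.seq_num != a.seq_num + 1 for a, b in zip(window, window[1:])
               if not (a.icode or b.icode)):
            continue
        cas = [r.atom("CA") for r in window]
        if any(a is None for a in cas):
            continue
        d13 = float(np.linalg.norm(cas[0].coords - cas[3].coords))
        if d13 > CA_DISTANCE_MAX:
            continue
        d1, d2 = dihedrals.get(window[1].key), dihedrals.get(window[2].key)
        if d1 is None or d2 is None or None in (d1.phi, d1.psi, d2.phi, d2.psi):
            continue

        def helical(d) -> bool:
            return (_angdiff(d.phi, _HELIX_CENTER[0]) <= _HELIX_WINDOW
                    and _angdiff(d.psi, _HELIX_CENTER[1]) <= _HELIX_WINDOW)

        if helical(d1) and helical(d2):
            continue
        angles = (d1.phi, d1.psi, d2.phi, d2.psi)
        hbond = None
        o_i, n_i3 = window[0].atom("O"), window[3].atom("N")
        if o_i is not None and n_i3 is not None:
            dist = float(np.linalg.norm(o_i.coords - n_i3.coords))
            if dist <= hbond_d_max:
                hbond = Contact(
                    "hbond",
                    (window[3].chain_id, window[3].seq_num, window[3].icode, "N"),
                    (window[0].chain_id, window[0].seq_num, window[0].icode, "O"),
                    dist,
                )
        turns.append(
            TurnAssignment(
                residues=tuple(r.key for r in window),
                ca_distance_i_i3=d13,
                phi_psi=angles,
                turn_type=classify_turn_type(*angles),
                stabilizing_hbond=hbond,
            )
        )
    return turns


@dataclass
class HairpinAssignment:
    strand_a: tuple[int, int]  # seq_num range, inclusive
    strand_b: tuple[int, int]
    chain_id: str
    orientation: str = "antiparallel"
    cross_strand_hbonds: list[Contact] = field(default_factory=list)


def detect_beta_hairpins(
    structure: Structure,
    chain: str,
    d_max: float = 3.5,
    angle_min: float = 90.0,
) -> list[HairpinAssignment]:
    """Antiparallel hairpins from reciprocal cross-strand backbone H-bonds.

    A register pair (i, j), j >= i+2, with both N(i)..O(j) and O(i)..N(j)
    hydrogen bonds seeds a hairpin; the register is extended outward in
    steps of two while further cross-strand bonds exist.  Only hairpins
    with >= 2 cross-strand bonds are reported.
    """
    spec = SelectionSpec(chain_ids=frozenset({chain}), atom_classes="backbone",
                         include_waters=False)
    hbonds = [c for c in find_hbonds(structure, spec, spec, d_max, angle_min)
              if {c.partner_a[3], c.partner_b[3]} == {"N", "O"}]

    def seqs(c: Contact) -> frozenset[int]:
        return frozenset({c.partner_a[1], c.partner_b[1]})

    bonded_pairs: dict[frozenset[int], list[Contact]] = {}
    for c in hbonds:
        bonded_pairs.setdefault(seqs(c), []).append(c)

    reciprocal = sorted(
        (min(p), max(p)) for p, cs in bonded_pairs.items()
        if len(p) == 2 and max(p) - min(p) >= 2 and len(cs) >= 2
    )
    # register pairs of one hairpin share the chain-reversal centre (i + j)
    by_center: dict[int, list[tuple[int, int]]] = {}
    for i, j in reciprocal:
        by_center.setdefault(i + j, []).append((i, j))
    hairpins: list[HairpinAssignment] = []
    for center in sorted(by_center):
        group = by_center[center]
        contacts: list[Contact] = []
        for i, j in group:
            contacts.extend(bonded_pairs[frozenset({i, j})])
            # pick up non-reciprocal register bonds two steps outward
            step = 1
            while frozenset({i - 2 * step, j + 2 * step}) in bonded_pairs:
                pair = (i - 2 * step, j + 2 * step)
                if pair not in group:
                    group.append(pair)
                step += 1
        lo_a = min(i for i, _ in group)
        hi_a = max(i for i, _ in group)
        lo_b = min(j for _, j in group)
        hi_b = max(j for _, j in group)
        dedup = {c.identity: c for c in contacts}
        hairpins.append(
            HairpinAssignment(
                strand_a=(lo_a, hi_a),
                strand_b=(lo_b, hi_b),
                chain_id=chain,
                cross_strand_hbonds=sorted(dedup.values(), key=lambda c: c.distance),
            )
        )
    return [h for h in hairpins if len(h.cross_strand_hbonds) >= 2]


@dataclass(frozen=True)
class SequonHit:
    position: int | str
    motif: str
    kind: str  # "N-linked sequon" | "O-linked candidate"


_AA = set("ACDEFGHIKLMNPQRSTVWY")


def scan_nglyc_sequons(
    sequence: str,
    numbering: Mapping[int, int | str] | None = None,
    o_linked_positions: Sequence[int] | None = None,
) -> list[SequonHit]:
    """Scan for N-glycosylation sequons N-X-[S/T] with X != P.

    ``numbering`` maps 0-based sequence index to a position label (for
    example TM-relative mucin numbering); by default positions are 1-based
    indices.  O-linked sites carry no sequence rule here; indices supplied
    via ``o_linked_positions`` (an external prediction) are echoed as
    candidates.
    """
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")

    def label(idx: int):
        return numbering[idx] if numbering is not None else idx + 1

    hits = [
        SequonHit(label(m.start()), seq[m.start() : m.start() + 3], "N-linked sequon")
        for m in re.finditer(r"N(?=[^P][ST])", seq)
    ]
    for idx in o_linked_positions or ():
        if seq[idx] not in "ST":
            raise ValueError(f"O-linked candidate at index {idx} is {seq[idx]}, not S/T")
        hits.append(SequonHit(label(idx), seq[idx], "O-linked candidate"))
    return hits


def percent_identity(aligned_sequences: Sequence[str]) -> np.ndarray:
    """Pairwise percent identity of pre-aligned (gapped) sequences.

    Columns where either sequence of a pair carries a gap are excluded
    for that pair (pairwise deletion).  Returns a symmetric matrix with
    100.0 on the diagonal.
    """
    seqs = [s.upper() for s in aligned_sequences]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    n = len(seqs)
    arr = np.array([list(s) for s in seqs])
    gaps = (arr == "-") | (arr == ".")
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(gaps[i] | gaps[j])
            total = int(keep.sum())
            ident = 100.0 * float((arr[i][keep] == arr[j][keep]).sum()) / total if total else 0.0
            out[i, j] = out[j, i] = ident
    return out
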