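"""Geometric detection of salt bridges and hydrogen bonds around Lys/Arg.

Definitions follow the classical heavy-atom distance criteria used for
surface-charge censuses:

* **salt bridge** -- a basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2)
  within 4.0 angstrom of a carboxylate oxygen (Asp OD1/OD2; Glu OE1/OE2);
* **hydrogen bond** -- a donor on the basic residue (its side-chain N, or
  its backbone N) within 2.5-3.2 angstrom (inclusive on both ends) of an
  acceptor: any backbone carbonyl O, or a side-chain O/N/S acceptor.

The two criteria are independent: a pair of atoms inside both windows is
reported in both lists.  No angular term is applied by default -- the
criteria are distance-only -- but an optional donor-acceptor-antecedent
angle filter is available.  Detection uses a k-d tree; an exhaustive
O(n^2) scan (:func:`brute_force_pairs`) is provided as an independent
oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, ResidueView, Structure

BASIC_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
}
ACIDIC_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}
#: Side-chain hydrogen-bond acceptors by residue type (backbone O is always one).
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
    "CYS": frozenset({"SG"}),
}


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance windows and atom sets for detection (angstrom)."""

    salt_bridge_max: float = 4.0
    hbond_min: float = 2.5
    hbond_max: float = 3.2
    clash_min: float = 1.5
    basic_atoms: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(BASIC_ATOMS)
    )
    acidic_atoms: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(ACIDIC_ATOMS)
    )
    sidechain_acceptors: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(SIDECHAIN_ACCEPTORS)
    )
    exclude_adjacent: int = 1  # |delta resnum| <= this is skipped for H-bonds
    angle_filter: bool = False
    min_dha_angle: float = 90.0  # donor-antecedent..acceptor proxy angle, degrees

    def __post_init__(self) -> None:
        for name in ("salt_bridge_max", "hbond_min", "hbond_max", "clash_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hbond_min >= self.hbond_max:
            raise ValueError("hbond_min must be below hbond_max")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected atom-pair interaction."""

    kind: str  # {salt_bridge, hydrogen_bond}
    basic_residue: str  # e.g. "K113"
    partner_residue: str  # e.g. "E111"
    basic_atom: str
    partner_atom: str
    distance: float
    backbone_involved: bool = False
    chain_id: str = ""
    basic_number: int = 0
    partner_number: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("salt_bridge", "hydrogen_bond"):
            raise ValueError(f"bad interaction kind {self.kind!r}")
        if self.basic_residue == self.partner_residue:
            raise ValueError("self-interaction")


def _atom_table(
    residues: Sequence[ResidueView], selector: Mapping[str, frozenset[str]],
    backbone: str | None = None,
) -> list[tuple[ResidueView, AtomRecord]]:
    """Atoms matching a {residue type -> atom names} map, optionally plus a
    backbone atom present on every residue type."""
    out: list[tuple[ResidueView, AtomRecord]] = []
    for res in residues:
        names = set(selector.get(res.residue_name, ()))
        if backbone:
            names.add(backbone)
        for a in res.atoms:
            if a.name in names:
                out.append((res, a))
    return out


def _paired_records(
    kind: str,
    donors: list[tuple[ResidueView, AtomRecord]],
    acceptors: list[tuple[ResidueView, AtomRecord]],
    dmin: float,
    dmax: float,
    exclude_adjacent: int,
) -> list[InteractionRecord]:
    if not donors or not acceptors:
        return []
    d_coords = np.array([a.position for _, a in donors])
    a_coords = np.array([a.position for _, a in acceptors])
    tree = cKDTree(a_coords)
    records: list[InteractionRecord] = []
    for i, (dres, datom) in enumerate(donors):
        for j in tree.query_ball_point(d_coords[i], dmax):
            ares, aatom = acceptors[j]
            if ares.chain_id != dres.chain_id:
                continue  # intra-chain census only
            if ares.residue_number == dres.residue_number and (
                ares.insertion_code == dres.insertion_code
            ):
                continue
            if abs(ares.residue_number - dres.residue_number) <= exclude_adjacent:
                continue
            dist = float(np.linalg.norm(d_coords[i] - a_coords[j]))
            if dist < dmin or dist > dmax:
                continue
            records.append(
                InteractionRecord(
                    kind=kind,
                    basic_residue=dres.key,
                    partner_residue=ares.key,
                    basic_atom=datom.name,
                    partner_atom=aatom.name,
                    distance=round(dist, 4),
                    backbone_involved=datom.name == "N",
                    chain_id=dres.chain_id,
                    basic_number=dres.residue_number,
                    partner_number=ares.residue_number,
                )
            )
    records.sort(key=lambda r: (r.chain_id, r.basic_number, r.partner_number, r.distance))
    return records


def find_salt_bridges(
    structure: Structure, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """All qualifying basic-N / acidic-O atom pairs within the cutoff.

    One record per atom pair; use :func:`deduplicate` for the residue-level
    view.  Pairs closer than ``clash_min`` are discarded as clashes.
    """
    crit = criteria or InteractionCriteria()
    residues = structure.resolved_residues()
    basics = _atom_table(residues, crit.basic_atoms)
    acidics = _atom_table(residues, crit.acidic_atoms)
    return _paired_records(
        "salt_bridge", basics, acidics, crit.clash_min, crit.salt_bridge_max,
        exclude_adjacent=0,
    )


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hydrogen_bonds(
    structure: Structure, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Hydrogen bonds donated by Lys/Arg (side-chain N or backbone N).

    Acceptors are backbone carbonyl oxygens of any residue plus side-chain
    O/N/S acceptors.  Sequence-adjacent pairs (|delta| <= 1) are excluded as
    covalent-neighbour artifacts.  Records whose donor is the basic residue's
    backbone N carry ``backbone_involved=True``.
    """
    crit = criteria or InteractionCriteria()
    residues = structure.resolved_residues()
    basic_res = [r for r in residues if r.residue_name in crit.basic_atoms]
    donors = _atom_table(basic_res, crit.basic_atoms, backbone="N")
    acceptors = _atom_table(residues, crit.sidechain_acceptors, backbone="O")
    records = _paired_records(
        "hydrogen_bond", donors, acceptors, crit.hbond_min, crit.hbond_max,
        exclude_adjacent=crit.exclude_adjacent,
    )
    if not crit.angle_filter:
        return records
    # optional proxy-angle screen: donor - acceptor - acceptor antecedent
    by_key = {(r.chain_id, r.residue_number): r for r in residues}
    kept = []
    for rec in records:
        ares = by_key[(rec.chain_id, rec.partner_number)]
        antecedent = _acceptor_antecedent(ares, rec.partner_atom)
        if antecedent is None:
            kept.append(rec)
            continue
        dres = by_key[(rec.chain_id, rec.basic_number)]
        datom = dres.atom(rec.basic_atom)
        aatom = ares.atom(rec.partner_atom)
        ang = _angle_deg(datom.xyz, aatom.xyz, antecedent.xyz)
        if ang >= crit.min_dha_angle:
            kept.append(rec)
    return kept


_ANTECEDENT = {
    "O": "C", "OD1": "CG", "OD2": "CG", "OE1": "CD", "OE2": "CD",
    "OG": "CB", "OG1": "CB", "OH": "CZ", "ND1": "CG", "NE2": "CD2",
    "SD": "CG", "SG": "CB",
}


def _acceptor_antecedent(res: ResidueView, acceptor_name: str) -> AtomRecord | None:
    name = _ANTECEDENT.get(acceptor_name)
    return res.atom(name) if name else None


def deduplicate(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Residue-level view: unique (basic residue, partner residue, kind)
    triples keeping the shortest atom-pair distance."""
    best: dict[tuple[str, str, str, str], InteractionRecord] = {}
    for rec in records:
        key = (rec.chain_id, rec.kind, rec.basic_residue, rec.partner_residue)
        if key not in best or rec.distance < best[key].distance:
            best[key] = rec
    out = list(best.values())
    out.sort(key=lambda r: (r.chain_id, r.basic_number, r.partner_number))
    return out


def classify_salt_bridge_complexity(
    records: Iterable[InteractionRecord],
    basic_residues: Iterable[str] | None = None,
) -> dict[str, str]:
    """Map basic residue -> {simple, complex, none}.

    *Complex* means salt bridges to two or more distinct partner residues;
    *simple* means exactly one.  Residues listed in ``basic_residues`` but
    absent from the records are reported as *none*.
    """
    partners: dict[str, set[str]] = {}
    for rec in records:
        if rec.kind != "salt_bridge":
            continue
        partners.setdefault(rec.basic_residue, set()).add(rec.partner_residue)
    out = {
        key: ("complex" if len(p) >= 2 else "simple") for key, p in partners.items()
    }
    for key in basic_residues or ():
        out.setdefault(key, "none")
    return out


def brute_force_pairs(
    structure: Structure,
    atom_set_a: Mapping[str, frozenset[str]],
    atom_set_b: Mapping[str, frozenset[str]],
    dmax: float,
    backbone_a: str | None = None,
    backbone_b: str | None = None,
) -> list[tuple[AtomRecord, AtomRecord, float]]:
    """Exhaustive O(n^2) distance scan -- the test oracle for detection.

    Pairs are reported once, ordered by atom serial within the pair when the
    two selections overlap; pairs within the same residue are skipped.
    """
    residues = structure.resolved_residues()
    set_a = _atom_table(residues, atom_set_a, backbone=backbone_a)
    set_b = _atom_table(residues, atom_set_b, backbone=backbone_b)
    symmetric = {id(a) for _, a in set_a} == {id(b) for _, b in set_b}
    out: list[tuple[AtomRecord, AtomRecord, float]] = []
    seen: set[tuple[int, int]] = set()
    for ra, aa in set_a:
        for rb, ab in set_b:
            if aa.serial == ab.serial:
                continue
            if (ra.chain_id, ra.residue_number) == (rb.chain_id, rb.residue_number):
                continue
            lo, hi = sorted((aa.serial, ab.serial))
            if symmetric and (lo, hi) in seen:
                continue
            dist = float(np.linalg.norm(aa.xyz - ab.xyz))
            if dist <= dmax:
                first, second = (aa, ab) if not symmetric or aa.serial < ab.serial else (ab, aa)
                out.append((first, second, dist))
                if symmetric:
                    seen.add((lo, hi))
    out.sort(key=lambda t: (t[0].serial, t[1].serial))
    return out
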