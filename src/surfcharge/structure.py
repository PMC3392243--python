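"""Macromolecular structure data model plus PDB/FASTA readers and writers.

The data model is deliberately small: immutable atom records grouped into
residue views grouped into a structure.  Author (PDB) residue numbering is
preserved verbatim and never renumbered -- the downstream census, diff and
design layers all speak in author numbers (K3 ... K238 for GFP).  Parsing
is delegated to :mod:`gemmi`; FASTA I/O to :mod:`Bio.SeqIO`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Atoms considered part of the peptide backbone (everything else is side chain).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class SecondaryStructure(NamedTuple):
    """Secondary-structure label of one residue.

    ``kind`` is one of ``"helix"``, ``"strand"`` or ``"loop"``; ``index`` is
    the 1-based strand index (strands ordered by their first residue) and
    ``None`` otherwise.
    """

    kind: str
    index: int | None = None

    def __str__(self) -> str:  # formatting used in census tables
        if self.kind == "strand":
            return f"β-strand {self.index}" if self.index else "β-strand"
        return self.kind.capitalize()


LOOP = SecondaryStructure("loop")


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom, PDB-style."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class ResidueView:
    """One residue: its atoms, or none when the residue is sequence-only.

    ``resolved=False`` marks residues present in SEQRES but absent from the
    coordinate section (disordered termini such as K238 in GFP).
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atoms: tuple[AtomRecord, ...] = ()
    resolved: bool = True
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.resolved and self.atoms:
            raise ValueError("unresolved residue must have no atoms")
        for a in self.atoms:
            if (a.chain_id, a.residue_number) != (self.chain_id, self.residue_number):
                raise ValueError("atom does not belong to this residue")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.residue_name, "X")

    @property
    def key(self) -> str:
        """Compact residue key in the field's notation, e.g. ``"K45"``."""
        return f"{self.one_letter}{self.residue_number}{self.insertion_code}"

    @property
    def number_key(self) -> str:
        return f"{self.residue_number}{self.insertion_code}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> tuple[AtomRecord, ...]:
        """Side-chain atoms (CB and beyond); CA stands in for glycine."""
        side = tuple(a for a in self.atoms if a.name not in BACKBONE_ATOMS)
        if not side and self.residue_name == "GLY":
            ca = self.atom("CA")
            side = (ca,) if ca is not None else ()
        return side


@dataclass(frozen=True)
class Structure:
    """An ordered collection of residues with secondary-structure labels."""

    residues: tuple[ResidueView, ...]
    secondary_structure: Mapping[tuple[str, int], SecondaryStructure] = field(
        default_factory=dict
    )
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.residue_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue number) pairs")

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return tuple(seen)

    def resolved_residues(self) -> tuple[ResidueView, ...]:
        return tuple(r for r in self.residues if r.resolved)

    def atoms(self) -> Iterator[AtomRecord]:
        for r in self.residues:
            yield from r.atoms

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def get_residue(self, chain_id: str, residue_number: int) -> ResidueView | None:
        for r in self.residues:
            if r.chain_id == chain_id and r.residue_number == residue_number:
                return r
        return None

    def ss_label(self, residue: ResidueView) -> SecondaryStructure:
        """Secondary structure of a residue; loop when unannotated."""
        return self.secondary_structure.get(
            (residue.chain_id, residue.residue_number), LOOP
        )


# ---------------------------------------------------------------------------
# PDB reading


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # keep blank or 'A' conformer when present, otherwise highest occupancy
    for a in atoms:
        if a.altloc in ("\0", "", " "):
            return a
    for a in atoms:
        if a.altloc == "A":
            return a
    return max(atoms, key=lambda a: a.occ)


def _secondary_structure_map(
    st: gemmi.Structure, chain_ids: set[str]
) -> dict[tuple[str, int], SecondaryStructure]:
    ss: dict[tuple[str, int], SecondaryStructure] = {}
    for helix in st.helices:
        cid = helix.start.chain_name
        if cid not in chain_ids:
            continue
        for num in range(helix.start.res_id.seqid.num, helix.end.res_id.seqid.num + 1):
            ss[(cid, num)] = SecondaryStructure("helix")
    # strands across all sheets, numbered 1..N by first residue (per chain)
    per_chain: dict[str, list[tuple[int, int]]] = {}
    for sheet in st.sheets:
        for strand in sheet.strands:
            cid = strand.start.chain_name
            if cid not in chain_ids:
                continue
            per_chain.setdefault(cid, []).append(
                (strand.start.res_id.seqid.num, strand.end.res_id.seqid.num)
            )
    for cid, spans in per_chain.items():
        for idx, (lo, hi) in enumerate(sorted(set(spans)), start=1):
            for num in range(lo, hi + 1):
                ss[(cid, num)] = SecondaryStructure("strand", idx)
    return ss


def read_pdb(
    path: str | Path,
    chain_selector: str = "first",
    altloc_policy: str = "default",
    include_hetatm: bool = False,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Hydrogens and waters are always discarded; HETATM groups are skipped
    unless ``include_hetatm``.  One conformer is kept per atom: the blank or
    'A' altloc when present, otherwise the highest-occupancy one.  HELIX and
    SHEET header records populate secondary structure (strands numbered by
    first residue); SEQRES entries without coordinates become unresolved
    residues, assuming author numbering follows the SEQRES index (true for
    single-chain depositions numbered from 1).

    ``chain_selector`` is a chain id, ``"first"`` (default) or ``"all"``.
    """
    if altloc_policy != "default":
        raise ValueError("only the default altloc policy is implemented")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise IOError(f"no models in {path}")
    model = st[0]
    available = [ch.name for ch in model]
    if chain_selector == "all":
        wanted = available
    elif chain_selector == "first":
        wanted = available[:1]
    else:
        if chain_selector not in available:
            raise ValueError(
                f"chain {chain_selector!r} not in {path.name}; "
                f"available chains: {', '.join(available)}"
            )
        wanted = [chain_selector]

    seqres: dict[str, list[str]] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            names = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
            # PDB SEQRES entities are named after their chain
            seqres[ent.name] = names

    residues: list[ResidueView] = []
    serial = 0
    for ch in model:
        if ch.name not in wanted:
            continue
        seen_numbers: set[int] = set()
        for res in ch:
            if res.name == "HOH" or res.is_water():
                continue
            if res.het_flag == "H" and not include_hetatm:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in by_name.items():
                a = _select_altloc(group)
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=a.element.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=ch.name,
                        position=(a.pos.x, a.pos.y, a.pos.z),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                        altloc="" if a.altloc in ("\0", " ") else a.altloc,
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueView(
                    chain_id=ch.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    atoms=tuple(atoms),
                    insertion_code=icode,
                )
            )
            seen_numbers.add(res.seqid.num)
        if ch.name in seqres:
            for pos, name in enumerate(seqres[ch.name], start=1):
                if pos not in seen_numbers:
                    residues.append(
                        ResidueView(
                            chain_id=ch.name,
                            residue_number=pos,
                            residue_name=name,
                            atoms=(),
                            resolved=False,
                        )
                    )
        else:
            logger.warning(
                "no SEQRES for chain %s in %s; sequence limited to resolved residues",
                ch.name,
                path.name,
            )
    residues.sort(key=lambda r: (r.chain_id, r.residue_number, r.insertion_code))
    ss = _secondary_structure_map(st, set(wanted))
    return Structure(
        residues=tuple(residues),
        secondary_structure=ss,
        source_id=st.name or path.stem,
    )


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write resolved residues as ATOM records (fixed-width, 3-decimal coords).

    Secondary structure and SEQRES are not emitted; round-tripping preserves
    names, numbers and coordinates (to PDB precision), not annotations.
    """
    st = gemmi.Structure()
    st.name = structure.source_id or "surfcharge"
    model = gemmi.Model("1")
    for cid in structure.chain_ids:
        chain = gemmi.Chain(cid)
        for res in structure.residues:
            if res.chain_id != cid or not res.resolved:
                continue
            r = gemmi.Residue()
            r.name = res.residue_name
            r.seqid = gemmi.SeqId(res.residue_number, res.insertion_code or " ")
            r.het_flag = "A"
            for atom in res.atoms:
                a = gemmi.Atom()
                a.name = atom.name
                a.element = gemmi.Element(atom.element)
                a.pos = gemmi.Position(*atom.position)
                a.occ = atom.occupancy
                a.altloc = atom.altloc or "\0"
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Sequences


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter sequence with per-position author numbers and resolved flags."""

    sequence: str
    positions: tuple[int, ...]
    resolved: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.positions) == len(self.resolved)):
            raise ValueError("sequence, positions and resolved must align")

    def __str__(self) -> str:
        return self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


def extract_sequence(structure: Structure) -> ProteinSequence:
    """Sequence of the structure ordered by residue number (first chain only
    when several are present).  Unknown residue names map to ``'X'``."""
    if not structure.residues:
        raise ValueError("empty structure")
    chain = structure.chain_ids[0]
    res = [r for r in structure.residues if r.chain_id == chain]
    res.sort(key=lambda r: (r.residue_number, r.insertion_code))
    return ProteinSequence(
        sequence="".join(r.one_letter for r in res),
        positions=tuple(r.residue_number for r in res),
        resolved=tuple(r.resolved for r in res),
    )


def write_fasta(sequence: str | ProteinSequence, identifier: str, path: str | Path) -> None:
    """Write a single-record FASTA file, 60 columns per line."""
    seq = str(sequence)
    if not seq:
        raise ValueError("empty sequence")
    record = SeqRecord(Seq(seq), id=identifier or "unnamed", description="")
    with open(path, "w") as handle:
        SeqIO.write([record], handle, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {identifier: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
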