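"""Rule-based surface mutation planning (Lys -> Arg and general X -> Y).

The planning rules mirror how surface-charge variants of GFP are designed:

1. every solvent-exposed residue of the source type is a substitution
   candidate (buried residues are excluded outright);
2. candidates sitting on beta-strands of the folding-critical "superstable
   core" (strands 1, 3, 4, 5 and 6 in GFP) are backed out, because mutating
   them abolishes folding;
3. explicit position lists build bespoke variants directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .profiles import ResidueProfile, parse_residue_key
from .structure import ONE_TO_THREE, THREE_TO_ONE, ProteinSequence, Structure


def _one_letter(residue_type: str) -> str:
    """Accept 'K', 'LYS' or 'Lys' and return the one-letter code."""
    token = residue_type.strip().upper()
    if len(token) == 1:
        if token not in ONE_TO_THREE:
            raise ValueError(f"unknown residue type {residue_type!r}")
        return token
    if token not in THREE_TO_ONE:
        raise ValueError(f"unknown residue type {residue_type!r}")
    return THREE_TO_ONE[token]


@dataclass(frozen=True)
class Substitution:
    position: int
    from_type: str  # one-letter
    to_type: str  # one-letter

    def __str__(self) -> str:
        return f"{self.from_type}{self.position}{self.to_type}"


@dataclass(frozen=True)
class MutationPlan:
    """An ordered set of substitutions plus the positions ruled out, with reasons."""

    substitutions: tuple[Substitution, ...] = ()
    excluded: tuple[tuple[int, str], ...] = ()  # (position, reason)
    variant_name: str = ""

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate substitution positions")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)


@dataclass(frozen=True)
class CoreExclusionRule:
    """Back out substitutions on folding-core beta strands."""

    strand_indices: frozenset[int] = frozenset({1, 3, 4, 5, 6})
    reason: str = "superstable core"

    def __post_init__(self) -> None:
        if not self.strand_indices:
            raise ValueError("strand_indices must be non-empty")


def select_surface_targets(
    profiles: Sequence[ResidueProfile],
    from_type: str = "LYS",
    to_type: str = "ARG",
    variant_name: str = "",
) -> MutationPlan:
    """Plan a substitution at every exposed residue of ``from_type``.

    Buried residues of the type are recorded as excluded with reason
    ``"buried"``; residues with unknown exposure are excluded as such.
    """
    src, dst = _one_letter(from_type), _one_letter(to_type)
    subs: list[Substitution] = []
    excluded: list[tuple[int, str]] = []
    for p in sorted(profiles, key=lambda p: p.position):
        rtype, pos = parse_residue_key(p.residue)
        if rtype != src:
            continue
        label = p.exposure.lower()
        if label == "exposed":
            subs.append(Substitution(pos, src, dst))
        elif label == "buried":
            excluded.append((pos, "buried"))
        else:
            excluded.append((pos, "exposure unknown"))
    return MutationPlan(tuple(subs), tuple(excluded), variant_name)


def strand_indices_from_profiles(
    profiles: Sequence[ResidueProfile],
) -> dict[int, int]:
    """Position -> strand index map read off census secondary-structure labels."""
    return {
        p.position: p.strand_index
        for p in profiles
        if p.strand_index is not None
    }


def _strand_map(source: Structure | Mapping[int, int]) -> Mapping[int, int]:
    if isinstance(source, Structure):
        out: dict[int, int] = {}
        for res in source.residues:
            ss = source.ss_label(res)
            if ss.kind == "strand" and ss.index is not None:
                out[res.residue_number] = ss.index
        return out
    return source


def apply_core_exclusion(
    plan: MutationPlan,
    strands: Structure | Mapping[int, int],
    rule: CoreExclusionRule | None = None,
) -> MutationPlan:
    """Move substitutions on core strands into the excluded list.

    ``strands`` is a structure with strand-indexed secondary structure or an
    explicit {position: strand index} map (census labels can provide one via
    :func:`strand_indices_from_profiles`).  Idempotent.
    """
    rule = rule or CoreExclusionRule()
    strand_of = _strand_map(strands)
    if isinstance(strands, Structure) and not strand_of:
        raise ValueError(
            "structure carries no strand annotations; supply a "
            "{position: strand index} map instead"
        )
    kept: list[Substitution] = []
    excluded = list(plan.excluded)
    for sub in plan.substitutions:
        if strand_of.get(sub.position) in rule.strand_indices:
            excluded.append((sub.position, rule.reason))
        else:
            kept.append(sub)
    return replace(plan, substitutions=tuple(kept), excluded=tuple(excluded))


def plan_from_positions(
    sequence: str | ProteinSequence,
    positions: Iterable[int],
    to_type: str = "ARG",
    variant_name: str = "",
) -> MutationPlan:
    """Build an explicit plan; source types are read from the sequence."""
    seq = str(sequence)
    dst = _one_letter(to_type)
    subs = []
    for pos in sorted(set(positions)):
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
        subs.append(Substitution(pos, seq[pos - 1], dst))
    return MutationPlan(tuple(subs), (), variant_name)


def validate_plan(sequence: str | ProteinSequence, plan: MutationPlan) -> None:
    seq = str(sequence)
    for sub in plan.substitutions:
        if not 1 <= sub.position <= len(seq):
            raise ValueError(
                f"position {sub.position} outside sequence of length {len(seq)}"
            )
        actual = seq[sub.position - 1]
        if actual != sub.from_type:
            raise ValueError(
                f"substitution {sub} expects {sub.from_type} at position "
                f"{sub.position} but sequence has {actual}"
            )


def apply_mutations(sequence: str | ProteinSequence, plan: MutationPlan) -> str:
    """Apply a validated plan; returns a same-length variant sequence."""
    seq = str(sequence)
    validate_plan(seq, plan)
    chars = list(seq)
    for sub in plan.substitutions:
        chars[sub.position - 1] = sub.to_type
    return "".join(chars)
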