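"""Interaction-network diffs between a protein and a designed variant.

Interactions are compared as (basic-residue position, partner residue key)
pairs, so a mutated basic residue (K79 -> R79) still matches by position
while partner identities must agree exactly.  The ledger splits a pair of
censuses into *maintained* (in both), *lost* (only in the reference) and
*new* (only in the variant) sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .profiles import ResidueProfile

Entry = tuple[int, str]  # (basic residue position, partner residue key)


@dataclass(frozen=True)
class DiffLedger:
    """Maintained/lost/new interaction sets for one interaction kind."""

    kind: str
    maintained: frozenset[Entry]
    lost: frozenset[Entry]
    new: frozenset[Entry]

    @property
    def n_maintained(self) -> int:
        return len(self.maintained)

    @property
    def n_lost(self) -> int:
        return len(self.lost)

    @property
    def n_new(self) -> int:
        return len(self.new)

    @property
    def n_reference(self) -> int:
        """Interactions in the reference census (maintained + lost)."""
        return self.n_maintained + self.n_lost

    @property
    def n_variant(self) -> int:
        """Interactions in the variant census (maintained + new)."""
        return self.n_maintained + self.n_new

    def summary_line(self) -> str:
        return (
            f"{self.kind}: maintained {self.n_maintained} "
            f"lost {self.n_lost} new {self.n_new}"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"status": status, "position": pos, "partner": partner}
            for status, entries in (
                ("maintained", self.maintained),
                ("lost", self.lost),
                ("new", self.new),
            )
            for pos, partner in sorted(entries)
        ]
        return pd.DataFrame(rows, columns=["status", "position", "partner"])


def _entries(profiles: Sequence[ResidueProfile], kind: str) -> set[Entry]:
    seen_positions: set[int] = set()
    entries: set[Entry] = set()
    for p in profiles:
        if p.position in seen_positions:
            raise ValueError(f"duplicate position {p.position} in profile list")
        seen_positions.add(p.position)
        partners = (
            p.salt_bridge_partners if kind == "salt_bridge" else p.hbond_partners
        )
        for partner in partners:
            entries.add((p.position, partner))
    return entries


def diff_interactions(
    profiles_a: Sequence[ResidueProfile],
    profiles_b: Sequence[ResidueProfile],
    kind: str = "salt_bridge",
) -> DiffLedger:
    """Diff two censuses; ``kind`` is ``salt_bridge`` or ``hydrogen_bond``."""
    if kind not in ("salt_bridge", "hydrogen_bond"):
        raise ValueError(f"bad interaction kind {kind!r}")
    a = _entries(profiles_a, kind)
    b = _entries(profiles_b, kind)
    return DiffLedger(
        kind=kind,
        maintained=frozenset(a & b),
        lost=frozenset(a - b),
        new=frozenset(b - a),
    )


def annotate_new(
    ledger: DiffLedger, profiles_b: Sequence[ResidueProfile]
) -> pd.DataFrame:
    """Variant census rows with newly formed interactions starred.

    Mirrors the asterisk convention of comparison tables: each partner in the
    ledger's ``new`` set is rendered ``"E6*"``; everything else is unmarked.
    """
    rows = []
    for p in sorted(profiles_b, key=lambda p: p.position):
        partners = (
            p.salt_bridge_partners
            if ledger.kind == "salt_bridge"
            else p.hbond_partners
        )
        marked = [
            partner + ("*" if (p.position, partner) in ledger.new else "")
            for partner in partners
        ]
        rows.append(
            {
                "residue": p.residue,
                "position": p.position,
                "partners": ";".join(marked),
                "n_new": sum(1 for m in marked if m.endswith("*")),
            }
        )
    return pd.DataFrame(rows, columns=["residue", "position", "partners", "n_new"])
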