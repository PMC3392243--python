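"""Per-residue interaction profiles and census summary statistics.

A profile is one row of the classical basic-residue census table: the
residue, its exposure and secondary-structure labels, and its salt-bridge
and hydrogen-bond partners at residue granularity.  Summaries count
residue-level partners (a complex salt bridge with two partners counts
two) and report means per residue of each type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .accessibility import ExposureResult
from .interactions import InteractionRecord, deduplicate
from .structure import (
    ONE_TO_THREE,
    THREE_TO_ONE,
    ProteinSequence,
    SecondaryStructure,
    Structure,
    extract_sequence,
)

_RESIDUE_KEY = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]?)\*?$")
_STRAND = re.compile(r"(?:β-strand|beta-strand|strand)\s*(\d+)?", re.IGNORECASE)

PROFILE_COLUMNS = [
    "residue",
    "exposure",
    "secondary_structure",
    "salt_bridge_partners",
    "hbond_partners",
]


def parse_residue_key(key: str) -> tuple[str, int]:
    """Split a key like ``"K45"`` (optionally starred) into type and number."""
    m = _RESIDUE_KEY.match(key.strip())
    if not m:
        raise ValueError(f"malformed residue key {key!r}")
    return m.group(1).upper(), int(m.group(2))


@dataclass(frozen=True)
class ResidueProfile:
    """One census row for a basic residue."""

    residue: str  # e.g. "K45"
    exposure: str = "Unknown"  # {Exposed, Buried, Unknown}
    secondary_structure: str = "Loop"
    salt_bridge_partners: tuple[str, ...] = ()
    hbond_partners: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        parse_residue_key(self.residue)
        for partners in (self.salt_bridge_partners, self.hbond_partners):
            if len(set(partners)) != len(partners):
                raise ValueError(f"duplicate partners in profile {self.residue}")

    @property
    def residue_type(self) -> str:
        one, _ = parse_residue_key(self.residue)
        return ONE_TO_THREE.get(one, "UNK")

    @property
    def position(self) -> int:
        return parse_residue_key(self.residue)[1]

    @property
    def strand_index(self) -> int | None:
        m = _STRAND.search(self.secondary_structure)
        if m and m.group(1):
            return int(m.group(1))
        return None

    @property
    def ss_kind(self) -> str:
        ss = self.secondary_structure.lower()
        if "helix" in ss:
            return "helix"
        if "strand" in ss or "sheet" in ss:
            return "strand"
        return "loop"


def build_profiles(
    structure: Structure,
    exposure_results: Sequence[ExposureResult],
    interaction_records: Iterable[InteractionRecord],
    basic_types: tuple[str, ...] = ("LYS", "ARG"),
) -> list[ResidueProfile]:
    """Assemble one profile per basic residue of the structure's sequence,
    including unresolved ones (which get empty partner sets)."""
    exposure_by_key = {(e.chain_id, e.residue_number): e for e in exposure_results}
    dedup = deduplicate(interaction_records)
    sb: dict[str, list[str]] = {}
    hb: dict[str, list[str]] = {}
    for rec in dedup:
        target = sb if rec.kind == "salt_bridge" else hb
        target.setdefault(rec.basic_residue, []).append(rec.partner_residue)
    profiles = []
    chain = structure.chain_ids[0]
    for res in sorted(
        (r for r in structure.residues if r.chain_id == chain),
        key=lambda r: r.residue_number,
    ):
        if res.residue_name not in basic_types:
            continue
        exp = exposure_by_key.get((res.chain_id, res.residue_number))
        profiles.append(
            ResidueProfile(
                residue=res.key,
                exposure=exp.label.capitalize() if exp else "Unknown",
                secondary_structure=str(structure.ss_label(res)),
                salt_bridge_partners=tuple(sb.get(res.key, ())),
                hbond_partners=tuple(hb.get(res.key, ())),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Composition


def composition(sequence: str | ProteinSequence) -> pd.DataFrame:
    """Amino-acid counts and percentages (100*count/length) of a sequence.

    Returns a DataFrame indexed by one-letter code with ``count``, ``percent``
    (full precision) and ``percent_1dp`` (as printed, one decimal).
    """
    seq = str(sequence)
    if not seq:
        raise ValueError("empty sequence")
    letters = sorted(THREE_TO_ONE.values())
    counts = {aa: seq.count(aa) for aa in letters}
    df = pd.DataFrame({"count": pd.Series(counts)})
    df["percent"] = 100.0 * df["count"] / len(seq)
    df["percent_1dp"] = df["percent"].map(lambda p: float(round_half_up(p, 1)))
    df.index.name = "residue"
    return df


# ---------------------------------------------------------------------------
# Summary


def round_half_up(value: float, decimals: int = 2) -> Decimal:
    """Round half away from zero (what a bench scientist means by rounding)."""
    q = Decimal(10) ** -decimals
    return Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)


def truncate(value: float, decimals: int = 2) -> Decimal:
    """Truncate toward zero at the given number of decimals."""
    q = 10**decimals
    return Decimal(int(value * q)) / Decimal(q)


def format_mean(value: float | None, decimals: int = 2, mode: str = "round") -> str:
    """Format a mean the way census tables print it.

    ``mode="round"`` rounds half away from zero; ``mode="truncate"`` chops,
    which reproduces printed values that were truncated rather than rounded
    (4/6 -> "0.66").
    """
    if value is None:
        return "-"
    if mode == "round":
        return f"{round_half_up(value, decimals):.{decimals}f}"
    if mode == "truncate":
        return f"{truncate(value, decimals):.{decimals}f}"
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class TypeSummary:
    """Census statistics for one residue type."""

    residue_type: str
    count: int
    exposed: int
    total_salt_bridges: int
    total_hbonds: int
    mean_salt_bridges: float | None
    mean_hbonds: float | None
    #: means over residues with at least one partner of that kind
    mean_salt_bridges_interacting: float | None
    mean_hbonds_interacting: float | None
    ss_tally: Mapping[str, int]


@dataclass(frozen=True)
class CensusSummary:
    per_type: Mapping[str, TypeSummary]

    def __getitem__(self, residue_type: str) -> TypeSummary:
        return self.per_type[residue_type]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.per_type.values():
            rows.append(
                {
                    "residue_type": t.residue_type,
                    "count": t.count,
                    "exposed": t.exposed,
                    "total_salt_bridges": t.total_salt_bridges,
                    "total_hbonds": t.total_hbonds,
                    "mean_salt_bridges": t.mean_salt_bridges,
                    "mean_hbonds": t.mean_hbonds,
                    "helix": t.ss_tally.get("helix", 0),
                    "strand": t.ss_tally.get("strand", 0),
                    "loop": t.ss_tally.get("loop", 0),
                }
            )
        return pd.DataFrame(rows).set_index("residue_type")


def _mean(total: int, count: int) -> float | None:
    return total / count if count else None


def summarize(profiles: Sequence[ResidueProfile]) -> CensusSummary:
    """Count residue-level partners per type and derive the census means."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    per_type: dict[str, TypeSummary] = {}
    types = sorted({p.residue_type for p in profiles})
    for rtype in types:
        rows = [p for p in profiles if p.residue_type == rtype]
        sb_total = sum(len(p.salt_bridge_partners) for p in rows)
        hb_total = sum(len(p.hbond_partners) for p in rows)
        sb_active = sum(1 for p in rows if p.salt_bridge_partners)
        hb_active = sum(1 for p in rows if p.hbond_partners)
        tally: dict[str, int] = {}
        for p in rows:
            tally[p.ss_kind] = tally.get(p.ss_kind, 0) + 1
        per_type[rtype] = TypeSummary(
            residue_type=rtype,
            count=len(rows),
            exposed=sum(1 for p in rows if p.exposure.lower() == "exposed"),
            total_salt_bridges=sb_total,
            total_hbonds=hb_total,
            mean_salt_bridges=_mean(sb_total, len(rows)),
            mean_hbonds=_mean(hb_total, len(rows)),
            mean_salt_bridges_interacting=_mean(sb_total, sb_active),
            mean_hbonds_interacting=_mean(hb_total, hb_active),
            ss_tally=tally,
        )
    return CensusSummary(per_type=per_type)


# ---------------------------------------------------------------------------
# Tabular I/O


def _clean_partner(token: str) -> str:
    token = token.strip().rstrip("*")
    if token:
        parse_residue_key(token)
    return token


def _split_partners(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text or text in ("-", "—"):
        return ()
    return tuple(_clean_partner(tok) for tok in re.split(r"[;,]", text) if tok.strip())


def read_profile_table(path: str | Path) -> list[ResidueProfile]:
    """Read census rows from TSV (columns: residue, exposure,
    secondary_structure, salt_bridge_partners, hbond_partners; partner lists
    separated by ``;``).  Stars marking new interactions are stripped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    profiles = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            profiles.append(
                ResidueProfile(
                    residue=row.residue.strip(),
                    exposure=(row.exposure.strip() or "Unknown").capitalize(),
                    secondary_structure=row.secondary_structure.strip() or "Loop",
                    salt_bridge_partners=_split_partners(row.salt_bridge_partners),
                    hbond_partners=_split_partners(row.hbond_partners),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return profiles


def write_profile_table(profiles: Sequence[ResidueProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [p.residue for p in profiles],
            "exposure": [p.exposure for p in profiles],
            "secondary_structure": [p.secondary_structure for p in profiles],
            "salt_bridge_partners": [";".join(p.salt_bridge_partners) for p in profiles],
            "hbond_partners": [";".join(p.hbond_partners) for p in profiles],
        }
    )
    df.to_csv(path, sep="\t", index=False)
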