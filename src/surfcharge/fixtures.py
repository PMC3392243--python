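"""Synthetic inputs with known ground truth.

Three generators make every stage of the pipeline testable without any
download:

* :func:`make_toy_structure` builds small structures in which chosen
  basic/partner atom pairs sit at *exactly* specified distances (on the
  0.001-angstrom PDB coordinate grid, so distances survive a PDB
  round-trip), with enough backbone per residue for the detectors'
  donor/acceptor logic to engage;
* :func:`gfp_table_fixtures` loads the packaged transcriptions of the GFP
  basic-residue censuses (wild-type crystal census; energy-minimised
  control vs 14-arginine variant comparison) as profile lists;
* :func:`simulate_decay` produces first-order fluorescence decay traces
  with a known half-life and optional Gaussian noise.

Toy structures use idealised local geometry: chemical realism is not a
goal, geometric ground truth is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .interactions import ACIDIC_ATOMS, BASIC_ATOMS, SIDECHAIN_ACCEPTORS
from .kinetics import AssayTrace
from .profiles import ResidueProfile, read_profile_table
from .structure import AtomRecord, ResidueView, Structure

# ---------------------------------------------------------------------------
# Toy structures with planted interactions

#: Local atom templates: CA at the origin, the side chain extending toward +x.
#: Coordinates are idealised, on the 0.001 A grid.
_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "LYS": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("CG", "C", (2.400, 0.000, 0.200)),
        ("CD", "C", (3.600, 0.600, 0.700)),
        ("CE", "C", (4.800, 0.000, 0.200)),
        ("NZ", "N", (6.000, 0.000, 0.000)),
    ],
    "ARG": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("CG", "C", (2.400, 0.000, 0.200)),
        ("CD", "C", (3.600, 0.600, 0.700)),
        ("NE", "N", (4.700, 0.000, 0.000)),
        ("CZ", "C", (6.000, 0.400, 0.000)),
        ("NH1", "N", (7.100, 0.000, 0.000)),  # points at the partner
        ("NH2", "N", (6.100, 1.750, 0.000)),
    ],
    "ASP": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("CG", "C", (2.400, 0.000, 0.200)),
        ("OD1", "O", (3.600, 0.000, 0.000)),  # points at the basic residue
        ("OD2", "O", (2.500, -1.300, 0.600)),
    ],
    "GLU": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("CG", "C", (2.400, 0.000, 0.200)),
        ("CD", "C", (3.600, 0.600, 0.700)),
        ("OE1", "O", (4.800, 0.000, 0.000)),
        ("OE2", "O", (3.700, 1.850, 0.900)),
    ],
    "SER": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("OG", "O", (2.400, 0.000, 0.000)),
    ],
    "ASN": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("CG", "C", (2.400, 0.000, 0.200)),
        ("OD1", "O", (3.600, 0.000, 0.000)),
        ("ND2", "N", (2.500, -1.300, 0.600)),
    ],
    "MET": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),  # backbone O: common acceptor target
        ("CB", "C", (1.200, 0.600, 0.700)),
        ("CG", "C", (2.400, 0.000, 0.200)),
        # side chain stretched away from the backbone O so the SD acceptor
        # cannot wander into a planted backbone-O contact window
        ("SD", "S", (5.000, 0.800, 0.800)),
        ("CE", "C", (6.300, 0.000, 0.200)),
    ],
    "ALA": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
        ("CB", "C", (1.200, 0.600, 0.700)),
    ],
    "GLY": [
        ("N", "N", (-1.900, 1.200, 0.000)),
        ("CA", "C", (0.000, 0.000, 0.000)),
        ("C", "C", (-0.900, -1.200, 0.300)),
        ("O", "O", (-2.100, -1.300, 0.300)),
    ],
}

_DEFAULT_BASIC_ATOM = {"LYS": "NZ", "ARG": "NH1"}
_DEFAULT_PARTNER_ATOM = {"ASP": "OD1", "GLU": "OE1"}


@dataclass(frozen=True)
class PlantedPair:
    """One interaction to plant: which atoms, at what distance."""

    kind: str  # {salt_bridge, hydrogen_bond}
    basic_residue: str = "LYS"
    partner_residue: str = "ASP"
    distance: float = 3.5
    basic_atom: str | None = None  # default: NZ / NH1; "N" plants a backbone donor
    partner_atom: str | None = None  # default: OD1/OE1, else backbone "O"

    def resolved_atoms(self) -> tuple[str, str]:
        b = self.basic_atom or _DEFAULT_BASIC_ATOM[self.basic_residue]
        p = self.partner_atom or _DEFAULT_PARTNER_ATOM.get(self.partner_residue, "O")
        return b, p


@dataclass(frozen=True)
class PlantedInteractionSpec:
    pairs: tuple[PlantedPair, ...]
    spacing: float = 30.0  # angstrom between planted pair rows
    jitter: float = 0.0  # gaussian SD applied to non-key atoms
    seed: int | None = None

    def __post_init__(self) -> None:
        for pair in self.pairs:
            if pair.distance <= 1.5:
                raise ValueError("target distances must exceed 1.5 angstrom")
        if self.jitter > 0 and self.seed is None:
            raise ValueError("seed is mandatory when jitter > 0")


def _snap(v: float) -> float:
    return round(v, 3)


def _place(
    template: Sequence[tuple[str, str, tuple[float, float, float]]],
    key_atom: str,
    key_position: np.ndarray,
    mirror_x: bool,
    rotation: float,
    jitter: float,
    rng: np.random.Generator | None,
) -> dict[str, tuple[str, tuple[float, float, float]]]:
    """Place a residue template so ``key_atom`` lands exactly on
    ``key_position``; other atoms may be rotated about the x axis through the
    key atom and jittered.  Only the key atom is guaranteed on-grid."""
    names = [n for n, _, _ in template]
    if key_atom not in names:
        raise ValueError(f"template has no atom {key_atom!r}")
    coords = {n: np.array(xyz) for n, _, xyz in template}
    elements = {n: e for n, e, _ in template}
    if mirror_x:
        for n in coords:
            coords[n] = coords[n] * np.array([-1.0, 1.0, 1.0])
    origin = coords[key_atom].copy()
    cos, sin = math.cos(rotation), math.sin(rotation)
    out: dict[str, tuple[str, tuple[float, float, float]]] = {}
    for n in names:
        rel = coords[n] - origin
        if n != key_atom:
            y, z = rel[1], rel[2]
            rel = np.array([rel[0], cos * y - sin * z, sin * y + cos * z])
            if jitter > 0 and rng is not None:
                rel = rel + rng.normal(0.0, jitter, size=3)
        pos = key_position + rel
        if n == key_atom:
            pos = key_position  # exactly on grid
        out[n] = (elements[n], (_snap(pos[0]), _snap(pos[1]), _snap(pos[2])))
    return out


def make_toy_structure(spec: PlantedInteractionSpec) -> Structure:
    """Build a structure whose only close contacts are the planted pairs.

    Pair *i* occupies its own row at y = i * spacing: the basic residue's key
    atom sits at (0, y, 0) and the partner's key atom at (distance, y, 0),
    both exactly on the PDB coordinate grid, so the planted distance is exact
    even after a write/read round-trip.  Residue numbers are spaced so the
    sequence-adjacency exclusion never triggers.  Raises when a planted
    residue type has no template or the placement is infeasible.
    """
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    residues: list[ResidueView] = []
    serial = 0
    for i, pair in enumerate(spec.pairs):
        if pair.basic_residue not in _TEMPLATES:
            raise ValueError(f"no template for residue type {pair.basic_residue!r}")
        if pair.partner_residue not in _TEMPLATES:
            raise ValueError(f"no template for residue type {pair.partner_residue!r}")
        basic_atom, partner_atom = pair.resolved_atoms()
        y = _snap(i * spec.spacing)
        rot_b = rng.uniform(0, 2 * math.pi) if rng is not None else 0.0
        rot_p = rng.uniform(0, 2 * math.pi) if rng is not None else 0.0
        # Each residue's side chain must point away from the other residue
        # unless it carries the contact atom: mirror the basic residue when
        # it donates through its backbone N, and mirror the partner only
        # when the contact atom is in its side chain (a backbone O contact
        # leaves the partner side chain trailing off to +x).
        placed_b = _place(
            _TEMPLATES[pair.basic_residue], basic_atom,
            np.array([0.0, y, 0.0]), mirror_x=(basic_atom == "N"),
            rotation=rot_b, jitter=spec.jitter, rng=rng,
        )
        placed_p = _place(
            _TEMPLATES[pair.partner_residue], partner_atom,
            np.array([_snap(pair.distance), y, 0.0]),
            mirror_x=partner_atom not in ("O", "N"),
            rotation=rot_p, jitter=spec.jitter, rng=rng,
        )
        for resname, number, placed in (
            (pair.basic_residue, 10 * i + 5, placed_b),
            (pair.partner_residue, 10 * i + 10, placed_p),
        ):
            atoms = []
            for name, (element, xyz) in placed.items():
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=element,
                        residue_name=resname,
                        residue_number=number,
                        chain_id="A",
                        position=xyz,
                    )
                )
            residues.append(
                ResidueView(
                    chain_id="A",
                    residue_number=number,
                    residue_name=resname,
                    atoms=tuple(atoms),
                )
            )
    structure = Structure(residues=tuple(residues), source_id="toy")
    _check_no_spurious_contacts(structure, spec)
    return structure


def _check_no_spurious_contacts(
    structure: Structure, spec: PlantedInteractionSpec
) -> None:
    """Reject placements where jitter or geometry created unplanned contacts
    between key-capable atoms of *different* pairs (infeasible spec)."""
    rows: dict[int, int] = {}
    for i, pair in enumerate(spec.pairs):
        rows[10 * i + 5] = i
        rows[10 * i + 10] = i
    names_of_interest = {"NZ", "NE", "NH1", "NH2", "N", "O", "OD1", "OD2",
                         "OE1", "OE2", "OG", "OG1", "SD", "SG"}
    atoms = [
        a
        for r in structure.resolved_residues()
        for a in r.atoms
        if a.name in names_of_interest
    ]
    cutoff = 4.0
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            if rows[a.residue_number] == rows[b.residue_number]:
                continue
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d <= cutoff:
                raise ValueError(
                    f"infeasible spec: atoms {a.name}/{b.name} of different "
                    f"pairs are {d:.2f} angstrom apart; increase spacing"
                )


# ---------------------------------------------------------------------------
# Packaged census transcriptions

_DATA_FILES = {
    "table1": "table1_gfp.tsv",
    "gfp_con": "table3_gfp_con.tsv",
    "gfp14r": "table3_gfp14r.tsv",
}


def data_path(name: str):
    """Path to a packaged data file (context-manager friendly Traversable)."""
    return resources.files("surfcharge.data").joinpath(name)


def gfp_table_fixtures() -> dict[str, list[ResidueProfile]]:
    """Packaged transcriptions of the GFP basic-residue censuses.

    Keys: ``table1`` (26 rows: wild-type crystal census), ``gfp_con`` and
    ``gfp14r`` (19 rows each: the energy-minimised control and the
    14-arginine variant, positions aligned).  Stars that mark new
    interactions in the source table are stripped by the profile reader.
    """
    out = {}
    for key, filename in _DATA_FILES.items():
        with resources.as_file(data_path(filename)) as path:
            out[key] = read_profile_table(path)
    return out


def gfp_sequence() -> str:
    """The 238-residue wild-type GFP sequence (20 Lys, 6 Arg)."""
    text = data_path("avgfp.fasta").read_text()
    return "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )


def gfp_half_life_table():
    """Measured half-lives of the GFP variants in ionic detergents."""
    import pandas as pd

    with resources.as_file(data_path("table2_half_lives.tsv")) as path:
        return pd.read_csv(path, sep="\t")


#: Strand indices of the surface lysines as annotated in the census
#: (back-mutation set {41, 45, 107, 113, 126} follows from strands {3, 5, 6}).
GFP_CORE_BACKMUTATIONS = (41, 45, 107, 113, 126)
GFP6R_POSITIONS = (3, 52, 79, 131, 140, 209)


# ---------------------------------------------------------------------------
# Decay simulation


@dataclass(frozen=True)
class DecaySimSpec:
    """Ground truth for simulated first-order fluorescence decay."""

    t_half: float  # minutes
    times: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    noise_sd: float = 0.0  # percent-points
    replicates: int = 1
    seed: int | None = None
    condition: str = ""
    variant: str = ""

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be positive")
        t = np.asarray(self.times)
        if t.size < 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ValueError("time grid must be strictly increasing")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("seed is mandatory when noise_sd > 0")


def simulate_decay(spec: DecaySimSpec) -> list[AssayTrace]:
    """Simulate ``signal = 100 * exp(-ln2 * t / t_half) + N(0, noise_sd)``,
    clipped at zero; reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    clean = 100.0 * np.exp(-math.log(2.0) * t / spec.t_half)
    traces = []
    for rep in range(spec.replicates):
        noisy = clean.copy()
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=t.size)
        noisy = np.clip(noisy, 0.0, None)
        traces.append(
            AssayTrace(
                times=tuple(t),
                signal=tuple(float(v) for v in noisy),
                condition=spec.condition,
                variant=spec.variant,
                replicate=str(rep + 1),
            )
        )
    return traces
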