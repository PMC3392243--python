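"""Solvent accessible surface area (SASA) and exposed/buried classification.

SASA is computed with the Shrake-Rupley rolling-probe method on a
*deterministic* golden-spiral point set, so exposed/buried labels are exactly
reproducible run to run.  A residue's side chain is called *exposed* when its
side-chain SASA exceeds 25% of a residue-type reference maximum (strict
inequality, i.e. "more than 25%").

The shipped reference maxima are derived from the theoretical maximum-ASA
scale of Tien et al. (2013) by subtracting its glycine value (104 A^2) as a
backbone allowance; glycine itself, whose CA serves as the side-chain proxy,
gets the alanine-minus-glycine increment.  The table is configurable, as is
the van der Waals radius set (Bondi-type single-atom radii by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueView, Structure

logger = logging.getLogger(__name__)

#: van der Waals radii (angstrom) per element; unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_VDW = 1.70

#: Theoretical maximum total ASA per residue type (A^2), Tien et al. 2013.
MAX_TOTAL_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Side-chain reference maxima: total minus the glycine backbone allowance.
MAX_SIDECHAIN_ASA: dict[str, float] = {
    name: round(total - MAX_TOTAL_ASA["GLY"], 1)
    for name, total in MAX_TOTAL_ASA.items()
    if name != "GLY"
}
MAX_SIDECHAIN_ASA["GLY"] = round(MAX_TOTAL_ASA["ALA"] - MAX_TOTAL_ASA["GLY"], 1)

#: Key identifying one atom: (chain id, residue number key, atom name).
AtomKey = tuple[str, str, str]


@dataclass(frozen=True)
class ExposureCriteria:
    """Parameters of the exposed/buried call."""

    probe_radius: float = 1.4
    sphere_points: int = 960
    threshold: float = 0.25
    reference_table: Mapping[str, float] = field(
        default_factory=lambda: dict(MAX_SIDECHAIN_ASA)
    )
    unresolved_policy: str = "exposed"  # {exposed, buried, unknown}

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.sphere_points < 60:
            raise ValueError("sphere_points must be >= 60")
        if self.unresolved_policy not in ("exposed", "buried", "unknown"):
            raise ValueError(f"bad unresolved_policy {self.unresolved_policy!r}")


@dataclass(frozen=True)
class ExposureResult:
    """Exposure call for one residue."""

    chain_id: str
    residue_key: str
    residue_name: str
    residue_number: int
    sidechain_sasa: float
    relative_fraction: float  # NaN for unresolved/unknown residues
    label: str  # {exposed, buried, unknown}


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (Fibonacci lattice).

    Deterministic by construction: no random number generator is involved.
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> dict[AtomKey, float]:
    """Per-atom Shrake-Rupley SASA (A^2) for all resolved atoms.

    A test point on an atom's solvent-extended sphere counts as accessible
    when it lies outside every neighbour's extended sphere; the atom's SASA
    is the accessible fraction of its sphere area.
    """
    vdw = dict(VDW_RADII)
    if radii:
        vdw.update(radii)
    atoms = [a for r in structure.resolved_residues() for a in r.atoms]
    if not atoms:
        raise ValueError("structure has no resolved atoms")
    coords = np.array([a.position for a in atoms], dtype=float)
    ext = np.array(
        [vdw.get(a.element, DEFAULT_VDW) + probe_radius for a in atoms], dtype=float
    )
    unit = golden_spiral_points(sphere_points)
    tree = cKDTree(coords)
    max_ext = float(ext.max())
    sasa: dict[AtomKey, float] = {}
    keyed = [
        (a.chain_id, f"{a.residue_number}", a.name) for a in atoms
    ]
    for i, atom in enumerate(atoms):
        neighbours = [
            j for j in tree.query_ball_point(coords[i], ext[i] + max_ext) if j != i
        ]
        points = coords[i] + ext[i] * unit  # (n, 3)
        if neighbours:
            nb = np.asarray(neighbours)
            diff = points[:, None, :] - coords[nb][None, :, :]
            inside = (diff * diff).sum(axis=2) < (ext[nb] ** 2)[None, :]
            accessible = ~inside.any(axis=1)
        else:
            accessible = np.ones(sphere_points, dtype=bool)
        area = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
        sasa[keyed[i]] = float(area)
    return sasa


def residue_sasa(
    residue: ResidueView, sasa_map: Mapping[AtomKey, float], sidechain_only: bool = True
) -> float:
    """Sum of per-atom SASA over a residue (side chain by default)."""
    atoms = residue.sidechain_atoms() if sidechain_only else residue.atoms
    return float(
        sum(sasa_map[(a.chain_id, f"{a.residue_number}", a.name)] for a in atoms)
    )


def classify_exposure(
    structure: Structure,
    sasa_map: Mapping[AtomKey, float],
    criteria: ExposureCriteria | None = None,
) -> list[ExposureResult]:
    """Label each residue exposed/buried from its relative side-chain SASA.

    ``relative_fraction`` is side-chain SASA over the residue type's reference
    maximum; it may exceed 1 for highly exposed residues.  Unresolved residues
    (no coordinates) are labelled per ``criteria.unresolved_policy`` --
    ``exposed`` by default, since disordered termini are solvent accessible.
    """
    crit = criteria or ExposureCriteria()
    results: list[ExposureResult] = []
    for res in structure.residues:
        if not res.resolved:
            results.append(
                ExposureResult(
                    chain_id=res.chain_id,
                    residue_key=res.key,
                    residue_name=res.residue_name,
                    residue_number=res.residue_number,
                    sidechain_sasa=0.0,
                    relative_fraction=float("nan"),
                    label=crit.unresolved_policy,
                )
            )
            continue
        if not res.atoms:
            logger.warning("residue %s has no atoms; skipped", res.key)
            continue
        reference = crit.reference_table.get(res.residue_name)
        sc_sasa = residue_sasa(res, sasa_map, sidechain_only=True)
        if reference is None:
            warnings.warn(
                f"residue type {res.residue_name} missing from reference table",
                stacklevel=2,
            )
            fraction, label = float("nan"), "unknown"
        else:
            fraction = sc_sasa / reference
            label = "exposed" if fraction > crit.threshold else "buried"
        results.append(
            ExposureResult(
                chain_id=res.chain_id,
                residue_key=res.key,
                residue_name=res.residue_name,
                residue_number=res.residue_number,
                sidechain_sasa=sc_sasa,
                relative_fraction=fraction,
                label=label,
            )
        )
    return results
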