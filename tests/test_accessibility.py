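"""Shrake-Rupley SASA and exposure classification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from surfcharge import fixtures
from surfcharge.accessibility import (
    ExposureCriteria,
    MAX_SIDECHAIN_ASA,
    VDW_RADII,
    classify_exposure,
    compute_sasa,
    golden_spiral_points,
    residue_sasa,
)
from surfcharge.structure import AtomRecord, ResidueView, Structure


def _carbon(serial: int, xyz, resnum: int | None = None, name: str = "CA") -> AtomRecord:
    num = resnum if resnum is not None else serial
    return AtomRecord(serial, name, "C", "ALA", num, "A", tuple(xyz))


def _structure_of(atoms_by_residue: dict[int, list[AtomRecord]]) -> Structure:
    residues = tuple(
        ResidueView("A", num, atoms[0].residue_name, tuple(atoms))
        for num, atoms in sorted(atoms_by_residue.items())
    )
    return Structure(residues=residues)


def _single_atom_structure() -> Structure:
    return _structure_of({1: [_carbon(1, (0.0, 0.0, 0.0))]})


class TestSpherePoints:
    def test_points_lie_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        assert np.array_equal(golden_spiral_points(240), golden_spiral_points(240))


class TestComputeSasa:
    def test_isolated_atom_matches_closed_form(self):
        """A lone carbon's SASA is the full extended-sphere area 4*pi*(r+probe)^2."""
        sasa = compute_sasa(_single_atom_structure())
        expected = 4.0 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert sasa[("A", "1", "CA")] == pytest.approx(expected, rel=0.01)

    def test_fully_caged_atom_has_zero_sasa(self):
        """An atom enclosed by 26 tight neighbours is completely occluded."""
        atoms = {1: [_carbon(1, (0.0, 0.0, 0.0))]}
        serial = 2
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    v = np.array([dx, dy, dz], dtype=float)
                    v = 2.0 * v / np.linalg.norm(v)
                    atoms[serial] = [_carbon(serial, v)]
                    serial += 1
        sasa = compute_sasa(_structure_of(atoms))
        assert sasa[("A", "1", "CA")] == pytest.approx(0.0, abs=1e-9)

    def test_two_distant_atoms_have_equal_sasa(self):
        st = _structure_of({1: [_carbon(1, (0, 0, 0))], 2: [_carbon(2, (50, 0, 0))]})
        sasa = compute_sasa(st)
        assert sasa[("A", "1", "CA")] == pytest.approx(sasa[("A", "2", "CA")])

    def test_rotation_invariance(self):
        """SASA changes by <0.5% under a rigid rotation of the structure."""
        spec = fixtures.PlantedInteractionSpec(
            pairs=(
                fixtures.PlantedPair("salt_bridge", "LYS", "ASP", 3.5),
                fixtures.PlantedPair("hydrogen_bond", "ARG", "MET", 2.9,
                                     partner_atom="O"),
            )
        )
        toy = fixtures.make_toy_structure(spec)
        angle = 0.7
        rot = np.array(
            [
                [math.cos(angle), -math.sin(angle), 0.0],
                [math.sin(angle), math.cos(angle), 0.0],
                [0.0, 0.0, 1.0],
            ]
        ) @ np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(1.1), -math.sin(1.1)],
                [0.0, math.sin(1.1), math.cos(1.1)],
            ]
        )
        rotated = Structure(
            residues=tuple(
                ResidueView(
                    r.chain_id,
                    r.residue_number,
                    r.residue_name,
                    tuple(
                        AtomRecord(
                            a.serial, a.name, a.element, a.residue_name,
                            a.residue_number, a.chain_id,
                            tuple(rot @ a.xyz + np.array([3.0, -2.0, 5.0])),
                        )
                        for a in r.atoms
                    ),
                )
                for r in toy.residues
            )
        )
        # per-atom values are quantized at ~4*pi*(r+probe)^2/n per sphere
        # point, so the 0.5% invariance check applies at residue and whole-
        # structure granularity, with n large enough for that tolerance
        before = compute_sasa(toy, sphere_points=4000)
        after = compute_sasa(rotated, sphere_points=4000)
        for res in toy.resolved_residues():
            assert residue_sasa(res, after, sidechain_only=False) == pytest.approx(
                residue_sasa(res, before, sidechain_only=False), rel=5e-3
            )
        assert sum(after.values()) == pytest.approx(
            sum(before.values()), rel=5e-3
        )

    def test_adding_occluder_never_increases_sasa(self):
        spec = fixtures.PlantedInteractionSpec(
            pairs=(fixtures.PlantedPair("salt_bridge", "LYS", "ASP", 3.5),)
        )
        toy = fixtures.make_toy_structure(spec)
        before = compute_sasa(toy)
        occluder = ResidueView(
            "A", 99, "ALA",
            (AtomRecord(999, "CB", "C", "ALA", 99, "A", (1.5, 1.5, 1.5)),),
        )
        bigger = Structure(residues=toy.residues + (occluder,))
        after = compute_sasa(bigger)
        for key, area in before.items():
            assert after[key] <= area + 1e-9

    def test_agrees_with_independent_implementation(self):
        """Cross-check total SASA against biotite's Shrake-Rupley."""
        biotite_struc = pytest.importorskip("biotite.structure")
        spec = fixtures.PlantedInteractionSpec(
            pairs=(
                fixtures.PlantedPair("salt_bridge", "LYS", "ASP", 3.5),
                fixtures.PlantedPair("hydrogen_bond", "ARG", "GLU", 2.8),
            )
        )
        toy = fixtures.make_toy_structure(spec)
        atoms = [a for r in toy.resolved_residues() for a in r.atoms]
        arr = biotite_struc.AtomArray(len(atoms))
        arr.coord = np.array([a.position for a in atoms])
        arr.chain_id[:] = "A"
        arr.res_id[:] = [a.residue_number for a in atoms]
        arr.res_name[:] = [a.residue_name for a in atoms]
        arr.atom_name[:] = [a.name for a in atoms]
        arr.element[:] = [a.element for a in atoms]
        reference = biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=2000, vdw_radii="Single"
        )
        ours = compute_sasa(toy, sphere_points=2000)
        total_ours = sum(ours.values())
        assert total_ours == pytest.approx(float(reference.sum()), rel=0.02)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            compute_sasa(Structure(residues=()))


class TestClassifyExposure:
    def test_residue_sasa_additivity(self):
        spec = fixtures.PlantedInteractionSpec(
            pairs=(fixtures.PlantedPair("salt_bridge", "LYS", "ASP", 3.5),)
        )
        toy = fixtures.make_toy_structure(spec)
        sasa = compute_sasa(toy)
        for res in toy.resolved_residues():
            total = residue_sasa(res, sasa, sidechain_only=False)
            assert total == pytest.approx(
                sum(sasa[("A", str(res.residue_number), a.name)] for a in res.atoms)
            )

    def test_isolated_lysine_is_maximally_exposed(self):
        spec = fixtures.PlantedInteractionSpec(
            pairs=(fixtures.PlantedPair("salt_bridge", "LYS", "ASP", 40.0),)
        )
        toy = fixtures.make_toy_structure(spec)
        sasa = compute_sasa(toy)
        results = {e.residue_key: e for e in classify_exposure(toy, sasa)}
        lys = results["K5"]
        assert lys.label == "exposed"
        assert lys.relative_fraction > 0.9

    def test_unresolved_residue_follows_policy(self):
        resolved = ResidueView(
            "A", 1, "ALA", (AtomRecord(1, "CA", "C", "ALA", 1, "A", (0, 0, 0)),)
        )
        st = Structure(residues=(resolved, ResidueView("A", 2, "LYS", resolved=False)))
        sasa = compute_sasa(st)
        for policy in ("exposed", "buried", "unknown"):
            crit = ExposureCriteria(unresolved_policy=policy)
            results = {e.residue_key: e for e in classify_exposure(st, sasa, crit)}
            assert results["K2"].label == policy
            assert math.isnan(results["K2"].relative_fraction)

    def test_unknown_residue_type_warns(self):
        atom = AtomRecord(1, "CA", "C", "XXX", 1, "A", (0, 0, 0))
        st = Structure(residues=(ResidueView("A", 1, "XXX", (atom,)),))
        sasa = compute_sasa(st)
        with pytest.warns(UserWarning, match="missing from reference table"):
            results = classify_exposure(st, sasa)
        assert results[0].label == "unknown"

    def test_threshold_is_strict(self):
        atom = AtomRecord(1, "CB", "C", "ALA", 1, "A", (0, 0, 0))
        st = Structure(residues=(ResidueView("A", 1, "ALA", (atom,)),))
        area = compute_sasa(st)[("A", "1", "CB")]
        at_threshold = ExposureCriteria(reference_table={"ALA": area * 4.0})
        result = classify_exposure(st, compute_sasa(st), at_threshold)[0]
        assert result.label == "buried"  # exactly 25% is not "more than 25%"

    def test_criteria_invariants(self):
        with pytest.raises(ValueError):
            ExposureCriteria(threshold=0.0)
        with pytest.raises(ValueError):
            ExposureCriteria(sphere_points=10)
        assert set(MAX_SIDECHAIN_ASA) == {
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLU", "GLN", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL",
        }
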