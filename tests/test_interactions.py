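"""Salt-bridge and hydrogen-bond detection against planted geometry."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import expected_interactions, random_planted_spec
from surfcharge import fixtures
from surfcharge.interactions import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    InteractionCriteria,
    InteractionRecord,
    brute_force_pairs,
    classify_salt_bridge_complexity,
    deduplicate,
    find_hydrogen_bonds,
    find_salt_bridges,
)
from surfcharge.structure import AtomRecord, ResidueView, Structure


def _planted(kind, basic, partner, distance, **kw):
    spec = fixtures.PlantedInteractionSpec(
        pairs=(fixtures.PlantedPair(kind, basic, partner, distance, **kw),)
    )
    return fixtures.make_toy_structure(spec)


class TestSaltBridges:
    def test_planted_pair_detected_at_exact_distance(self):
        toy = _planted("salt_bridge", "LYS", "ASP", 3.5)
        records = deduplicate(find_salt_bridges(toy))
        assert [(r.basic_residue, r.partner_residue) for r in records] == [
            ("K5", "D10")
        ]
        assert records[0].distance == pytest.approx(3.5, abs=1e-9)
        assert records[0].basic_atom == "NZ"
        assert records[0].partner_atom == "OD1"

    def test_pair_beyond_cutoff_not_detected(self):
        toy = _planted("salt_bridge", "LYS", "ASP", 4.5)
        assert find_salt_bridges(toy) == []

    def test_cutoff_monotonicity(self):
        """Enlarging the cutoff never removes a record."""
        toy = _planted("salt_bridge", "ARG", "GLU", 3.9)
        small = {
            (r.basic_atom, r.partner_atom)
            for r in find_salt_bridges(toy, InteractionCriteria(salt_bridge_max=4.0))
        }
        large = {
            (r.basic_atom, r.partner_atom)
            for r in find_salt_bridges(toy, InteractionCriteria(salt_bridge_max=5.0))
        }
        assert small <= large

    def test_atom_level_vs_residue_level_views(self):
        """Both carboxylate oxygens may qualify; the deduplicated view keeps
        one record per residue pair at the shortest distance."""
        toy = _planted("salt_bridge", "LYS", "ASP", 2.6)
        atom_level = find_salt_bridges(toy)
        assert len(atom_level) >= 2  # OD1 planted plus OD2 within reach
        dedup = deduplicate(atom_level)
        assert len(dedup) == 1
        assert dedup[0].distance == pytest.approx(2.6, abs=1e-9)


class TestHydrogenBonds:
    def test_backbone_acceptor_detected(self):
        """An Arg guanidinium nitrogen donating to a backbone carbonyl O."""
        toy = _planted("hydrogen_bond", "ARG", "MET", 2.9, partner_atom="O")
        records = deduplicate(find_hydrogen_bonds(toy))
        assert [(r.basic_residue, r.partner_residue) for r in records] == [
            ("R5", "M10")
        ]
        assert records[0].partner_atom == "O"
        assert not records[0].backbone_involved

    def test_below_window_not_detected(self):
        toy = _planted("hydrogen_bond", "ARG", "MET", 2.3, partner_atom="O")
        assert find_hydrogen_bonds(toy) == []

    def test_upper_bound_inclusive(self):
        toy = _planted("hydrogen_bond", "ARG", "MET", 3.2, partner_atom="O")
        records = deduplicate(find_hydrogen_bonds(toy))
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.2, abs=1e-9)

    def test_backbone_donor_flagged(self):
        """Bonds donated by the basic residue's backbone N are flagged."""
        toy = _planted("hydrogen_bond", "LYS", "MET", 3.0,
                       basic_atom="N", partner_atom="O")
        records = deduplicate(find_hydrogen_bonds(toy))
        assert len(records) == 1
        assert records[0].basic_atom == "N"
        assert records[0].backbone_involved

    def test_salt_bridge_window_overlap(self):
        """A close ion pair shows up in both censuses (independent criteria)."""
        toy = _planted("salt_bridge", "LYS", "ASP", 3.0)
        sb = deduplicate(find_salt_bridges(toy))
        hb = deduplicate(find_hydrogen_bonds(toy))
        assert len(sb) == 1 and len(hb) == 1
        assert sb[0].partner_residue == hb[0].partner_residue == "D10"

    def test_sequence_adjacent_donor_acceptor_excluded(self):
        """i,i+1 contacts are covalent-neighbour artifacts, not H-bonds."""
        lys = ResidueView(
            "A", 5, "LYS",
            (AtomRecord(1, "NZ", "N", "LYS", 5, "A", (0.0, 0.0, 0.0)),),
        )
        asp = ResidueView(
            "A", 6, "ASP",
            (AtomRecord(2, "OD1", "O", "ASP", 6, "A", (3.0, 0.0, 0.0)),),
        )
        st = Structure(residues=(lys, asp))
        assert find_hydrogen_bonds(st) == []
        # the salt-bridge census has no adjacency exclusion
        assert len(find_salt_bridges(st)) == 1


class TestComplexity:
    def test_two_partners_is_complex(self):
        records = [
            InteractionRecord("salt_bridge", "K45", "E213", "NZ", "OE1", 3.1),
            InteractionRecord("salt_bridge", "K45", "D210", "NZ", "OD1", 3.4),
            InteractionRecord("salt_bridge", "K26", "D21", "NZ", "OD1", 3.0),
        ]
        result = classify_salt_bridge_complexity(records, basic_residues=["K3"])
        assert result == {"K45": "complex", "K26": "simple", "K3": "none"}

    def test_empty_records_all_none(self):
        assert classify_salt_bridge_complexity([], basic_residues=["K1", "R2"]) == {
            "K1": "none",
            "R2": "none",
        }

    def test_duplicate_atom_pairs_count_one_partner(self):
        records = [
            InteractionRecord("salt_bridge", "K5", "D10", "NZ", "OD1", 2.6),
            InteractionRecord("salt_bridge", "K5", "D10", "NZ", "OD2", 3.9),
        ]
        assert classify_salt_bridge_complexity(records) == {"K5": "simple"}


class TestBruteForceOracle:
    def test_detection_matches_brute_force_on_random_fixtures(self):
        """k-d-tree detection equals the exhaustive scan, pair for pair."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            spec = random_planted_spec(rng)
            toy = fixtures.make_toy_structure(spec)
            fast = {
                (r.basic_atom, r.basic_residue, r.partner_atom, r.partner_residue)
                for r in find_salt_bridges(toy)
            }
            slow = {
                (a.name, f"K{a.residue_number}" if a.residue_name == "LYS"
                 else f"R{a.residue_number}", b.name,
                 {"ASP": "D", "GLU": "E"}[b.residue_name] + str(b.residue_number))
                for a, b, d in brute_force_pairs(
                    toy, BASIC_ATOMS, ACIDIC_ATOMS, 4.0
                )
                if d >= 1.5
            }
            assert fast == slow

    def test_zero_cutoff_yields_nothing(self, single_salt_bridge_structure):
        assert brute_force_pairs(
            single_salt_bridge_structure, BASIC_ATOMS, ACIDIC_ATOMS, 0.0
        ) == []

    def test_symmetric_selection_reports_each_pair_once(self):
        toy = _planted("salt_bridge", "LYS", "ASP", 3.5)
        sel = {"LYS": frozenset({"NZ"}), "ASP": frozenset({"OD1"})}
        pairs = brute_force_pairs(toy, sel, sel, 10.0)
        assert len(pairs) == 1
        a, b, _ = pairs[0]
        assert a.serial < b.serial


class TestPlantedRecovery:
    def test_residue_level_recovery_over_random_specs(self):
        """Detection recovers exactly the planted interaction sets."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            spec = random_planted_spec(rng)
            toy = fixtures.make_toy_structure(spec)
            expected_sb, expected_hb = expected_interactions(spec)
            got_sb = {
                (r.basic_residue, r.partner_residue)
                for r in deduplicate(find_salt_bridges(toy))
            }
            got_hb = {
                (r.basic_residue, r.partner_residue)
                for r in deduplicate(find_hydrogen_bonds(toy))
            }
            assert got_sb == expected_sb
            assert got_hb == expected_hb


class TestCriteria:
    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            InteractionCriteria(hbond_min=3.5, hbond_max=3.2)
        with pytest.raises(ValueError):
            InteractionCriteria(salt_bridge_max=0.0)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            InteractionRecord("bad_kind", "K1", "D2", "NZ", "OD1", 3.0)
        with pytest.raises(ValueError):
            InteractionRecord("salt_bridge", "K1", "K1", "NZ", "OD1", 3.0)
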