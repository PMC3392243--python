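"""Shared fixtures: toy structures, random planted specs and their oracles."""

from __future__ import annotations

import numpy as np
import pytest

from surfcharge import fixtures
from surfcharge.structure import ONE_TO_THREE, THREE_TO_ONE

# distance windows mirrored here so the expectation oracle stays independent
# of the detection code under test
SALT_BRIDGE_MAX = 4.0
HBOND_MIN, HBOND_MAX = 2.5, 3.2

ACIDIC = {"ASP", "GLU"}
SIDECHAIN_BASIC = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}
SIDECHAIN_ACIDIC_O = {"OD1", "OD2", "OE1", "OE2"}

#: backbone-O acceptor partners safe for random planting (no other acceptor
#: atom can approach the contact axis in the idealised templates)
BACKBONE_O_PARTNERS = ("MET", "ALA", "GLY")


def _off_boundary(distance: float, cutoffs: tuple[float, ...]) -> float:
    """Nudge a random distance off any exact detection cutoff so the
    expectation oracle and the detector cannot disagree by one float ulp."""
    if any(abs(distance - c) < 1e-9 for c in cutoffs):
        return round(distance + 0.003, 3)
    return distance


def random_planted_spec(rng: np.random.Generator) -> fixtures.PlantedInteractionSpec:
    """A random mix of planted salt bridges and hydrogen bonds, some of them
    deliberately outside the detection windows."""
    pairs = []
    for _ in range(int(rng.integers(1, 5))):
        basic = rng.choice(["LYS", "ARG"])
        if rng.random() < 0.5:
            pairs.append(
                fixtures.PlantedPair(
                    kind="salt_bridge",
                    basic_residue=basic,
                    partner_residue=rng.choice(["ASP", "GLU"]),
                    distance=_off_boundary(
                        round(float(rng.uniform(2.0, 4.6)), 3),
                        (SALT_BRIDGE_MAX, HBOND_MIN, HBOND_MAX),
                    ),
                )
            )
        else:
            backbone_donor = rng.random() < 0.3
            if rng.random() < 0.5:
                partner, partner_atom = str(rng.choice(BACKBONE_O_PARTNERS)), "O"
            else:
                partner, partner_atom = [("SER", "OG"), ("ASN", "OD1")][
                    int(rng.integers(0, 2))
                ]
            pairs.append(
                fixtures.PlantedPair(
                    kind="hydrogen_bond",
                    basic_residue=basic,
                    partner_residue=partner,
                    partner_atom=partner_atom,
                    basic_atom="N" if backbone_donor else None,
                    distance=_off_boundary(
                        round(float(rng.uniform(2.2, 3.3)), 3),
                        (HBOND_MIN, HBOND_MAX),
                    ),
                )
            )
    jitter = float(rng.choice([0.0, 0.05]))
    return fixtures.PlantedInteractionSpec(
        pairs=tuple(pairs),
        jitter=jitter,
        seed=int(rng.integers(0, 2**31)) if jitter > 0 else None,
    )


def expected_interactions(
    spec: fixtures.PlantedInteractionSpec,
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Residue-level (basic, partner) pairs detection must report, derived
    from the planted geometry alone (not from the detectors)."""
    expected_sb: set[tuple[str, str]] = set()
    expected_hb: set[tuple[str, str]] = set()
    for i, pair in enumerate(spec.pairs):
        basic_key = f"{THREE_TO_ONE[pair.basic_residue]}{10 * i + 5}"
        partner_key = f"{THREE_TO_ONE[pair.partner_residue]}{10 * i + 10}"
        basic_atom, partner_atom = pair.resolved_atoms()
        is_sb_pair = (
            basic_atom in SIDECHAIN_BASIC[pair.basic_residue]
            and partner_atom in SIDECHAIN_ACIDIC_O
            and pair.partner_residue in ACIDIC
        )
        if is_sb_pair and pair.distance <= SALT_BRIDGE_MAX:
            expected_sb.add((basic_key, partner_key))
        if HBOND_MIN <= pair.distance <= HBOND_MAX:
            expected_hb.add((basic_key, partner_key))
    return expected_sb, expected_hb


@pytest.fixture
def single_salt_bridge_structure():
    spec = fixtures.PlantedInteractionSpec(
        pairs=(fixtures.PlantedPair("salt_bridge", "LYS", "ASP", 3.5),)
    )
    return fixtures.make_toy_structure(spec)


@pytest.fixture(scope="session")
def gfp_tables():
    return fixtures.gfp_table_fixtures()


@pytest.fixture(scope="session")
def gfp_seq():
    return fixtures.gfp_sequence()
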