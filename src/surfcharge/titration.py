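"""Henderson-Hasselbalch protonation fractions for basic side chains.

For an ionizable group with acid dissociation constant pKa, the ratio of
protonated to deprotonated forms at a given pH obeys

    log10([AH+] / [A]) = pKa - pH,

so the protonated fraction is 1 / (1 + 10**(pH - pKa)).  Defaults carry the
standard side-chain pKa values of lysine (10.53) and arginine (12.48), whose
difference is why arginine-rich surfaces stay charged at alkaline pH where
lysines have already lost their protons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_PKA: dict[str, float] = {"LYS": 10.53, "ARG": 12.48}


@dataclass(frozen=True)
class ProtonationParams:
    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self) -> None:
        for name, value in self.pka.items():
            if not np.isfinite(value):
                raise ValueError(f"pKa of {name} is not finite")
            if not 0.0 <= value <= 14.0:
                warnings.warn(
                    f"pKa {value} of {name} outside [0, 14]", stacklevel=2
                )


def fraction_protonated(pka: float, ph: float) -> float:
    """Protonated fraction 1/(1 + 10**(pH - pKa)); always in (0, 1)."""
    if not (np.isfinite(pka) and np.isfinite(ph)):
        raise ValueError("pKa and pH must be finite")
    return float(1.0 / (1.0 + 10.0 ** (ph - pka)))


def titration_curve(
    params: ProtonationParams | None,
    residue_type: str,
    ph_grid: Sequence[float],
) -> pd.DataFrame:
    """Protonated fraction and percent along an ascending pH grid."""
    params = params or ProtonationParams()
    key = residue_type.strip().upper()
    if key not in params.pka:
        raise ValueError(
            f"unknown residue type {residue_type!r}; have {sorted(params.pka)}"
        )
    grid = np.asarray(list(ph_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty pH grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("pH grid must be strictly ascending")
    frac = np.array([fraction_protonated(params.pka[key], ph) for ph in grid])
    return pd.DataFrame(
        {"pH": grid, "fraction": frac, "percent": 100.0 * frac}
    )
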