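"""Monoisotopic mass constants for peptide mass arithmetic.

All masses are monoisotopic and in daltons. The table covers exactly the 20
standard amino acid residues (residue = amino acid minus water). HexNAc is the
mass of one O-linked N-acetylhexosamine (GlcNAc) moiety, the delta that
separates a glycosylated peptide from its naked counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

WATER = 18.010565
PROTON = 1.007276
HEXNAC = 203.079373

#: HexNAc oxocarbenium reporter ion (singly charged fragment of the glycan).
OXOCARBENIUM_MZ = HEXNAC + PROTON

_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic residue masses plus the constants used everywhere else."""

    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(_RESIDUE_MASSES)
    )
    water: float = WATER
    proton: float = PROTON
    hexnac: float = HEXNAC

    def residue(self, aa: str) -> float:
        try:
            return self.residue_masses[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None

    def __contains__(self, aa: str) -> bool:
        return aa in self.residue_masses


DEFAULT_MASS_TABLE = MassTable()
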