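"""Monoisotopic mass constants for glycopeptide arithmetic.

Everything downstream (precursor m/z, Y-ion ladders, transition lists) is
computed on the monoisotopic scale from the residue masses collected here.
Amino-acid residue masses come from pyteomics; monosaccharide residue masses
are the standard values for the dehydrated (residue) forms.
"""

from __future__ import annotations

from types import MappingProxyType

from pyteomics import mass as _pmass

#: Monoisotopic amino-acid residue masses (Da), keyed by one-letter code.
RESIDUE_MASSES = MappingProxyType({aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"})

#: Monosaccharide residue masses (Da), i.e. the mass added on glycosidic
#: bond formation (free sugar minus water).
HEXNAC = 203.079373  # C8H13NO5
HEX = 162.052824     # C6H10O5
FUC = 146.057909     # C6H10O4 (deoxyhexose)
NEU5AC = 291.095417  # C11H17NO8

MONOSACCHARIDE_MASSES = MappingProxyType(
    {"HexNAc": HEXNAC, "Hex": HEX, "Fuc": FUC, "Neu5Ac": NEU5AC}
)

WATER = 18.0105646863
PROTON = 1.00727646677

#: Oxonium (B-type) marker ions, singly charged, and their water losses.
OXONIUM_IONS = MappingProxyType(
    {
        "HexNAc+": 204.086649,
        "HexNAc+-H2O": 186.076084,
        "Neu5Ac+": 292.102693,
        "Neu5Ac+-H2O": 274.092128,
    }
)


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of a peptide (residue sum + water).

    Raises ``KeyError`` on a character that is not a standard one-letter
    amino-acid code.
    """
    return sum(RESIDUE_MASSES[aa] for aa in sequence) + WATER
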