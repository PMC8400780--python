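"""Glycan compositions, glycopeptide mass arithmetic, and the PRM target list.

The core objects are :class:`GlycanComposition` (four-digit HexNAc-Hex-Fuc-
Neu5Ac composition codes), :class:`GlycoSite` (the three tryptic/Glu-C
haptoglobin glycopeptide backbones carrying Asn184, Asn207 and Asn241), and
:class:`GlycopeptideTarget` (one PRM transition-list entry: precursor m/z,
six quantifier fragment m/z values, expected retention time, isomer index).

The packaged target list transcribes the published site-by-site
microheterogeneity table for serum haptoglobin: 72 isomeric entries over 41
distinct (site, composition) forms.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from . import masses
from .masses import FUC, HEX, HEXNAC, NEU5AC, OXONIUM_IONS, PROTON

__all__ = [
    "GlycanComposition",
    "GlycanClass",
    "GlycoSite",
    "GlycopeptideTarget",
    "FragmentIon",
    "SITES",
    "TABLE1_TRANSCRIPTION",
    "parse_glycan_code",
    "glycan_mass",
    "precursor_mz",
    "y_ion_series",
    "classify_glycan",
    "build_target_list",
    "site_overlap_counts",
]


class GlycanParseError(ValueError):
    """Raised on a malformed four-digit glycan composition code."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of the four monosaccharide classes in an N-glycan.

    The four-digit code ``"a-b-c-d"`` gives HexNAc, Hex, Fuc and Neu5Ac
    counts in that order; ``str()`` round-trips exactly through
    :func:`parse_glycan_code`.
    """

    hexnac: int
    hex: int
    fuc: int
    neuac: int

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    def __str__(self) -> str:
        return f"{self.hexnac}-{self.hex}-{self.fuc}-{self.neuac}"

    @property
    def code(self) -> str:
        return str(self)


class GlycanClass(str, Enum):
    SIALYLATED = "sialylated"
    SIALYLATED_FUCOSYLATED = "sialylated_fucosylated"
    OTHER = "other"


@dataclass(frozen=True)
class GlycoSite:
    """One haptoglobin N-glycosylation site and its peptide backbone."""

    site_id: str
    peptide_sequence: str
    elution_window: tuple[float, float]  # minutes

    @property
    def peptide_monoisotopic_mass(self) -> float:
        return masses.peptide_mass(self.peptide_sequence)


#: The three quantifiable haptoglobin sites with their peptide backbones and
#: the retention-time windows within which their glycopeptides elute on the
#: 50 cm C18 gradient (minutes).
SITES: Mapping[str, GlycoSite] = {
    "Asn184": GlycoSite("Asn184", "MVSHHNLTTGATLINE", (42.0, 54.0)),
    "Asn207": GlycoSite("Asn207", "NLFLNHSE", (40.0, 60.0)),
    "Asn241": GlycoSite("Asn241", "VVLHPNYSQVDIGLIK", (61.0, 88.0)),
}


@dataclass(frozen=True)
class FragmentIon:
    label: str
    mz: float
    quantifier: bool


@dataclass(frozen=True)
class GlycopeptideTarget:
    """One PRM target: a (site, composition, isomer) entry of the list."""

    site: GlycoSite
    composition: GlycanComposition
    charge: int
    precursor_mz: float
    fragment_mzs: tuple[float, ...]
    expected_rt: float  # minutes
    isomer_index: int = 1
    n_isomers: int = 1

    @property
    def key(self) -> str:
        """``site|code`` identifier of the glycoform (isomers share it)."""
        return f"{self.site.site_id}|{self.composition}"

    @property
    def entry_key(self) -> str:
        """``site|code|isomer`` identifier of this isomer entry."""
        return f"{self.key}|{self.isomer_index}"


_CODE_RE = re.compile(r"^(\d+)-(\d+)-(\d+)-(\d+)$")


def parse_glycan_code(code: str) -> GlycanComposition:
    """Parse a four-digit composition code like ``"5-6-1-3"``.

    Digits give HexNAc, Hex, Fuc and Neu5Ac counts positionally.
    """
    tokens = code.strip().split("-")
    if len(tokens) != 4:
        raise GlycanParseError(
            f"expected four dash-separated counts, got {len(tokens)} in {code!r}"
        )
    counts = []
    for token in tokens:
        if not token.isdigit():
            raise GlycanParseError(f"non-integer token {token!r} in code {code!r}")
        counts.append(int(token))
    return GlycanComposition(*counts)


def glycan_mass(comp: GlycanComposition) -> float:
    """Monoisotopic residue-mass sum of the glycan moiety (Da)."""
    return comp.hexnac * HEXNAC + comp.hex * HEX + comp.fuc * FUC + comp.neuac * NEU5AC


def precursor_mz(site: GlycoSite, comp: GlycanComposition, charge: int) -> float:
    """m/z of the protonated glycopeptide at the given charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    neutral = site.peptide_monoisotopic_mass + glycan_mass(comp)
    return (neutral + charge * PROTON) / charge


def y_ion_series(site: GlycoSite, comp: GlycanComposition) -> list[FragmentIon]:
    """Singly protonated Y-ion ladder plus oxonium marker ions.

    The ladder starts at Y0 (bare peptide) and Y1 (peptide + HexNAc), then
    climbs the trimannosyl core: +HexNAc, +Hex, +Hex, +Hex, and finally one
    antenna step +HexNAc+Hex. Compositions too small for a step truncate the
    ladder there. The six quantifier ions (collision energy tuned for stable
    core Y fragments) are Y1 and the five ladder steps above it; Y0 and the
    oxonium ions are emitted flagged non-quantifier.
    """
    pep = site.peptide_monoisotopic_mass
    ions: list[FragmentIon] = [FragmentIon("Y0", pep + PROTON, False)]
    # (label, monosaccharide increments, HexNAc/Hex budget consumed so far)
    steps = [
        ("Y1", (1, 0)),
        ("Y1+HexNAc", (1, 0)),
        ("Y1+HexNAc+Hex", (0, 1)),
        ("Y1+HexNAc+Hex2", (0, 1)),
        ("Y1+HexNAc+Hex3", (0, 1)),
        ("Y1+2HexNAc+Hex4", (1, 1)),
    ]
    used_hexnac = used_hex = 0
    mz = pep + PROTON
    for label, (d_hexnac, d_hex) in steps:
        used_hexnac += d_hexnac
        used_hex += d_hex
        if used_hexnac > comp.hexnac or used_hex > comp.hex:
            break
        mz += d_hexnac * HEXNAC + d_hex * HEX
        ions.append(FragmentIon(label, mz, True))
    ions.append(FragmentIon("HexNAc+", OXONIUM_IONS["HexNAc+"], False))
    ions.append(FragmentIon("HexNAc+-H2O", OXONIUM_IONS["HexNAc+-H2O"], False))
    if comp.neuac > 0:
        ions.append(FragmentIon("Neu5Ac+", OXONIUM_IONS["Neu5Ac+"], False))
        ions.append(FragmentIon("Neu5Ac+-H2O", OXONIUM_IONS["Neu5Ac+-H2O"], False))
    return ions


def quantifier_fragments(site: GlycoSite, comp: GlycanComposition) -> tuple[float, ...]:
    """The (up to six) quantifier fragment m/z values for a target."""
    return tuple(ion.mz for ion in y_ion_series(site, comp) if ion.quantifier)


def classify_glycan(comp: GlycanComposition) -> GlycanClass:
    """Assign the three-way glycan class used in the group-level summaries."""
    if comp.neuac > 0 and comp.fuc > 0:
        return GlycanClass.SIALYLATED_FUCOSYLATED
    if comp.neuac > 0:
        return GlycanClass.SIALYLATED
    return GlycanClass.OTHER


#: Transcription of the published site-by-site microheterogeneity table:
#: per site, one cell per glycoform, "code[, k Isomers]". 72 isomer entries
#: over 41 distinct (site, composition) forms.
TABLE1_TRANSCRIPTION: Mapping[str, tuple[str, ...]] = {
    "Asn184": (
        "4-5-0-0, 2 Isomers",
        "4-5-1-1",
        "4-5-1-2",
        "4-5-0-1",
        "4-5-0-2",
        "4-6-0-1",
        "5-6-1-1",
        "5-6-1-2",
        "5-6-1-3",
        "5-6-0-1",
        "5-6-0-2, 2 Isomers",
    ),
    "Asn207": (
        "3-4-0-1, 2 Isomers",
        "4-4-0-1, 3 Isomers",
        "4-5-0-0, 2 Isomers",
        "4-5-1-1, 2 Isomers",
        "4-5-1-2, 2 Isomers",
        "4-5-0-1",
        "4-5-0-2, 2 Isomers",
        "5-6-1-1, 2 Isomers",
        "5-6-1-2, 2 Isomers",
        "5-6-1-3, 2 Isomers",
        "5-6-0-1, 2 Isomers",
        "5-6-0-2, 2 Isomers",
        "5-6-0-3, 3 Isomers",
        "6-7-1-1, 4 Isomers",
        "6-7-1-2, 3 Isomers",
        "6-7-1-3, 5 Isomers",
        "6-7-0-1",
        "6-7-0-2, 3 Isomers",
    ),
    "Asn241": (
        "4-4-0-1",
        "4-5-0-0",
        "4-5-1-2, 2 Isomers",
        "4-5-0-1",
        "4-5-0-2",
        "5-6-1-2",
        "5-6-0-1",
        "5-6-0-2",
        "5-6-0-3, 3 Isomers",
        "6-7-0-1",
        "6-7-0-2",
        "6-7-0-3, 2 Isomers",
    ),
}

_CELL_RE = re.compile(r"^\s*(\d+-\d+-\d+-\d+)\s*(?:,\s*(\d+)\s*Isomers?\s*)?$")

#: Default retention-time spacing between isomer peaks of one composition
#: (minutes); a fixture convention shared with the synthetic renderer.
DEFAULT_ISOMER_RT_SPACING = 2.0


def _parse_cell(cell: str) -> tuple[GlycanComposition, int]:
    m = _CELL_RE.match(cell)
    if m is None:
        raise ValueError(f"unparseable microheterogeneity cell: {cell!r}")
    return parse_glycan_code(m.group(1)), int(m.group(2) or 1)


def _charge_for(site: GlycoSite, comp: GlycanComposition) -> int:
    # Triply charged precursors throughout, except tri/tetra-antennary
    # sialylated glycans on the long Asn241 backbone, observed at 4+.
    if site.site_id == "Asn241" and comp.hexnac - 2 >= 3 and comp.neuac >= 1:
        return 4
    return 3


def _elution_order_key(comp: GlycanComposition) -> tuple:
    # Small biantennary mono-/di-sialylated structures elute first;
    # sialylated-fucosylated glycans elute by sialic-acid count.
    return (comp.neuac, comp.hexnac + comp.hex, comp.fuc, str(comp))


def build_target_list(
    table: Mapping[str, Sequence[str]] = TABLE1_TRANSCRIPTION,
    isomer_rt_spacing: float = DEFAULT_ISOMER_RT_SPACING,
) -> list[GlycopeptideTarget]:
    """Build the packaged PRM target list, one entry per isomer.

    Precursor charge follows the observed-charge rule, fragments are the
    quantifier Y-ion set, and expected retention times place each site's
    glycoforms evenly inside its elution window in elution order, with the
    isomers of one composition spaced ``isomer_rt_spacing`` minutes apart
    (earliest isomer = index 1). Expected RTs are fixture conventions.
    """
    targets: list[GlycopeptideTarget] = []
    for site_id, cells in table.items():
        site = SITES[site_id]
        parsed = [_parse_cell(cell) for cell in cells]
        parsed.sort(key=lambda ci: _elution_order_key(ci[0]))
        max_k = max(k for _, k in parsed)
        lo = site.elution_window[0] + 1.0
        hi = site.elution_window[1] - 1.0 - (max_k - 1) * isomer_rt_spacing
        n = len(parsed)
        for i, (comp, k) in enumerate(parsed):
            base_rt = lo if n == 1 else lo + i * (hi - lo) / (n - 1)
            charge = _charge_for(site, comp)
            frags = quantifier_fragments(site, comp)
            for iso in range(1, k + 1):
                targets.append(
                    GlycopeptideTarget(
                        site=site,
                        composition=comp,
                        charge=charge,
                        precursor_mz=precursor_mz(site, comp, charge),
                        fragment_mzs=frags,
                        expected_rt=base_rt + (iso - 1) * isomer_rt_spacing,
                        isomer_index=iso,
                        n_isomers=k,
                    )
                )
    return targets


def site_overlap_counts(targets: Iterable[GlycopeptideTarget]) -> dict[tuple[str, ...], int]:
    """Distinct-composition overlaps between sites.

    Returns counts keyed by sorted site-id pairs plus one key with all sites
    (the triple intersection when three sites are present). Pairs absent from
    the target list count 0.
    """
    by_site: dict[str, set[GlycanComposition]] = {s: set() for s in SITES}
    for t in targets:
        by_site.setdefault(t.site.site_id, set()).add(t.composition)
    site_ids = sorted(by_site)
    out: dict[tuple[str, ...], int] = {}
    for a, b in itertools.combinations(site_ids, 2):
        out[(a, b)] = len(by_site[a] & by_site[b])
    if len(site_ids) >= 3:
        common = set.intersection(*by_site.values())
        out[tuple(site_ids)] = len(common)
    return out
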