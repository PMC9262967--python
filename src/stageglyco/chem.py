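"""Exact monoisotopic mass arithmetic for peptides, modifications and glycans.

Everything downstream (fragment m/z, remnant deltas, reporter ions) is
derived from the isotope masses in :data:`ISOTOPE_MASS`; printed literature
values are never used as runtime constants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

__all__ = [
    "ISOTOPE_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER",
    "ElementalComposition",
    "Modification",
    "GlycanComposition",
    "OxoniumIon",
    "monoisotopic_mass",
    "remnant_delta",
    "oxonium_table",
    "peptide_mass",
    "peptide_mz",
    "default_modifications",
    "tmt10_reporter_mz",
    "TMT10_CHANNELS",
    "GLYCAN_RESIDUES",
    "AA_COMPOSITIONS",
]

# Monoisotopic isotope masses in Da, CODATA/AME2020 values (≥6 dp).
# Keys like "13C" denote a specific heavy isotope; bare symbols denote the
# principal (lightest stable) isotope.
ISOTOPE_MASS: Dict[str, float] = {
    "H": 1.0078250319,
    "2H": 2.0141017780,
    "C": 12.0,
    "13C": 13.0033548378,
    "N": 14.0030740052,
    "15N": 15.0001088984,
    "O": 15.9949146221,
    "18O": 17.9991604,
    "S": 31.97207069,
    "P": 30.97376151,
}

PROTON_MASS = 1.00727646688  # Da, H+ (H atom minus one electron)
ELECTRON_MASS = 0.00054857990924  # Da

_FORMULA_TOKEN = re.compile(r"(\d*[A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Counts per isotope-resolved element symbol.

    Counts are non-negative integers; the empty composition has mass zero.
    Build from a formula string (``"C8H13NO5"``, isotopes as ``"13C4"``)
    or a mapping.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in dict(self.counts).items():
            if sym not in ISOTOPE_MASS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula.replace(" ", "")):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            sym = m.group(1)
            n = int(m.group(2) or 1)
            counts[sym] = counts.get(sym, 0) + n
        if pos != len(formula.replace(" ", "")):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    @property
    def mass(self) -> float:
        return sum(ISOTOPE_MASS[sym] * n for sym, n in self.counts.items())

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalComposition(merged)


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int] | str) -> float:
    """Monoisotopic mass in Da of a composition, mapping or formula string."""
    if isinstance(comp, str):
        comp = ElementalComposition.from_formula(comp)
    elif not isinstance(comp, ElementalComposition):
        comp = ElementalComposition(comp)
    return comp.mass


# Amino-acid residue compositions (peptide-bond residues, i.e. minus water).
AA_COMPOSITIONS: Dict[str, ElementalComposition] = {
    aa: ElementalComposition.from_formula(f)
    for aa, f in {
        "G": "C2H3NO",
        "A": "C3H5NO",
        "S": "C3H5NO2",
        "P": "C5H7NO",
        "V": "C5H9NO",
        "T": "C4H7NO2",
        "C": "C3H5NOS",
        "L": "C6H11NO",
        "I": "C6H11NO",
        "N": "C4H6N2O2",
        "D": "C4H5NO3",
        "Q": "C5H8N2O2",
        "K": "C6H12N2O",
        "E": "C5H7NO3",
        "M": "C5H9NOS",
        "H": "C6H7N3O",
        "F": "C9H9NO",
        "R": "C6H12N4O",
        "Y": "C9H9NO2",
        "W": "C11H10N2O",
    }.items()
}

AA_MASS: Dict[str, float] = {aa: c.mass for aa, c in AA_COMPOSITIONS.items()}

WATER = ElementalComposition.from_formula("H2O").mass

# Glycan residue (dehydrated monosaccharide) compositions.
GLYCAN_RESIDUES: Dict[str, ElementalComposition] = {
    "HexNAc": ElementalComposition.from_formula("C8H13NO5"),
    "Hex": ElementalComposition.from_formula("C6H10O5"),
    "dHex": ElementalComposition.from_formula("C6H10O4"),
    "NeuAc": ElementalComposition.from_formula("C11H17NO8"),
}


@dataclass(frozen=True)
class Modification:
    """A residue- or terminus-targeted mass modification.

    ``delta`` is an elemental composition when the modification is a pure
    addition; ``delta_mass`` is used directly when the delta involves atom
    removal (e.g. deamidation, N→D) and cannot be a non-negative composition.
    """

    name: str
    target: str  # residue letter, "N-term" or "C-term"
    delta_mass: float
    kind: str = "dynamic"  # "static" | "dynamic"
    composition: ElementalComposition | None = None

    @classmethod
    def from_composition(
        cls, name: str, target: str, comp: ElementalComposition, kind: str = "dynamic"
    ) -> "Modification":
        return cls(name, target, comp.mass, kind, comp)


def remnant_delta(remnant: str) -> float:
    """Mass delta in Da of a sequential-deglycosylation remnant signature.

    ``"HexNAc-Fuc"`` — Endo F3 leaves the core GlcNAc plus core fucose
    (HexNAc + dHex residues) on the glycosite asparagine.
    ``"HexNAc"`` — residual single core GlcNAc.
    ``"deamidation"`` — PNGase F converts the glycosite Asn to Asp.
    """
    if remnant == "HexNAc-Fuc":
        return GLYCAN_RESIDUES["HexNAc"].mass + GLYCAN_RESIDUES["dHex"].mass
    if remnant == "HexNAc":
        return GLYCAN_RESIDUES["HexNAc"].mass
    if remnant == "deamidation":
        return AA_MASS["D"] - AA_MASS["N"]
    raise ValueError(f"unknown remnant: {remnant!r}")


def default_modifications() -> Dict[str, Modification]:
    """The standard search modification set.

    Carbamidomethyl-Cys is static; oxidation-Met and the three
    deglycosylation remnant signatures are dynamic; the TMT 10-plex label
    (Lys and peptide N-terminus) is used for labeled designs.
    """
    cam = ElementalComposition.from_formula("C2H3NO")
    ox = ElementalComposition.from_formula("O")
    # TMT 10-plex label: 8 12C + 4 13C, 20 H, one 14N + one 15N, 2 O.
    tmt = ElementalComposition({"C": 8, "13C": 4, "H": 20, "N": 1, "15N": 1, "O": 2})
    mods = {
        "carbamidomethyl": Modification.from_composition("carbamidomethyl", "C", cam, "static"),
        "oxidation": Modification.from_composition("oxidation", "M", ox),
        "deamidation": Modification("deamidation", "N", remnant_delta("deamidation")),
        "hexnac": Modification(
            "hexnac", "N", remnant_delta("HexNAc"),
            composition=GLYCAN_RESIDUES["HexNAc"],
        ),
        "hexnac_fuc": Modification(
            "hexnac_fuc", "N", remnant_delta("HexNAc-Fuc"),
            composition=GLYCAN_RESIDUES["HexNAc"] + GLYCAN_RESIDUES["dHex"],
        ),
        "tmt10_K": Modification.from_composition("tmt10_K", "K", tmt),
        "tmt10_nterm": Modification.from_composition("tmt10_nterm", "N-term", tmt),
    }
    return mods


REMNANT_MOD_NAMES = {"hexnac_fuc": "CF", "hexnac": "HexNAc", "deamidation": "deamidated"}


_GLYCAN_NOTATION = re.compile(r"^(?:N(\d+))?(?:H(\d+))?(?:F(\d+))?(?:S(\d+))?$")


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide classes, NxHyFzSw notation.

    N = HexNAc, H = Hex, F = fucose (dHex), S = sialic acid (NeuAc).
    """

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        if min(self.hexnac, self.hex, self.dhex, self.neuac) < 0:
            raise ValueError("monosaccharide counts must be non-negative")

    @property
    def mass(self) -> float:
        return (
            self.hexnac * GLYCAN_RESIDUES["HexNAc"].mass
            + self.hex * GLYCAN_RESIDUES["Hex"].mass
            + self.dhex * GLYCAN_RESIDUES["dHex"].mass
            + self.neuac * GLYCAN_RESIDUES["NeuAc"].mass
        )

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        m = _GLYCAN_NOTATION.match(text.strip())
        if not m or not text.strip():
            raise ValueError(f"cannot parse glycan notation {text!r}")
        n, h, f, s = (int(g) if g else 0 for g in m.groups())
        return cls(n, h, f, s)

    def to_string(self) -> str:
        parts = []
        for letter, count in (("N", self.hexnac), ("H", self.hex), ("F", self.dhex), ("S", self.neuac)):
            if count:
                parts.append(f"{letter}{count}")
        return "".join(parts) or "N0"

    def __str__(self) -> str:  # pragma: no cover
        return self.to_string()


@dataclass(frozen=True)
class OxoniumIon:
    """A singly charged low-mass glycan fragment cation."""

    label: str
    composition: ElementalComposition

    @property
    def mz(self) -> float:
        # cation m/z at charge 1: neutral-atom composition minus one electron
        return self.composition.mass - ELECTRON_MASS


def oxonium_table() -> list[OxoniumIon]:
    """Reference oxonium ions used for glycopeptide triage and validation.

    The first four are the HexNAc fragment series used to validate remnant
    PSMs; HexNAc (the intact HexNAc oxonium, ~m/z 204.087) doubles as the
    triage ion. m/z is always computed from the composition.
    """
    return [
        OxoniumIon("HexNAc-C2H6O3", ElementalComposition.from_formula("C6H8NO2")),
        OxoniumIon("HexNAc-CH6O3", ElementalComposition.from_formula("C7H8NO2")),
        OxoniumIon("HexNAc-H2O", ElementalComposition.from_formula("C8H12NO4")),
        OxoniumIon("HexNAc", ElementalComposition.from_formula("C8H14NO5")),
        OxoniumIon("HexNAc-Fuc", ElementalComposition.from_formula("C14H24NO9")),
    ]


VALIDATION_OXONIUM_LABELS = ("HexNAc-C2H6O3", "HexNAc-CH6O3", "HexNAc-H2O", "HexNAc")
TRIAGE_OXONIUM_LABEL = "HexNAc"


def peptide_mass(sequence: str, mods: Mapping[int, Modification] | None = None) -> float:
    """Neutral monoisotopic mass of a peptide with positional modifications.

    ``mods`` maps 1-based residue positions (0 = N-terminus,
    len(sequence)+1 = C-terminus) to modifications.
    """
    total = WATER
    for aa in sequence:
        try:
            total += AA_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter: {aa!r}") from None
    if mods:
        for pos, mod in mods.items():
            if not 0 <= pos <= len(sequence) + 1:
                raise ValueError(f"modification position {pos} outside peptide")
            total += mod.delta_mass
    return total


def peptide_mz(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON_MASS) / charge


# --- TMT 10-plex reporter ions -------------------------------------------

# Reporter cation compositions: C8H16N+ backbone with heavy-isotope
# substitutions distinguishing N/C channels (6.32 mDa 13C vs 15N spacing).
_TMT10_REPORTERS: Dict[str, ElementalComposition] = {
    "126": ElementalComposition({"C": 8, "H": 16, "N": 1}),
    "127N": ElementalComposition({"C": 8, "H": 16, "15N": 1}),
    "127C": ElementalComposition({"C": 7, "13C": 1, "H": 16, "N": 1}),
    "128N": ElementalComposition({"C": 7, "13C": 1, "H": 16, "15N": 1}),
    "128C": ElementalComposition({"C": 6, "13C": 2, "H": 16, "N": 1}),
    "129N": ElementalComposition({"C": 6, "13C": 2, "H": 16, "15N": 1}),
    "129C": ElementalComposition({"C": 5, "13C": 3, "H": 16, "N": 1}),
    "130N": ElementalComposition({"C": 5, "13C": 3, "H": 16, "15N": 1}),
    "130C": ElementalComposition({"C": 4, "13C": 4, "H": 16, "N": 1}),
    "131": ElementalComposition({"C": 4, "13C": 4, "H": 16, "15N": 1}),
}

TMT10_CHANNELS = tuple(_TMT10_REPORTERS)


def tmt10_reporter_mz() -> Dict[str, float]:
    """Reporter-ion m/z (charge 1) per TMT 10-plex channel, computed from
    the reporter cation compositions."""
    return {ch: comp.mass - ELECTRON_MASS for ch, comp in _TMT10_REPORTERS.items()}
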