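"""Monoisotopic mass constants and mass arithmetic.

Single source of truth for the masses used throughout the package:
elements, amino-acid residues, monosaccharide residues, the diagnostic
oxonium-ion m/z table, and the N-glycan core Y-ion offset template.

Monosaccharide and oxonium constants are stored at the precision of the
published decomposer configuration and used verbatim by the pipeline;
:func:`formula_mass` / :func:`oxonium_mz` recompute m/z values from
elemental first principles for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pyteomics import mass as _pmass

#: Mass of a proton in Da (CODATA).
PROTON = 1.00727646

#: Monoisotopic mass of H2O in Da.
WATER = 18.0105646863

#: 13C - 12C mass difference in Da, the spacing of an isotope envelope.
ISOTOPE_SPACING = 1.00335

#: Monoisotopic element masses in Da.
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
}

#: Elemental composition of each monosaccharide *residue* (after loss of
#: water on glycosidic bond formation).
MONOSACCHARIDE_FORMULAS: Mapping[str, Mapping[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dHex": {"C": 6, "H": 10, "O": 4},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
}

#: Canonical ordering of monosaccharides in composition vectors.
MONOSACCHARIDE_ORDER: tuple[str, ...] = ("Hex", "HexNAc", "dHex", "NeuAc")

#: Monosaccharide residue masses in Da, published decomposer configuration.
MONOSACCHARIDE_MASSES: Mapping[str, float] = {
    "Hex": 162.05282,
    "HexNAc": 203.07937,
    "dHex": 146.05791,
    "NeuAc": 291.09542,
}

#: Default per-monosaccharide count bounds for composition generation.
DEFAULT_BOUNDS: Mapping[str, tuple[int, int]] = {
    "Hex": (0, 12),
    "HexNAc": (1, 7),
    "dHex": (0, 3),
    "NeuAc": (0, 4),
}

#: Production six-ion diagnostic oxonium table: (name, m/z in Da).
DEFAULT_OXONIUM_IONS: tuple[tuple[str, float], ...] = (
    ("HexHexNAc", 366.139472),
    ("HexHexNAcNeuAc", 657.234889),
    ("HexHexNAcdHex", 512.19793),
    ("NeuAc", 292.102693),
    ("NeuAc-H2O", 274.092128),
    ("HexNAc", 204.0867),
)

#: N-glycan core Y-ion pattern offsets in Da relative to the reference
#: [peptide + HexNAc]1+ (Y1) peak. Negative entries are the Y0 peak
#: (-HexNAc), the cross-ring 0,2X fragment of the proximal HexNAc
#: (-120.0423) and the reported deamidated-Asn-related peak (-220.0821);
#: positive entries climb the core: +HexNAc (Y2), then +1..3 Hex.
DEFAULT_PATTERN_OFFSETS: tuple[float, ...] = (
    -220.0821,
    -203.0794,
    -120.0423,
    0.0,
    203.0794,
    365.1322,
    527.185,
    689.2378,
)

#: Standard monoisotopic residue masses for the 20 amino acids (pyteomics).
AA_RESIDUE_MASSES: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}


@dataclass(frozen=True)
class MonosaccharideTable:
    """Monosaccharide residue masses plus count bounds for enumeration."""

    masses: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOSACCHARIDE_MASSES)
    )
    bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name not in self.masses:
                raise ValueError(f"bounds given for unknown monosaccharide {name!r}")
            if lo < 0 or hi < 0 or lo > hi:
                raise ValueError(
                    f"invalid bounds for {name!r}: ({lo}, {hi}); need 0 <= min <= max"
                )
        for name, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"non-positive residue mass for {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(
            n for n in MONOSACCHARIDE_ORDER if n in self.masses
        ) + tuple(n for n in self.masses if n not in MONOSACCHARIDE_ORDER)


@dataclass(frozen=True)
class OxoniumTable:
    """Diagnostic oxonium ions as (name, singly protonated m/z) entries."""

    entries: tuple[tuple[str, float], ...] = DEFAULT_OXONIUM_IONS

    def __post_init__(self) -> None:
        for name, mz in self.entries:
            if mz <= 0:
                raise ValueError(f"non-positive oxonium m/z for {name!r}")

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(mz for _, mz in self.entries)


@dataclass(frozen=True)
class PatternTemplate:
    """Signed mass offsets of the core Y-ion pattern, 0 = reference (Y1)."""

    offsets: tuple[float, ...] = DEFAULT_PATTERN_OFFSETS

    def __post_init__(self) -> None:
        offs = tuple(self.offsets)
        if 0.0 not in offs:
            raise ValueError("pattern template must contain the 0 (reference) offset")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("pattern offsets must be strictly increasing")


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental formula, in Da."""
    unknown = set(formula) - set(ELEMENT_MASSES)
    if unknown:
        raise ValueError(f"unknown element(s): {sorted(unknown)}")
    return sum(ELEMENT_MASSES[el] * n for el, n in formula.items())


def peptide_neutral_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide with free termini.

    Parameters
    ----------
    sequence:
        Amino-acid sequence in one-letter code (the 20 standard residues).

    Returns
    -------
    float
        Sum of residue masses plus one water, in Da. The empty sequence
        returns the mass of water.
    """
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total += AA_RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid residue {aa!r} at position {i}"
            ) from None
    return total


def glycan_mass(
    composition: Mapping[str, int],
    table: MonosaccharideTable | None = None,
) -> float:
    """Neutral mass of a glycan composition (count vector), in Da."""
    masses = (table or MonosaccharideTable()).masses
    total = 0.0
    for name, count in composition.items():
        if name not in masses:
            raise ValueError(f"unknown monosaccharide {name!r}")
        if count < 0:
            raise ValueError(f"negative count for {name!r}: {count}")
        total += count * masses[name]
    return total


def oxonium_mz(composition: Mapping[str, int], water_losses: int = 0) -> float:
    """Singly protonated oxonium m/z for a monosaccharide composition.

    Computed from elemental first principles: the sum of residue formula
    masses, minus ``water_losses`` waters, plus a proton. Reproduces the
    default :class:`OxoniumTable` (the HexHexNAcdHex entry is stored at its
    published value, which differs from the elemental value by ~0.55 mDa).
    """
    if not composition or sum(composition.values()) == 0:
        raise ValueError("oxonium composition must be non-empty")
    total = 0.0
    for name, count in composition.items():
        if name not in MONOSACCHARIDE_FORMULAS:
            raise ValueError(f"unknown monosaccharide {name!r}")
        if count < 0:
            raise ValueError(f"negative count for {name!r}: {count}")
        total += count * formula_mass(MONOSACCHARIDE_FORMULAS[name])
    water = formula_mass({"H": 2, "O": 1})
    return total - water_losses * water + PROTON


def pattern_offsets_from_core(masses: Mapping[str, float] | None = None) -> tuple[float, ...]:
    """Positive core-ladder offsets implied by the monosaccharide masses.

    Relative to Y1: +HexNAc (Y2), then Y2 + 1..3 Hex. Used to cross-check
    the stored template against the residue-mass table.
    """
    m = masses or MONOSACCHARIDE_MASSES
    hexnac, hexose = m["HexNAc"], m["Hex"]
    return (hexnac, hexnac + hexose, hexnac + 2 * hexose, hexnac + 3 * hexose)
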