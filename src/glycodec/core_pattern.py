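"""Step 2 of the decomposer: locate the N-glycan core Y-ion pattern.

Collisional activation of an N-glycopeptide cleaves the glycan at
glycosidic bonds, producing a Y-ion ladder that walks down the conserved
core (peptide, peptide+HexNAc, +2HexNAc, +2HexNAc+1..3Hex) plus two
commonly observed auxiliary fragments. Anchoring the 8-peak offset
template at a candidate reference peak (the Y1 = [peptide + HexNAc]1+ ion)
and counting in-window matches yields candidate placements; the best
placement fixes the peptide-moiety mass and, by difference from the
precursor, the glycan-moiety mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .masses import MONOSACCHARIDE_MASSES, PROTON, PatternTemplate
from .spectra_io import Peak, Spectrum, precursor_neutral_mass


@dataclass(frozen=True)
class PatternMatch:
    """One placement of the core pattern anchored at a reference peak."""

    reference_mz: float
    reference_intensity: float
    matched_offsets: tuple[float, ...]
    n_matched: int
    peptide_moiety_mass: float
    glycan_moiety_mass: float
    rank: int | None = None


def candidate_references(
    spectrum: Spectrum,
    min_mz: float = 850.0,
    min_relative_intensity: float = 0.1,
) -> list[Peak]:
    """Peaks eligible as the Y1 reference: heavy enough and intense enough.

    Gates are inclusive: m/z >= ``min_mz`` and intensity >=
    ``min_relative_intensity`` x base peak intensity.
    """
    base = spectrum.base_peak_intensity
    if base == 0:
        return []
    cutoff = min_relative_intensity * base
    return [p for p in spectrum.peaks if p.mz >= min_mz and p.intensity >= cutoff]


def match_pattern(
    spectrum: Spectrum,
    reference: Peak,
    template: PatternTemplate | None = None,
    mz_tolerance: float = 0.05,
    min_pattern_peaks: int = 2,
    hexnac_mass: float = MONOSACCHARIDE_MASSES["HexNAc"],
) -> PatternMatch | None:
    """Try to place the offset template at one reference peak.

    The 0 offset always matches the reference itself; every other offset
    matches when some peak lies within +/- ``mz_tolerance`` of
    ``reference.mz + offset`` (the most intense such peak, at most one per
    offset). Returns ``None`` unless at least ``min_pattern_peaks`` offsets
    match and the derived glycan-moiety mass is positive.
    """
    template = template or PatternTemplate()
    matched = []
    for offset in template.offsets:
        if offset == 0:
            matched.append(offset)
            continue
        target = reference.mz + offset
        if target <= 0:
            continue
        in_window = [p for p in spectrum.peaks if abs(p.mz - target) <= mz_tolerance]
        if in_window:
            matched.append(offset)
    if len(matched) < min_pattern_peaks:
        return None
    peptide_mass = (reference.mz - PROTON) - hexnac_mass
    glycan_mass = precursor_neutral_mass(spectrum) - peptide_mass
    if glycan_mass <= 0:
        return None
    return PatternMatch(
        reference_mz=reference.mz,
        reference_intensity=reference.intensity,
        matched_offsets=tuple(matched),
        n_matched=len(matched),
        peptide_moiety_mass=peptide_mass,
        glycan_moiety_mass=glycan_mass,
    )


def rank_patterns(matches: Sequence[PatternMatch]) -> list[PatternMatch]:
    """Order candidate placements: most matched peaks first, then most
    intense reference, then lowest reference m/z; ranks assigned 1..k."""
    ordered = sorted(
        matches,
        key=lambda m: (-m.n_matched, -m.reference_intensity, m.reference_mz),
    )
    return [replace(m, rank=i) for i, m in enumerate(ordered, start=1)]


def find_patterns(
    spectrum: Spectrum,
    template: PatternTemplate | None = None,
    min_reference_mz: float = 850.0,
    min_reference_rel_intensity: float = 0.1,
    mz_tolerance: float = 0.05,
    min_pattern_peaks: int = 2,
    hexnac_mass: float = MONOSACCHARIDE_MASSES["HexNAc"],
) -> list[PatternMatch]:
    """All ranked pattern placements for one (deconvoluted) spectrum."""
    matches = []
    for ref in candidate_references(
        spectrum, min_reference_mz, min_reference_rel_intensity
    ):
        m = match_pattern(
            spectrum, ref, template, mz_tolerance, min_pattern_peaks, hexnac_mass
        )
        if m is not None:
            matches.append(m)
    return rank_patterns(matches)


def group_isotope_patterns(
    matches: Sequence[PatternMatch],
    isotope_spacing: float = 1.00335,
    k_max: int = 3,
    tolerance: float = 0.05,
) -> list[list[PatternMatch]]:
    """Partition matches whose references are isotope-shifted copies.

    Two matches belong together when their reference m/z differ by
    k x spacing (1 <= k <= ``k_max``) within ``tolerance``; grouping is
    transitive. Used for reporting, not ranking.
    """
    n = len(matches)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            delta = abs(matches[i].reference_mz - matches[j].reference_mz)
            if any(
                abs(delta - k * isotope_spacing) <= tolerance
                for k in range(1, k_max + 1)
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[PatternMatch]] = {}
    for i, m in enumerate(matches):
        groups.setdefault(find(i), []).append(m)
    return list(groups.values())
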