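"""Step 3: emit peptide-moiety and glycan-moiety composite spectra.

Given the rank-1 core-pattern placement, the peptide-moiety spectrum is
the charge-deconvoluted spectrum with oxonium peaks removed, truncated
above the reference (Y1) peak, and re-precursored to [M + HexNAc]1+; the
glycan-moiety spectrum is the deconvoluted spectrum with the derived
glycan mass attached as metadata. ``decompose_stream`` wires the three
steps into the per-spectrum pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

from . import core_pattern, oxonium_filter
from .config import Config
from .core_pattern import PatternMatch
from .glycan_compositions import GLYCAN_MASS_KEY, GlycanComposition
from .oxonium_filter import OxoniumResult
from .spectra_io import Spectrum, charge_deconvolute, prefilter_peaks

logger = logging.getLogger(__name__)


@dataclass
class DecomposedPair:
    """The two composite spectra decomposed from one hybrid spectrum."""

    peptide_spectrum: Spectrum
    glycan_spectrum: Spectrum
    source_id: str
    pattern: PatternMatch
    compositions: list[GlycanComposition] | None = None


@dataclass
class Outcome:
    """Per-spectrum result of the decomposition pipeline."""

    category: str  # "non-glyco" | "decomposed" | "glyco-no-pattern" | "error"
    spectrum: Spectrum
    oxonium: OxoniumResult | None = None
    pair: DecomposedPair | None = None
    patterns: list[PatternMatch] = field(default_factory=list)
    message: str | None = None


def _check_pattern_source(spectrum: Spectrum, pattern: PatternMatch) -> Spectrum:
    """Deconvolute and verify the pattern's reference peak is present."""
    deconv = charge_deconvolute(spectrum)
    if not any(abs(p.mz - pattern.reference_mz) <= 1e-6 for p in deconv.peaks):
        raise ValueError(
            f"pattern reference {pattern.reference_mz:.4f} not found in "
            f"spectrum {spectrum.identifier!r}; pattern does not derive from it"
        )
    return deconv


def make_peptide_spectrum(
    spectrum: Spectrum,
    pattern: PatternMatch,
    config: Config | None = None,
) -> Spectrum:
    """Peptide-moiety composite spectrum with pseudo-precursor [M+HexNAc]1+.

    In order: charge-deconvolute; delete peaks within the oxonium
    tolerance of any table ion; delete peaks above the reference m/z plus
    the pattern tolerance (the Y1 peak itself survives); set the precursor
    to (reference m/z, charge 1).
    """
    config = config or Config()
    deconv = _check_pattern_source(spectrum, pattern)
    oxo_mzs = config.oxonium_table().mz_values
    tol = config.oxonium_tolerance
    peaks = [
        p
        for p in deconv.peaks
        if not any(abs(p.mz - omz) <= tol for omz in oxo_mzs)
    ]
    cutoff = pattern.reference_mz + config.pattern_tolerance
    peaks = [p for p in peaks if p.mz <= cutoff]
    out = replace(
        deconv,
        identifier=f"{spectrum.identifier}|peptide",
        precursor_mz=pattern.reference_mz,
        precursor_charge=1,
        peaks=peaks,
        metadata={**spectrum.metadata, "source_id": spectrum.identifier},
    )
    return out


def make_glycan_spectrum(
    spectrum: Spectrum,
    pattern: PatternMatch,
) -> Spectrum:
    """Glycan-moiety composite: deconvoluted copy carrying the glycan mass."""
    deconv = _check_pattern_source(spectrum, pattern)
    return replace(
        deconv,
        identifier=f"{spectrum.identifier}|glycan",
        metadata={
            **spectrum.metadata,
            "source_id": spectrum.identifier,
            GLYCAN_MASS_KEY: pattern.glycan_moiety_mass,
        },
    )


def decompose_spectrum(spectrum: Spectrum, config: Config | None = None) -> Outcome:
    """Run prefilter -> oxonium filter -> pattern search -> decomposition."""
    config = config or Config()
    filtered = prefilter_peaks(spectrum, config.min_peak_intensity)
    oxo = oxonium_filter.evaluate(
        filtered,
        config.oxonium_table(),
        config.oxonium_tolerance,
        config.min_oxonium_ions,
        config.oxonium_sum_threshold,
    )
    if not oxo.is_glycopeptide:
        return Outcome("non-glyco", spectrum, oxonium=oxo)
    deconv = charge_deconvolute(filtered, config.merge_tolerance)
    patterns = core_pattern.find_patterns(
        deconv,
        config.pattern_template(),
        config.min_reference_mz,
        config.min_reference_rel_intensity,
        config.pattern_tolerance,
        config.min_pattern_peaks,
        config.monosaccharide_masses["HexNAc"],
    )
    if not patterns:
        return Outcome("glyco-no-pattern", spectrum, oxonium=oxo)
    best = patterns[0]
    pair = DecomposedPair(
        peptide_spectrum=make_peptide_spectrum(filtered, best, config),
        glycan_spectrum=make_glycan_spectrum(filtered, best),
        source_id=spectrum.identifier,
        pattern=best,
    )
    return Outcome("decomposed", spectrum, oxonium=oxo, pair=pair, patterns=patterns)


def decompose_stream(
    spectra: Iterable[Spectrum],
    config: Config | None = None,
) -> tuple[list[Outcome], dict[str, int]]:
    """Decompose a stream of spectra; never aborts on one bad spectrum.

    Returns the per-spectrum outcomes plus a category-count summary
    (counts sum to the number of input spectra).
    """
    config = config or Config()
    outcomes: list[Outcome] = []
    counts = {"non-glyco": 0, "decomposed": 0, "glyco-no-pattern": 0, "error": 0}
    for spectrum in spectra:
        try:
            outcome = decompose_spectrum(spectrum, config)
        except Exception as exc:  # per-spectrum failures are logged, not fatal
            logger.warning("skipping spectrum %r: %s", spectrum.identifier, exc)
            outcome = Outcome("error", spectrum, message=str(exc))
        outcomes.append(outcome)
        counts[outcome.category] += 1
    logger.info(
        "decomposed %d spectra: %s",
        len(outcomes),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return outcomes, counts
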