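"""Step 1 of the decomposer: oxonium-ion based glycopeptide classification.

Oxonium ions are low-mass B-type glycan fragment cations (e.g. HexNAc+ at
m/z 204.0867) that flag a precursor as carrying a glycan. A spectrum is
called a glycopeptide spectrum when enough table ions are detected and
their summed intensity, relative to the total spectrum intensity, clears
a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .masses import OxoniumTable
from .spectra_io import Spectrum


@dataclass(frozen=True)
class OxoniumMatch:
    name: str
    theoretical_mz: float
    peak_mz: float
    peak_intensity: float


@dataclass(frozen=True)
class OxoniumResult:
    """Per-spectrum oxonium detections and the glyco/non-glyco call."""

    matches: tuple[OxoniumMatch, ...]
    relative_intensity_sum: float
    n_ions_detected: int
    is_glycopeptide: bool | None = None


def detect_oxonium(
    spectrum: Spectrum,
    table: OxoniumTable | None = None,
    mz_tolerance: float = 0.02,
) -> OxoniumResult:
    """Match the oxonium table against a (prefiltered) spectrum.

    Each table entry matches at most one peak — the most intense peak
    within +/- ``mz_tolerance`` — and each peak serves at most one entry;
    when two entries claim the same peak the entry closer in m/z wins and
    the other falls back to its next-most-intense in-window peak.
    ``relative_intensity_sum`` is the matched intensity divided by the
    total intensity of the spectrum.
    """
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be > 0")
    table = table or OxoniumTable()
    total = spectrum.total_intensity
    if not spectrum.peaks or total == 0:
        return OxoniumResult((), 0.0, 0)

    # candidate peaks per entry, most intense first
    candidates: dict[str, list[int]] = {}
    theo = dict(table.entries)
    for name, mz in table.entries:
        in_window = [
            i for i, p in enumerate(spectrum.peaks) if abs(p.mz - mz) <= mz_tolerance
        ]
        in_window.sort(key=lambda i: (-spectrum.peaks[i].intensity, spectrum.peaks[i].mz))
        candidates[name] = in_window

    assigned: dict[str, int] = {}  # entry name -> peak index
    claimed: dict[int, str] = {}  # peak index -> entry name
    pending = [name for name, _ in table.entries]
    while pending:
        name = pending.pop(0)
        for i in candidates[name]:
            holder = claimed.get(i)
            if holder is None:
                claimed[i] = name
                assigned[name] = i
                break
            # conflict: closest-m/z entry keeps the peak
            peak = spectrum.peaks[i]
            if abs(peak.mz - theo[name]) < abs(peak.mz - theo[holder]):
                claimed[i] = name
                assigned[name] = i
                del assigned[holder]
                pending.append(holder)
                break
            # else try this entry's next candidate peak
        # no free/winnable peak -> entry unmatched

    matches = tuple(
        OxoniumMatch(
            name, theo[name], spectrum.peaks[i].mz, spectrum.peaks[i].intensity
        )
        for name, i in sorted(assigned.items(), key=lambda kv: theo[kv[0]])
    )
    rel = sum(m.peak_intensity for m in matches) / total
    return OxoniumResult(matches, rel, len(matches))


def classify_glyco(
    result: OxoniumResult,
    min_ions: int = 1,
    intensity_threshold: float = 0.0047,
) -> bool:
    """Glycopeptide call: enough distinct ions AND enough relative intensity.

    Both thresholds are inclusive. Spectra classified ``False`` are routed
    through the pipeline unmodified (ordinary peptide spectra).
    """
    return bool(
        result.n_ions_detected >= min_ions
        and result.relative_intensity_sum >= intensity_threshold
    )


def evaluate(
    spectrum: Spectrum,
    table: OxoniumTable | None = None,
    mz_tolerance: float = 0.02,
    min_ions: int = 1,
    intensity_threshold: float = 0.0047,
) -> OxoniumResult:
    """Detect and classify in one call; returns the completed result."""
    result = detect_oxonium(spectrum, table, mz_tolerance)
    return replace(
        result,
        is_glycopeptide=classify_glyco(result, min_ions, intensity_threshold),
    )
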