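"""Synthetic glycopeptide / non-glycopeptide MS/MS spectra with ground truth.

Emulates the fragment inventory of an N-glycopeptide CID spectrum:
diagnostic oxonium ions implied by the glycan composition, the 8-peak
core Y-ion pattern anchored at Y1 = [peptide + HexNAc]1+, peptide
backbone b/y ions with and without the proximal HexNAc, and uniform
random noise peaks. Non-glycopeptide spectra carry b/y ions and noise
only, with every peak displaced out of the oxonium detection windows so
labelled negatives are clean by construction.

Peaks are emitted singly protonated (inputs are deisotoped and decharged
by contract); no isotope envelopes or collision-energy physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masses import (
    DEFAULT_PATTERN_OFFSETS,
    MONOSACCHARIDE_MASSES,
    PROTON,
    WATER,
    AA_RESIDUE_MASSES,
    MonosaccharideTable,
    OxoniumTable,
    glycan_mass,
    peptide_neutral_mass,
)
from .spectra_io import Peak, Spectrum, write_mgf

#: Default peptide pool: tryptic plasma glycopeptide backbones, each
#: carrying an N-X(!=P)-S/T sequon.
DEFAULT_PEPTIDES: tuple[str, ...] = (
    "SVQEIQATFFYFTPNK",
    "VVLHPNYSQVDIGIK",
    "SLGNVNFTVSAEALESQELCGTEVPSVPEHGR",
    "GLTFQQNASSMCVPDQDTAIR",
    "EEQFNSTFR",
    "LCPDCPLLAPLNDSR",
    "VSNKTLSLFFTVLQDVPVR",
)

#: Default composition pool: the dominant plasma N-glycome (complex di-
#: and tri-antennary, fucosylated and high-mannose species).
DEFAULT_COMPOSITIONS: tuple[Mapping[str, int], ...] = (
    {"Hex": 5, "HexNAc": 4, "NeuAc": 2},
    {"Hex": 5, "HexNAc": 4, "NeuAc": 1},
    {"Hex": 5, "HexNAc": 4, "dHex": 1, "NeuAc": 1},
    {"Hex": 6, "HexNAc": 5, "NeuAc": 3},
    {"Hex": 5, "HexNAc": 2},
    {"Hex": 3, "HexNAc": 2},
    {"Hex": 4, "HexNAc": 3, "NeuAc": 1},
    {"Hex": 3, "HexNAc": 4, "dHex": 1},
)


@dataclass(frozen=True)
class SimParams:
    """Spectrum-generation knobs; the defaults are the study conditions.

    ladder_completeness: probability each non-reference core-pattern peak
    appears. by_coverage: probability each b/y (+/- HexNAc) ion appears.
    oxonium_intensity_fraction: target fraction of total spectrum
    intensity carried by oxonium peaks. n_noise_peaks: fixed count of
    uniform noise peaks. noise_mz_range: noise m/z window; ``None`` upper
    bound means precursor m/z x charge. seed: fixes the full output.
    """

    ladder_completeness: float = 0.9
    by_coverage: float = 0.7
    oxonium_intensity_fraction: float = 0.05
    n_noise_peaks: int = 50
    noise_mz_range: tuple[float, float | None] = (200.0, None)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ladder_completeness", "by_coverage", "oxonium_intensity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


#: Noise-free, fully covered variant used for clean fixtures.
CLEAN_PARAMS = SimParams(
    ladder_completeness=1.0, by_coverage=1.0, n_noise_peaks=0
)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated spectrum."""

    identifier: str
    peptide: str
    composition: tuple[tuple[str, int], ...]
    precursor_charge: int
    true_y1_mz: float
    true_peptide_mass: float
    true_glycan_mass: float
    label: str  # "glyco" | "non-glyco"


def find_sequon(peptide: str) -> int | None:
    """Index of the Asn of the first N-X(!=P)-S/T motif, or None."""
    for i in range(len(peptide) - 2):
        if peptide[i] == "N" and peptide[i + 1] != "P" and peptide[i + 2] in "ST":
            return i
    return None


def _fragment_mzs(peptide: str, site: int | None, hexnac: float) -> list[float]:
    """b/y ion m/z values, plus +HexNAc variants for site-bearing fragments."""
    residues = [AA_RESIDUE_MASSES[aa] for aa in peptide]
    mzs: list[float] = []
    n = len(peptide)
    prefix = 0.0
    for i in range(1, n):  # b_i covers residues [0, i)
        prefix += residues[i - 1]
        b = prefix + PROTON
        mzs.append(b)
        if site is not None and i > site:
            mzs.append(b + hexnac)
    suffix = 0.0
    for i in range(1, n):  # y_i covers residues [n - i, n)
        suffix += residues[n - i]
        y = suffix + WATER + PROTON
        mzs.append(y)
        if site is not None and n - i <= site:
            mzs.append(y + hexnac)
    return mzs


def _oxonium_ions_for(composition: Mapping[str, int], table: OxoniumTable) -> list[float]:
    """Oxonium m/z values a glycan of this composition plausibly yields."""
    c = {k: composition.get(k, 0) for k in ("Hex", "HexNAc", "dHex", "NeuAc")}
    wanted = {"HexNAc"}
    if c["Hex"] >= 1:
        wanted.add("HexHexNAc")
    if c["NeuAc"] >= 1:
        wanted.update({"NeuAc", "NeuAc-H2O"})
        if c["Hex"] >= 1:
            wanted.add("HexHexNAcNeuAc")
    if c["dHex"] >= 1 and c["Hex"] >= 1:
        wanted.add("HexHexNAcdHex")
    return [mz for name, mz in table.entries if name in wanted]


def _draw_intensities(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-uniform fragment intensities in [1e2, 1e4] counts."""
    return 10.0 ** rng.uniform(2.0, 4.0, size=n)


def simulate_glycopeptide(
    peptide: str,
    composition: Mapping[str, int],
    charge: int,
    params: SimParams = SimParams(),
    rng: np.random.Generator | None = None,
    identifier: str = "sim_glyco",
) -> tuple[Spectrum, SimTruth]:
    """Simulate one glycopeptide spectrum plus its ground truth.

    The Y1 peak is biased to be the most intense peak of the spectrum;
    the glycosylation site sits at the first sequon when one exists.
    """
    if len(peptide) < 5:
        raise ValueError("peptide must be at least 5 residues long")
    for name, (lo, hi) in MonosaccharideTable().bounds.items():
        c = composition.get(name, 0)
        if not lo <= c <= hi:
            raise ValueError(
                f"composition count {name}={c} outside bounds [{lo}, {hi}]"
            )
    unknown = set(composition) - set(MONOSACCHARIDE_MASSES)
    if unknown:
        raise ValueError(f"unknown monosaccharide(s): {sorted(unknown)}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    hexnac = MONOSACCHARIDE_MASSES["HexNAc"]
    pep_mass = peptide_neutral_mass(peptide)
    gly_mass = glycan_mass(composition)
    total_mass = pep_mass + gly_mass
    precursor_mz = total_mass / charge + PROTON
    y1 = pep_mass + hexnac + PROTON
    site = find_sequon(peptide)

    mzs: list[float] = []
    # peptide backbone ions
    for mz in _fragment_mzs(peptide, site, hexnac):
        if rng.random() < params.by_coverage:
            mzs.append(mz)
    # core Y-ion pattern around Y1
    for offset in DEFAULT_PATTERN_OFFSETS:
        if offset == 0:
            continue
        if rng.random() < params.ladder_completeness:
            target = y1 + offset
            if target > 0:
                mzs.append(target)
    intensities = list(_draw_intensities(rng, len(mzs)))
    # Y1 reference: present always, biased to be the base peak
    top = max(intensities, default=1e4)
    mzs.append(y1)
    intensities.append(top * rng.uniform(1.0, 1.3))

    # oxonium ions scaled to the target fraction of total intensity
    oxo_mzs = _oxonium_ions_for(composition, OxoniumTable())
    f = params.oxonium_intensity_fraction
    if oxo_mzs and f > 0:
        weights = rng.uniform(0.5, 1.0, size=len(oxo_mzs))
        weights /= weights.sum()
        oxo_total = f / (1.0 - f) * sum(intensities)
        mzs.extend(oxo_mzs)
        intensities.extend(oxo_total * weights)

    # noise
    lo, hi = params.noise_mz_range
    hi = hi if hi is not None else precursor_mz * charge
    for _ in range(params.n_noise_peaks):
        mzs.append(rng.uniform(lo, hi))
        intensities.append(10.0 ** rng.uniform(1.2, 3.3))

    spectrum = Spectrum(
        identifier=identifier,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=[Peak(m, i, 1) for m, i in zip(mzs, intensities)],
    )
    truth = SimTruth(
        identifier=identifier,
        peptide=peptide,
        composition=tuple(sorted(composition.items())),
        precursor_charge=charge,
        true_y1_mz=y1,
        true_peptide_mass=pep_mass,
        true_glycan_mass=gly_mass,
        label="glyco",
    )
    return spectrum, truth


def simulate_nonglyco(
    peptide: str,
    charge: int,
    params: SimParams = SimParams(),
    rng: np.random.Generator | None = None,
    identifier: str = "sim_nonglyco",
    oxonium_guard: float = 0.03,
) -> tuple[Spectrum, SimTruth]:
    """Simulate a plain peptide spectrum: b/y ions plus noise only.

    Every peak (fragment or noise) landing within ``oxonium_guard`` Da of
    a table oxonium m/z is displaced just outside the window, so the
    spectrum is a clean negative by construction.
    """
    if len(peptide) < 5:
        raise ValueError("peptide must be at least 5 residues long")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pep_mass = peptide_neutral_mass(peptide)
    precursor_mz = pep_mass / charge + PROTON
    oxo_mzs = OxoniumTable().mz_values

    def displaced(mz: float) -> float:
        for omz in oxo_mzs:
            if abs(mz - omz) <= oxonium_guard:
                return omz + oxonium_guard + 0.01
        return mz

    mzs: list[float] = []
    for mz in _fragment_mzs(peptide, None, 0.0):
        if rng.random() < params.by_coverage:
            mzs.append(displaced(mz))
    intensities = list(_draw_intensities(rng, len(mzs)))
    lo, hi = params.noise_mz_range
    hi = hi if hi is not None else precursor_mz * charge
    for _ in range(params.n_noise_peaks):
        mzs.append(displaced(rng.uniform(lo, hi)))
        intensities.append(10.0 ** rng.uniform(1.2, 3.3))

    spectrum = Spectrum(
        identifier=identifier,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=[Peak(m, i, 1) for m, i in zip(mzs, intensities)],
    )
    truth = SimTruth(
        identifier=identifier,
        peptide=peptide,
        composition=(),
        precursor_charge=charge,
        true_y1_mz=float("nan"),
        true_peptide_mass=pep_mass,
        true_glycan_mass=0.0,
        label="non-glyco",
    )
    return spectrum, truth


def simulate_cohort(
    n_glyco: int,
    n_nonglyco: int,
    params: SimParams = SimParams(),
    peptides: Sequence[str] = DEFAULT_PEPTIDES,
    compositions: Sequence[Mapping[str, int]] = DEFAULT_COMPOSITIONS,
    charges: Sequence[int] = (2, 3),
    out_prefix: str | Path | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate a labelled cohort; optionally write MGF + truth TSV.

    Peptides, compositions and charges are sampled uniformly from the
    pools with a generator seeded by ``params.seed``; with ``out_prefix``
    set, writes ``<prefix>.mgf`` and ``<prefix>_truth.tsv``.
    """
    if n_glyco > 0 and (not peptides or not compositions):
        raise ValueError("peptide and composition pools must be non-empty")
    if n_nonglyco > 0 and not peptides:
        raise ValueError("peptide pool must be non-empty")
    rng = np.random.default_rng(params.seed)
    spectra: list[Spectrum] = []
    truths: list[SimTruth] = []
    for i in range(n_glyco):
        pep = peptides[rng.integers(len(peptides))]
        comp = compositions[rng.integers(len(compositions))]
        z = int(charges[rng.integers(len(charges))])
        s, t = simulate_glycopeptide(
            pep, comp, z, params, rng, identifier=f"glyco_{i:05d}"
        )
        spectra.append(s)
        truths.append(t)
    for i in range(n_nonglyco):
        pep = peptides[rng.integers(len(peptides))]
        z = int(charges[rng.integers(len(charges))])
        s, t = simulate_nonglyco(pep, z, params, rng, identifier=f"nonglyco_{i:05d}")
        spectra.append(s)
        truths.append(t)
    truth_df = pd.DataFrame(
        {
            "identifier": [t.identifier for t in truths],
            "label": [t.label for t in truths],
            "peptide": [t.peptide for t in truths],
            "composition": [
                "".join(f"{n}{c}" for n, c in t.composition) for t in truths
            ],
            "precursor_charge": [t.precursor_charge for t in truths],
            "true_y1_mz": [round(t.true_y1_mz, 6) for t in truths],
            "true_peptide_mass": [round(t.true_peptide_mass, 6) for t in truths],
            "true_glycan_mass": [round(t.true_glycan_mass, 6) for t in truths],
        }
    )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_mgf(spectra, prefix.with_suffix(".mgf"))
        truth_df.to_csv(f"{prefix}_truth.tsv", sep="\t", index=False)
    return spectra, truth_df
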