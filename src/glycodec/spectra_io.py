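"""Peak-list containers and I/O for centroided MS/MS spectra.

Supports the MGF and ms2 dialects (inputs are assumed centroided and
deisotoped), the global minimum-intensity prefilter, precursor neutral
mass computation, and charge deconvolution to singly protonated peaks.
Reading goes through pyteomics; writing is plain-text and mirrors what
the readers accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy
from pyteomics import mgf as _mgf
from pyteomics import ms2 as _ms2

from .masses import PROTON


@dataclass(frozen=True)
class Peak:
    """One centroided peak: m/z in Da, intensity in counts, optional charge."""

    mz: float
    intensity: float
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """A precursor descriptor plus its peak list, sorted ascending by m/z."""

    identifier: str
    precursor_mz: float
    precursor_charge: int | None
    peaks: list[Peak] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_charge is not None and self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1 when known")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def mz_array(self) -> list[float]:
        return [p.mz for p in self.peaks]


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
    else:
        f = Path(path).suffix.lstrip(".").lower()
    if f not in ("mgf", "ms2"):
        raise ValueError(f"unsupported peak-list format {f!r}; use 'mgf' or 'ms2'")
    return f


def read_spectra(path: str | Path, fmt: str | None = None) -> Iterator[Spectrum]:
    """Stream spectra from an MGF or ms2 file in file order.

    Per-peak charge annotations are kept when the dialect carries them,
    otherwise charge is unknown. A malformed record raises a ``ValueError``
    naming the file and record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    f = _infer_format(path, fmt)
    reader = _mgf.read if f == "mgf" else _ms2.read
    with reader(str(path), use_index=False) as entries:
        index = 0
        while True:
            try:
                entry = next(entries)
            except StopIteration:
                return
            except Exception as exc:
                raise ValueError(
                    f"malformed {f} record #{index} in {path}: {exc}"
                ) from exc
            yield _entry_to_spectrum(entry, f, index)
            index += 1


def _entry_to_spectrum(entry: dict, fmt: str, index: int) -> Spectrum:
    params = entry.get("params", {})
    if fmt == "mgf":
        identifier = str(params.get("title", f"spectrum_{index}"))
        pepmass = params.get("pepmass", (0.0,))
        precursor_mz = float(pepmass[0])
        charge_field = params.get("charge")
        precursor_charge = int(charge_field[0]) if charge_field else None
    else:  # ms2
        identifier = str(params.get("scan", [index])[0])
        precursor_mz = float(params.get("precursor m/z", 0.0))
        charges = params.get("charge", [])
        precursor_charge = int(charges[0]) if len(charges) else None
    mzs = entry.get("m/z array")
    intensities = entry.get("intensity array")
    charges = entry.get("charge array")
    peaks = []
    n = 0 if mzs is None else len(mzs)
    for i in range(n):
        z = None
        if charges is not None:
            try:
                ci = charges[i]
                if ci is not None and not numpy.ma.is_masked(ci) and int(ci) != 0:
                    z = int(ci)
            except (TypeError, ValueError):
                z = None
        peaks.append(Peak(float(mzs[i]), float(intensities[i]), z))
    return Spectrum(identifier, precursor_mz, precursor_charge, peaks)


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> int:
    """Write spectra as MGF; returns the number of spectra written."""
    n = 0
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            for p in s.peaks:
                if p.charge is not None:
                    fh.write(f"{p.mz:.6f} {p.intensity:.4f} {p.charge}\n")
                else:
                    fh.write(f"{p.mz:.6f} {p.intensity:.4f}\n")
            fh.write("END IONS\n")
            n += 1
    return n


def write_ms2(spectra: Iterable[Spectrum], path: str | Path) -> int:
    """Write spectra as ms2 (S/Z header lines per scan); returns the count.

    The Z line carries the charge and the singly protonated mass
    ``(precursor_mz - proton) * z + proton``, per the ms2 convention.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("H\tCreationTool\tglycodec\n")
        for i, s in enumerate(spectra, start=1):
            fh.write(f"S\t{i}\t{i}\t{s.precursor_mz:.6f}\n")
            z = s.precursor_charge or 1
            mh = (s.precursor_mz - PROTON) * z + PROTON
            fh.write(f"Z\t{z}\t{mh:.6f}\n")
            fh.write(f"I\tTITLE\t{s.identifier}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.6f} {p.intensity:.4f}\n")
            n += 1
    return n


def prefilter_peaks(spectrum: Spectrum, min_intensity: float = 15.0) -> Spectrum:
    """Drop peaks below the global minimum intensity (inclusive keep)."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    kept = [p for p in spectrum.peaks if p.intensity >= min_intensity]
    return replace(spectrum, peaks=kept, metadata=dict(spectrum.metadata))


def precursor_neutral_mass(spectrum: Spectrum) -> float:
    """Neutral precursor mass M = z * (precursor_mz - proton), in Da."""
    z = spectrum.precursor_charge
    if z is None or z < 1:
        raise ValueError(
            f"spectrum {spectrum.identifier!r} has no usable precursor charge"
        )
    return z * (spectrum.precursor_mz - PROTON)


def charge_deconvolute(spectrum: Spectrum, merge_tolerance: float = 0.001) -> Spectrum:
    """Convert every multiply charged peak to its singly protonated m/z.

    A peak with known charge z > 1 moves to ``mz * z - (z - 1) * proton``
    with charge 1; unknown-charge and z = 1 peaks are untouched (inputs
    are decharged by contract, so annotations are advisory). The result is
    re-sorted and peaks closer than ``merge_tolerance`` are merged into an
    intensity-weighted centroid with summed intensity.
    """
    moved = []
    for p in spectrum.peaks:
        if p.charge is not None and p.charge > 1:
            moved.append(
                Peak(p.mz * p.charge - (p.charge - 1) * PROTON, p.intensity, 1)
            )
        else:
            moved.append(p)
    moved.sort(key=lambda p: p.mz)
    merged: list[Peak] = []
    cluster: list[Peak] = []
    for p in moved:
        if cluster and p.mz - cluster[-1].mz > merge_tolerance:
            merged.append(_merge_cluster(cluster))
            cluster = []
        cluster.append(p)
    if cluster:
        merged.append(_merge_cluster(cluster))
    return replace(spectrum, peaks=merged, metadata=dict(spectrum.metadata))


def _merge_cluster(cluster: Sequence[Peak]) -> Peak:
    if len(cluster) == 1:
        return cluster[0]
    total = sum(p.intensity for p in cluster)
    if total > 0:
        mz = sum(p.mz * p.intensity for p in cluster) / total
    else:
        mz = cluster[0].mz
    charge = cluster[0].charge
    return Peak(mz, total, charge)
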