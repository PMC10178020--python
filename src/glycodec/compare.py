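"""Equivalence of glycopeptide identifications and result-set agreement.

Two identifications of the same spectrum count as the same when the
peptide-moiety sequences are identical and the glycan-moiety masses agree
within a small tolerance after allowing up to a few 13C isotope
displacements (either tool may have anchored on a non-monoisotopic
precursor peak).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .masses import ISOTOPE_SPACING

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Identification:
    """One glycopeptide identification of one spectrum."""

    source_id: str
    peptide: str
    glycan_mass: float
    charge: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.glycan_mass <= 0:
            raise ValueError("glycan_mass must be > 0")


def same_identification(
    a: Identification,
    b: Identification,
    mass_tol: float = 0.05,
    max_isotopes: int = 3,
) -> bool:
    """Same peptide sequence and glycan masses equal up to k isotopes.

    True iff the peptide strings match exactly and
    ``min_k | |dM| - k * 1.00335 | <= mass_tol`` for some k in
    0..``max_isotopes``; the isotope shift applies in either direction.
    """
    if a.peptide != b.peptide:
        return False
    delta = abs(a.glycan_mass - b.glycan_mass)
    return any(
        abs(delta - k * ISOTOPE_SPACING) <= mass_tol
        for k in range(max_isotopes + 1)
    )


def _dedupe(ids: Iterable[Identification]) -> dict[str, Identification]:
    by_id: dict[str, Identification] = {}
    for ident in ids:
        prev = by_id.get(ident.source_id)
        if prev is None:
            by_id[ident.source_id] = ident
        else:
            logger.info("duplicate source_id %r: keeping best score", ident.source_id)
            if (ident.score or 0.0) > (prev.score or 0.0):
                by_id[ident.source_id] = ident
    return by_id


def agreement_table(
    set_a: Iterable[Identification],
    set_b: Iterable[Identification],
    mass_tol: float = 0.05,
    max_isotopes: int = 3,
) -> dict[str, int]:
    """Partition the union of spectrum ids into four agreement classes.

    Returns counts ``both_same``, ``both_different``, ``a_only``,
    ``b_only``; duplicated ids within a set keep the best-scoring record.
    """
    a_map = _dedupe(set_a)
    b_map = _dedupe(set_b)
    counts = {"both_same": 0, "both_different": 0, "a_only": 0, "b_only": 0}
    for sid in set(a_map) | set(b_map):
        if sid in a_map and sid in b_map:
            if same_identification(a_map[sid], b_map[sid], mass_tol, max_isotopes):
                counts["both_same"] += 1
            else:
                counts["both_different"] += 1
        elif sid in a_map:
            counts["a_only"] += 1
        else:
            counts["b_only"] += 1
    return counts


def read_identifications(path: str | Path) -> list[Identification]:
    """Read a delimited identification table (columns: source_id, peptide,
    glycan_mass, charge[, score])."""
    df = pd.read_csv(path, sep="\t")
    required = {"source_id", "peptide", "glycan_mass", "charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        out.append(
            Identification(
                source_id=str(row.source_id),
                peptide=str(row.peptide),
                glycan_mass=float(row.glycan_mass),
                charge=int(row.charge),
                score=None if score is None or pd.isna(score) else float(score),
            )
        )
    return out


def write_identifications(ids: Iterable[Identification], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source_id": i.source_id,
                "peptide": i.peptide,
                "glycan_mass": i.glycan_mass,
                "charge": i.charge,
                "score": i.score,
            }
            for i in ids
        ]
    ).to_csv(path, sep="\t", index=False)
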