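"""Database-independent glycan identification by exhaustive enumeration.

Every monosaccharide count vector within the per-residue bounds whose
mass lies within tolerance of the query (glycan-moiety) mass is returned
— no database lookup, so unexpected (e.g. disease-specific) glycans are
never missed by omission from a reference list. The search is a
depth-first walk with residual-mass pruning but is set-equivalent to the
full nested-loop enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masses import MonosaccharideTable

#: Metadata key under which a glycan-moiety composite spectrum carries its mass.
GLYCAN_MASS_KEY = "glycan_moiety_mass"


@dataclass(frozen=True)
class GlycanComposition:
    """A count vector with its mass and signed deviation from the query."""

    counts: tuple[tuple[str, int], ...]
    mass: float
    delta: float  # composition mass - query mass

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return "".join(f"{n}{c}" for n, c in self.counts if c > 0) or "empty"


def generate_compositions(
    query_mass: float,
    table: MonosaccharideTable | None = None,
    tolerance: float = 0.1,
) -> list[GlycanComposition]:
    """All in-bounds compositions whose mass is within +/- tolerance.

    Results are sorted by absolute mass deviation, ties broken by the
    count vector in canonical monosaccharide order. Complete with respect
    to brute-force enumeration of the bounded count space.
    """
    if query_mass <= 0:
        raise ValueError(f"query mass must be > 0, got {query_mass}")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    table = table or MonosaccharideTable()
    names = table.names
    masses = [table.masses[n] for n in names]
    bounds = [table.bounds.get(n, (0, 0)) for n in names]
    # residual mass attainable from position i onward, for pruning
    min_rest = [0.0] * (len(names) + 1)
    max_rest = [0.0] * (len(names) + 1)
    for i in range(len(names) - 1, -1, -1):
        lo, hi = bounds[i]
        min_rest[i] = min_rest[i + 1] + lo * masses[i]
        max_rest[i] = max_rest[i + 1] + hi * masses[i]

    out: list[GlycanComposition] = []
    counts = [0] * len(names)

    def walk(i: int, acc: float) -> None:
        if i == len(names):
            delta = acc - query_mass
            if abs(delta) <= tolerance:
                out.append(
                    GlycanComposition(tuple(zip(names, counts)), acc, delta)
                )
            return
        lo, hi = bounds[i]
        for c in range(lo, hi + 1):
            mass = acc + c * masses[i]
            if mass + min_rest[i + 1] > query_mass + tolerance:
                break  # counts only grow from here
            if mass + max_rest[i + 1] < query_mass - tolerance:
                continue
            counts[i] = c
            walk(i + 1, mass)
        counts[i] = 0

    walk(0, 0.0)
    out.sort(key=lambda g: (abs(g.delta), tuple(c for _, c in g.counts)))
    return out


def compositions_for_pair(pair, table=None, tolerance: float = 0.1):
    """Attach the composition list for a decomposed pair's glycan mass.

    The pair must carry the glycan-moiety mass in its glycan spectrum
    metadata; an empty list flags a mass no bounded composition explains.
    Returns the same pair with ``compositions`` populated.
    """
    mass = pair.glycan_spectrum.metadata.get(GLYCAN_MASS_KEY)
    if mass is None:
        raise ValueError(
            f"pair {pair.source_id!r} carries no {GLYCAN_MASS_KEY!r} metadata"
        )
    pair.compositions = generate_compositions(mass, table, tolerance)
    return pair
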