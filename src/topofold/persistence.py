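"""Degree-1 persistent homology of an alpha filtration.

Pairs are computed by the standard mod-2 boundary-matrix column
reduction restricted to the edge/triangle block: each triangle column is
reduced against earlier columns until its lowest nonzero entry (an edge
rank) is unique, which pairs the triangle (death) with that edge
(birth).  Columns are represented as Python integers used as bitmasks,
which is plenty fast at the molecular point-cloud sizes this package
targets (tens of atoms).
"""

from __future__ import annotations

from dataclasses import dataclass

from .alpha import FilteredComplex


@dataclass(frozen=True)
class PersistencePair:
    """A finite degree-1 persistence pair: a loop born at radius
    ``birth`` (when ``birth_edge`` enters) and filled at ``death``
    (when ``death_triangle`` enters).  Angstrom."""

    birth: float
    death: float
    birth_edge: tuple[int, int]
    death_triangle: tuple[int, int, int]

    @property
    def lifetime(self) -> float:
        return self.death - self.birth


def compute_persistence(fc: FilteredComplex) -> list[PersistencePair]:
    """All finite degree-1 persistence pairs, ascending birth order.

    Zero-lifetime pairs (birth == death) are discarded; pairs with tiny
    positive lifetime are kept.
    """
    edges = fc.of_dim(1)
    triangles = fc.of_dim(2)
    edge_rank = {e: i for i, e in enumerate(edges)}

    columns: dict[int, int] = {}   # low edge rank -> reduced column bitmask
    deaths: dict[int, tuple[int, int, int]] = {}
    for tri in triangles:
        (a, b, c) = tri
        col = 0
        for e in ((a, b), (a, c), (b, c)):
            col ^= 1 << edge_rank[e]
        while col:
            low = col.bit_length() - 1
            if low not in columns:
                columns[low] = col
                deaths[low] = tri
                break
            col ^= columns[low]

    pairs = []
    for low, tri in deaths.items():
        edge = edges[low]
        b = fc.alpha_of(edge)
        d = fc.alpha_of(tri)
        if d > b:
            pairs.append(PersistencePair(b, d, edge, tri))
    pairs.sort(key=lambda p: (p.birth, p.death, p.birth_edge))
    return pairs


def betti1_at_radius(pairs: list[PersistencePair], r: float) -> int:
    """First Betti number at ball radius ``r``: the count of pairs with
    ``birth <= r < death`` (closed at birth, open at death)."""
    if r < 0:
        raise ValueError("radius must be nonnegative")
    return sum(1 for p in pairs if p.birth <= r < p.death)


def barcode(pairs: list[PersistencePair]) -> list[tuple[float, float]]:
    """(birth, death) intervals sorted by ascending birth."""
    return sorted((p.birth, p.death) for p in pairs)


def accumulated_bar_length(pairs: list[PersistencePair]) -> float:
    """Sum of lifetimes (death - birth) over all pairs, in Angstrom.

    This is the molecular-topological-fingerprint style scalar summary
    of a persistence barcode; 0 for an empty list.
    """
    return float(sum(p.death - p.birth for p in pairs))
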