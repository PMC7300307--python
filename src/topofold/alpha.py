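"""Alpha-complex filtrations of 3-D point clouds.

The filtration value of a simplex is the smallest ball radius ``r`` (in
Angstrom) at which the simplex enters the alpha complex: its own
circumradius when the circumscribing sphere is empty of the remaining
points (the Gabriel condition), otherwise the smallest filtration value
of a Delaunay coface through which it is carried in.  Radii, not squared
radii, are exposed, so births and deaths downstream share the Angstrom
length scale of the coordinates.

Degenerate inputs (coplanar, cocircular or cospherical configurations
that break the Delaunay triangulation) are resolved by a deterministic
jitter of magnitude 1e-9 A seeded from a hash of the coordinates, so
repeated runs on identical input produce identical complexes; every such
event is logged.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial import QhullError

from .cloud import PointCloud

logger = logging.getLogger("topofold")

_GABRIEL_RTOL = 1e-12
_PERTURB_SCALE = 1e-9


@dataclass(frozen=True)
class FilteredComplex:
    """A Delaunay complex with alpha filtration values, totally ordered.

    ``simplices`` are sorted-vertex tuples listed in filtration order:
    nondecreasing alpha, ties broken by (dimension, lexicographic vertex
    tuple), which guarantees faces precede cofaces.
    """

    n_points: int
    simplices: tuple[tuple[int, ...], ...]
    alpha: np.ndarray  # Angstrom, aligned with `simplices`

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "_position",
                           {s: i for i, s in enumerate(self.simplices)})

    def position(self, simplex: tuple[int, ...]) -> int:
        """Rank of a simplex in the filtration order."""
        return self._position[tuple(sorted(simplex))]

    def alpha_of(self, simplex: tuple[int, ...]) -> float:
        return float(self.alpha[self.position(simplex)])

    def of_dim(self, dim: int) -> list[tuple[int, ...]]:
        """Simplices of one dimension, in filtration order."""
        return [s for s in self.simplices if len(s) == dim + 1]


def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest sphere through all points (center in their affine hull).

    Returns (center, squared radius).
    """
    p0 = points[0]
    B = points[1:] - p0
    if B.shape[0] == 0:
        return p0.copy(), 0.0
    d = np.einsum("ij,ij->i", B, B)
    G = 2.0 * (B @ B.T)
    try:
        y = np.linalg.solve(G, d)
    except np.linalg.LinAlgError:
        y, *_ = np.linalg.lstsq(G, d, rcond=None)
    center = p0 + y @ B
    r2 = float(np.dot(y @ B, y @ B))
    return center, r2


def _maximal_simplices(pts: np.ndarray) -> list[tuple[int, ...]]:
    """Top-dimensional Delaunay simplices, with the deterministic
    perturbation fallback for degenerate configurations."""
    n = pts.shape[0]
    if n == 1:
        return [(0,)]
    if n == 2:
        return [(0, 1)]
    if n == 3:
        return [(0, 1, 2)]

    coords = pts
    for attempt in range(4):
        try:
            tri = Delaunay(coords)
        except QhullError:
            tri = None
        if tri is not None and len(tri.coplanar) == 0:
            used = np.unique(tri.simplices)
            if used.size == n:
                if attempt > 0:
                    logger.info(
                        "degenerate point configuration: applied deterministic "
                        "perturbation of magnitude %.1e A (attempt %d)",
                        _PERTURB_SCALE * 10 ** (attempt - 1), attempt)
                return [tuple(sorted(int(v) for v in s)) for s in tri.simplices]
        # deterministic jitter seeded from the coordinate bytes
        seed = zlib.crc32(pts.tobytes()) + attempt
        rng = np.random.default_rng(seed % (2**31))
        coords = pts + rng.normal(scale=_PERTURB_SCALE * 10**attempt,
                                  size=pts.shape)
    raise ValueError("could not build a Delaunay triangulation even after "
                     "deterministic perturbation")


def build_alpha_filtration(cloud: PointCloud) -> FilteredComplex:
    """Build the alpha filtration of a point cloud.

    Parameters
    ----------
    cloud : PointCloud
        At least one point; no two points coincident.

    Returns
    -------
    FilteredComplex
        All Delaunay simplices (dimensions 0-3) with alpha values on the
        radius scale (Angstrom), in filtration order.
    """
    pts = cloud.coords
    n = cloud.n
    if n >= 2:
        from scipy.spatial.distance import pdist
        if pdist(pts).min() < 1e-9:
            raise ValueError("duplicate (or near-coincident) points in cloud")

    maximal = _maximal_simplices(pts)
    top_dim = max(len(s) for s in maximal) - 1

    # enumerate all faces of all maximal simplices
    by_dim: list[set[tuple[int, ...]]] = [set() for _ in range(top_dim + 1)]
    for s in maximal:
        k = len(s) - 1
        for d in range(k + 1):
            for face in combinations(s, d + 1):
                by_dim[d].add(face)
    for v in range(n):
        by_dim[0].add((v,))

    # Propagate filtration values downward (Gudhi-style): a face either
    # inherits the min over the values of cofaces whose opposite vertex
    # violates its Gabriel condition, or keeps its own circumradius.
    alpha2: dict[tuple[int, ...], float] = {}
    for dim in range(top_dim, 0, -1):
        for s in sorted(by_dim[dim]):
            if s not in alpha2:  # Gabriel for every coface seen so far
                _, r2 = _circumsphere(pts[list(s)])
                alpha2[s] = r2
            a_cof = alpha2[s]
            if dim == 1:
                continue
            for face in combinations(s, dim):
                if face in alpha2:
                    alpha2[face] = min(alpha2[face], a_cof)
                else:
                    center, r2 = _circumsphere(pts[list(face)])
                    opposite = [v for v in s if v not in face]
                    d2 = np.einsum("ij,ij->i",
                                   pts[opposite] - center,
                                   pts[opposite] - center)
                    if np.any(d2 < r2 * (1.0 - _GABRIEL_RTOL)):
                        alpha2[face] = a_cof  # not Gabriel for this coface
    for v in range(n):
        alpha2[(v,)] = 0.0

    simplices = sorted(alpha2, key=lambda s: (alpha2[s], len(s), s))
    alpha = np.sqrt(np.maximum([alpha2[s] for s in simplices], 0.0))
    return FilteredComplex(n_points=n, simplices=tuple(simplices), alpha=alpha)
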