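"""Featurization of molecular point clouds.

The central feature is the topological feature vector (TFV): a
fixed-length nonnegative vector with one slot per unordered atom pair
(i, j), i < j, of length M = n(n-1)/2.  A slot accumulates, over all
degree-1 generators whose volume-optimal cycle uses that edge, the
generator's death radius (or birth, or lifetime); edges used by no cycle
stay 0.  Because the slot layout depends only on the atom count, TFVs
from snapshots with different loop counts live in the same space and
feed directly into matrix factorizations.

Comparison features from the same literature are provided alongside:
binary contact maps at an 8 A cutoff, flattened Cartesian coordinate
vectors (optionally superposed on a reference), distance maps, and the
accumulated bar length scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .alpha import build_alpha_filtration
from .cloud import PointCloud
from .persistence import accumulated_bar_length  # noqa: F401  (re-export)
from .persistence import compute_persistence
from .volume import Generator, generators_of_cloud

_MODES = ("death", "birth", "lifetime")


def edge_slot(i: int, j: int, n: int) -> int:
    """Canonical slot of the unordered pair (i, j), i < j, among the
    M = n(n-1)/2 pairs: slot = i*n - i(i+1)/2 + (j - i - 1), 0-based."""
    if not (0 <= i < j < n):
        raise ValueError(f"need 0 <= i < j < n, got ({i}, {j}) with n={n}")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def slot_edge(slot: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`edge_slot`."""
    m = n * (n - 1) // 2
    if not 0 <= slot < m:
        raise ValueError(f"slot {slot} out of range for n={n}")
    i = 0
    while slot >= n - i - 1:
        slot -= n - i - 1
        i += 1
    return i, i + 1 + slot


def edge_labels(n: int) -> list[str]:
    """Slot-ordered labels "i-j" (0-based) for all M pairs."""
    return [f"{i}-{j}" for i in range(n) for j in range(i + 1, n)]


@dataclass(frozen=True)
class TFV:
    """A topological feature vector over the M = n(n-1)/2 atom pairs."""

    values: np.ndarray  # length M, nonnegative, Angstrom
    n: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n * (self.n - 1) // 2,):
            raise ValueError("TFV length must be n(n-1)/2")
        object.__setattr__(self, "values", v)

    def __getitem__(self, edge: tuple[int, int]) -> float:
        i, j = sorted(edge)
        return float(self.values[edge_slot(i, j, self.n)])


def build_tfv(generators: list[Generator], n: int,
              mode: str = "death") -> TFV:
    """Aggregate generators into a TFV.

    Each generator adds its death (default), birth or lifetime to the
    slot of every edge in its volume-optimal cycle.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    v = np.zeros(n * (n - 1) // 2)
    for g in generators:
        p = g.pair
        w = {"death": p.death, "birth": p.birth,
             "lifetime": p.death - p.birth}[mode]
        for (i, j) in g.cycle:
            if not (0 <= i < j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for n={n}")
            v[edge_slot(i, j, n)] += w
    return TFV(values=v, n=n)


class TopologicalFeaturizer(BaseEstimator, TransformerMixin):
    """Transform point-cloud frames into a matrix of TFVs.

    A stateless sklearn-style transformer: ``transform`` runs, per
    frame, the alpha filtration, degree-1 persistence and the
    volume-optimal cycle solver, and stacks the resulting TFVs as rows.

    Parameters
    ----------
    mode : {"death", "birth", "lifetime"}
        Edge weight accumulated per generator (default "death").
    volume_method : {"auto", "exhaustive", "milp"}
        Solver for the optimal volumes.
    """

    def __init__(self, mode: str = "death", volume_method: str = "auto"):
        self.mode = mode
        self.volume_method = volume_method

    def fit(self, X, y=None):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        self.n_atoms_ = self._as_clouds(X)[0].n
        self.n_features_out_ = self.n_atoms_ * (self.n_atoms_ - 1) // 2
        return self

    @staticmethod
    def _as_clouds(X) -> list[PointCloud]:
        if isinstance(X, PointCloud):
            return [X]
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [PointCloud(f) for f in X]
        return [f if isinstance(f, PointCloud) else PointCloud(f) for f in X]

    def transform(self, X) -> np.ndarray:
        """Return the (n_frames, M) TFV matrix."""
        clouds = self._as_clouds(X)
        if not hasattr(self, "n_atoms_"):
            self.fit(clouds)
        rows = []
        for cloud in clouds:
            if cloud.n != self.n_atoms_:
                raise ValueError("all frames must share the atom count")
            rows.append(self.frame_tfv(cloud).values)
        return np.asarray(rows)

    def frame_tfv(self, cloud: PointCloud) -> TFV:
        """TFV of a single frame (runs the full topological stage)."""
        gens = self.frame_generators(cloud)
        return build_tfv(gens, cloud.n, mode=self.mode)

    def frame_generators(self, cloud: PointCloud) -> list[Generator]:
        fc = build_alpha_filtration(cloud)
        pairs = compute_persistence(fc)
        return generators_of_cloud(fc, pairs, method=self.volume_method)


@dataclass(frozen=True)
class ContactMap:
    """Binary contact map: entry 1 iff the pair distance is strictly
    below the threshold (diagonal and i >= j excluded)."""

    matrix: np.ndarray  # (n, n) symmetric 0/1
    threshold: float

    def flattened(self) -> np.ndarray:
        """Upper-triangle entries in the canonical TFV slot order."""
        n = self.matrix.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.matrix[iu].astype(float)


def contact_map(cloud: PointCloud, threshold: float = 8.0) -> ContactMap:
    """Contact map at a strict distance threshold (default 8 A)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if cloud.n < 2:
        raise ValueError("contact map needs at least two points")
    d = squareform(pdist(cloud.coords))
    mat = (d < threshold).astype(np.int8)
    np.fill_diagonal(mat, 0)
    return ContactMap(matrix=mat, threshold=threshold)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto
    ``reference``; returns the moved copy."""
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    H = (mob - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (mob - mc) @ R.T + rc


def cartesian_feature(cloud: PointCloud,
                      reference: PointCloud | None = None) -> np.ndarray:
    """Flattened 3n-vector (x1, y1, z1, ..., xn, yn, zn), optionally
    after rigid superposition onto ``reference``."""
    coords = cloud.coords
    if reference is not None:
        if reference.n != cloud.n:
            raise ValueError("reference must have the same atom count")
        coords = superpose(coords, reference.coords)
    return coords.reshape(-1).copy()


def distance_map(cloud: PointCloud) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix (A), zero diagonal."""
    if cloud.n < 2:
        raise ValueError("distance map needs at least two points")
    return squareform(pdist(cloud.coords))
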