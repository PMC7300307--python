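"""Optimal volumes and volume-optimal cycles for persistence pairs.

A persistence pair's *optimal volume* is the smallest mod-2 chain of
triangles V such that

* the death triangle belongs to V and every other triangle of V
  precedes it in the filtration order,
* the mod-2 boundary of V contains the birth edge and no edge that
  enters the filtration after the birth edge.

Its boundary is the *volume-optimal cycle*: the canonical set of edges
representing the loop.  The minimum triangle count is unique; the set
attaining it need not be, so a deterministic tie-break is applied (see
``compute_optimal_volume``).

Two solvers are provided: exhaustive enumeration by increasing chain
size (used for small candidate sets, and returning the lexicographically
smallest optimum), and an exact 0/1 integer program where the mod-2
parity constraints are encoded with auxiliary integer slack variables,
solved with HiGHS through :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import csr_matrix

from .alpha import FilteredComplex
from .persistence import PersistencePair

_EXHAUSTIVE_LIMIT = 20


@dataclass(frozen=True)
class Generator:
    """A degree-1 generator: a persistence pair together with its
    optimal volume (triangles) and volume-optimal cycle (edges)."""

    pair: PersistencePair
    volume: frozenset[tuple[int, int, int]]
    cycle: frozenset[tuple[int, int]]


def _boundary_edges(volume) -> frozenset[tuple[int, int]]:
    """Mod-2 boundary of a triangle chain."""
    parity: dict[tuple[int, int], int] = {}
    for (a, b, c) in volume:
        for e in ((a, b), (a, c), (b, c)):
            parity[e] = parity.get(e, 0) ^ 1
    return frozenset(e for e, p in parity.items() if p)


def _candidates(fc: FilteredComplex, pair: PersistencePair):
    """Candidate triangles (before the death triangle, plus itself) and
    the parity constraints on their edges."""
    death_pos = fc.position(pair.death_triangle)
    birth_pos = fc.position(pair.birth_edge)
    cands = [t for t in fc.of_dim(2) if fc.position(t) <= death_pos]
    cands.sort(key=fc.position)
    # edges whose parity is constrained: the birth edge (odd) and every
    # edge entering after it (even, i.e. absent from the boundary)
    edge_ids: dict[tuple[int, int], int] = {}
    tri_edge_masks = []
    for (a, b, c) in cands:
        mask = 0
        for e in ((a, b), (a, c), (b, c)):
            if fc.position(e) >= birth_pos:
                if e not in edge_ids:
                    edge_ids[e] = len(edge_ids)
                mask |= 1 << edge_ids[e]
        tri_edge_masks.append(mask)
    target = 1 << edge_ids[pair.birth_edge]  # birth edge odd, the rest even
    return cands, tri_edge_masks, target


def _solve_exhaustive(cands, masks, target, death_idx):
    """Enumerate chains containing the death triangle by increasing
    size; first hit is the lexicographically smallest optimum."""
    others = [i for i in range(len(cands)) if i != death_idx]
    base = masks[death_idx]
    if base == target:
        return [death_idx]
    for size in range(1, len(others) + 1):
        for combo in combinations(others, size):
            acc = base
            for i in combo:
                acc ^= masks[i]
            if acc == target:
                return sorted([death_idx, *combo])
    return None


def _solve_milp(cands, masks, target, death_idx, n_edges):
    """Exact ILP: minimize triangle count subject to mod-2 parity
    (encoded via integer slacks), with a cardinality-preserving
    index-sum perturbation as deterministic tie-break."""
    m = len(cands)
    # rows: constrained edges; columns: triangle indicators then slacks
    rows, cols, vals = [], [], []
    tris_per_edge = np.zeros(n_edges, dtype=int)
    for j, mask in enumerate(masks):
        e = 0
        while mask:
            if mask & 1:
                rows.append(e)
                cols.append(j)
                vals.append(1.0)
                tris_per_edge[e] += 1
            mask >>= 1
            e += 1
    for e in range(n_edges):
        rows.append(e)
        cols.append(m + e)
        vals.append(-2.0)
    A = csr_matrix((vals, (rows, cols)), shape=(n_edges, m + n_edges))
    rhs = np.zeros(n_edges)
    te = 0
    t = target
    while not (t & 1):
        t >>= 1
        te += 1
    rhs[te] = 1.0

    eps = 0.5 / (m * m + 1.0)
    c = np.concatenate([1.0 + eps * np.arange(m), np.zeros(n_edges)])
    lb = np.zeros(m + n_edges)
    ub = np.concatenate([np.ones(m), np.maximum(tris_per_edge // 2, 1)])
    lb[death_idx] = 1.0
    res = milp(c=c, constraints=LinearConstraint(A, rhs, rhs),
               integrality=np.ones(m + n_edges),
               bounds=(lb, ub))
    if not res.success:
        return None
    z = np.round(res.x[:m]).astype(int)
    return [j for j in range(m) if z[j] == 1]


def compute_optimal_volume(fc: FilteredComplex, pair: PersistencePair,
                           method: str = "auto") -> Generator:
    """Solve for a pair's optimal volume and volume-optimal cycle.

    Parameters
    ----------
    fc : FilteredComplex
        The filtration the pair was computed from.
    pair : PersistencePair
    method : {"auto", "exhaustive", "milp"}
        "auto" enumerates exhaustively when at most 20 candidate
        triangles exist and uses the integer program otherwise.

    Returns
    -------
    Generator
        With ``volume`` minimizing the triangle count and ``cycle`` its
        mod-2 boundary (which contains the birth edge).

    Raises
    ------
    RuntimeError
        If the program is infeasible, which indicates an inconsistent
        pair/filtration combination.
    """
    cands, masks, target = _candidates(fc, pair)
    death_idx = cands.index(tuple(sorted(pair.death_triangle)))
    if method == "auto":
        method = "exhaustive" if len(cands) <= _EXHAUSTIVE_LIMIT else "milp"
    if method == "exhaustive":
        sol = _solve_exhaustive(cands, masks, target, death_idx)
    elif method == "milp":
        n_edges = max(int(mask).bit_length() for mask in masks + [target])
        sol = _solve_milp(cands, masks, target, death_idx, n_edges)
    else:
        raise ValueError(f"unknown method {method!r}")
    if sol is None:
        raise RuntimeError(
            "optimal-volume program infeasible; the pair does not belong "
            "to this filtration")
    volume = frozenset(cands[j] for j in sol)
    return Generator(pair=pair, volume=volume, cycle=_boundary_edges(volume))


def generators_of_cloud(fc: FilteredComplex, pairs=None,
                        method: str = "auto") -> list[Generator]:
    """Convenience: optimal volumes for all (or given) pairs of a
    filtration, in ascending birth order."""
    from .persistence import compute_persistence
    if pairs is None:
        pairs = compute_persistence(fc)
    return [compute_optimal_volume(fc, p, method=method) for p in pairs]
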