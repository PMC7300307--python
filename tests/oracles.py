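"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's persistence/optimization code
paths: Betti numbers come from dense mod-2 rank-nullity over the
subcomplex at a radius, and minimal volumes from exhaustive subset
search with direct invariant checking.
"""

from itertools import combinations


def _rank_gf2(columns):
    """Rank of a set of GF(2) columns given as Python-int bitmasks."""
    pivots = {}
    rank = 0
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low in pivots:
                col ^= pivots[low]
            else:
                pivots[low] = col
                rank += 1
                break
    return rank


def betti1_dense(fc, r):
    """First Betti number of the subcomplex {sigma : alpha <= r} by
    rank-nullity: dim ker(d1) - rank(d2)."""
    simp = [s for s, a in zip(fc.simplices, fc.alpha) if a <= r]
    verts = {s[0]: i for i, s in enumerate(simp) if len(s) == 1}
    edges = [s for s in simp if len(s) == 2]
    tris = [s for s in simp if len(s) == 3]
    eidx = {e: i for i, e in enumerate(edges)}
    d1 = [(1 << verts[e[0]]) | (1 << verts[e[1]]) for e in edges]
    d2 = []
    for (a, b, c) in tris:
        col = 0
        for e in ((a, b), (a, c), (b, c)):
            col ^= 1 << eidx[e]
        d2.append(col)
    return (len(edges) - _rank_gf2(d1)) - _rank_gf2(d2)


def minimal_volume_size(fc, pair):
    """Size of the smallest triangle chain containing the death
    triangle whose mod-2 boundary includes the birth edge and no edge
    later than it, by exhaustive subset search."""
    death_pos = fc.position(pair.death_triangle)
    birth_pos = fc.position(pair.birth_edge)
    cands = [t for t in fc.of_dim(2) if fc.position(t) <= death_pos]
    death = tuple(sorted(pair.death_triangle))
    others = [t for t in cands if t != death]

    def feasible(chain):
        parity = {}
        for (a, b, c) in chain:
            for e in ((a, b), (a, c), (b, c)):
                parity[e] = parity.get(e, 0) ^ 1
        boundary = {e for e, p in parity.items() if p}
        if pair.birth_edge not in boundary:
            return False
        return all(fc.position(e) <= birth_pos for e in boundary)

    for size in range(1, len(cands) + 1):
        for combo in combinations(others, size - 1):
            if feasible((death, *combo)):
                return size
    raise AssertionError("no feasible volume exists")
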