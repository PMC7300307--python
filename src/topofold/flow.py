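"""Flow-field analysis of folding dynamics in the reduced space.

Given the per-frame reduced coordinates h(t) (Angstrom, nonnegative),
the one-step displacements dh(t) = h(t + dt) - h(t) are binned on a
square grid (default 1.5 x 1.5 A, origin at 0) by the cell containing
the *source* frame, and averaged per cell.  Cells with fewer samples
than a count floor are masked: a single-sample average is noise, not
flow.  Candidate fixed points are local minima of the mean-flow
magnitude; each is classified by the eigenvalues of a linear map fitted
to the neighborhood flow (both real parts negative: stable; mixed
signs: saddle; otherwise unclassified).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EIG_TOL = 0.02  # per-step contraction below which an eigenvalue is noise


@dataclass(frozen=True)
class ReducedTrajectory:
    """Uniformly sampled reduced-space time series.

    times are in ps, strictly increasing with constant spacing; h is the
    (n_frames, L) array of nonnegative reduced coordinates in Angstrom.
    """

    times: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.h, dtype=float)
        if t.ndim != 1 or h.ndim != 2 or h.shape[0] != t.shape[0]:
            raise ValueError("times (N,) and h (N, L) must align")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8,
                                                  atol=1e-10):
                raise ValueError("times must be strictly increasing and "
                                 "uniformly spaced")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "h", h)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class FlowField:
    """Grid-averaged displacement field in a 2-D reduced space."""

    cell: float              # grid cell edge (A); origin at 0
    mean: np.ndarray         # (nx, ny, 2) mean dh per cell (A)
    counts: np.ndarray       # (nx, ny) samples per cell
    var: np.ndarray          # (nx, ny) per-component sample variance of dh
    min_count: int = 10

    @property
    def mask(self) -> np.ndarray:
        """True where a cell holds enough samples to be trusted."""
        return self.counts >= self.min_count

    def standard_error(self) -> np.ndarray:
        """Per-cell standard error of the mean displacement (A)."""
        se = np.full(self.counts.shape, np.inf)
        ok = self.counts > 0
        se[ok] = np.sqrt(self.var[ok] / self.counts[ok])
        return se

    def cell_center(self, ix: int, iy: int) -> np.ndarray:
        return (np.array([ix, iy]) + 0.5) * self.cell


def flow_field(traj: ReducedTrajectory, cell: float = 1.5,
               min_count: int = 10,
               components: tuple[int, int] = (0, 1)) -> FlowField:
    """Grid-average the one-step displacements of a reduced trajectory.

    For L > 2, ``components`` picks the coordinate pair whose marginal
    flow is computed.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if traj.h.shape[0] < 2:
        raise ValueError("need at least two frames")
    h = traj.h[:, list(components)]
    dh = np.diff(h, axis=0)
    src = h[:-1]
    idx = np.floor(src / cell).astype(int)
    idx = np.maximum(idx, 0)  # h is nonnegative; guard roundoff
    nx, ny = idx.max(axis=0) + 1
    sums = np.zeros((nx, ny, 2))
    sq = np.zeros((nx, ny))
    counts = np.zeros((nx, ny), dtype=int)
    np.add.at(counts, (idx[:, 0], idx[:, 1]), 1)
    np.add.at(sums, (idx[:, 0], idx[:, 1]), dh)
    np.add.at(sq, (idx[:, 0], idx[:, 1]), np.einsum("ij,ij->i", dh, dh))
    mean = np.zeros_like(sums)
    nonzero = counts > 0
    mean[nonzero] = sums[nonzero] / counts[nonzero, None]
    # per-component variance, averaged over the two components
    var = np.zeros_like(sq)
    var[nonzero] = np.maximum(
        sq[nonzero] / counts[nonzero]
        - np.einsum("ij,ij->i", mean[nonzero], mean[nonzero]), 0.0) / 2.0
    return FlowField(cell=cell, mean=mean, counts=counts, var=var,
                     min_count=min_count)


def _fit_local_map(field: FlowField, ix: int, iy: int, radius: int = 2):
    """Inverse-variance weighted affine fit dh ~ J (x - center) + r
    over the unmasked cells in the (2 radius + 1)^2 neighborhood.

    Returns (J, r, slope_se): the local linear map, the flow at the
    cell center, and the standard error of the fitted J entries, so the
    caller can refuse to classify eigenvalues indistinguishable from
    sampling noise.
    """
    nx, ny = field.counts.shape
    se = field.standard_error()
    rows_x, rows_y, w = [], [], []
    for jx in range(max(0, ix - radius), min(nx, ix + radius + 1)):
        for jy in range(max(0, iy - radius), min(ny, iy + radius + 1)):
            if field.counts[jx, jy] >= field.min_count:
                rows_x.append(field.cell_center(jx, jy))
                rows_y.append(field.mean[jx, jy])
                w.append(1.0 / max(se[jx, jy], 1e-12))
    if len(rows_x) < 6:
        return None, None, np.inf
    X = np.asarray(rows_x) - field.cell_center(ix, iy)
    Y = np.asarray(rows_y)
    w = np.asarray(w)[:, None]
    A = np.c_[X, np.ones(len(X))]
    coef, *_ = np.linalg.lstsq(A * w, Y * w, rcond=None)
    J = coef[:2].T        # (2, 2) local linear map
    r = coef[2]           # flow at the cell center
    try:
        cov = np.linalg.inv((A * w).T @ (A * w))
        slope_se = float(np.sqrt(np.mean(np.diag(cov)[:2])))
    except np.linalg.LinAlgError:
        slope_se = np.inf
    return J, r, slope_se


def fixed_point_summary(field: FlowField, eig_tol: float = _EIG_TOL
                        ) -> list[tuple[np.ndarray, str]]:
    """Candidate fixed points with a stability classification.

    Returns a list of (location (2,) in A, type) where type is
    "stable", "saddle" or "unclassified".  Candidates are unmasked
    cells whose mean-flow magnitude is a local minimum among unmasked
    neighbors; neighboring candidates of equal type are merged keeping
    the weaker flow.  Eigenvalues with |Re| below ``eig_tol`` are
    treated as indistinguishable from zero (a diffusive random walk
    yields no classification).
    """
    ok = field.mask
    if not ok.any():
        return []
    mag = np.linalg.norm(field.mean, axis=2)
    nx, ny = ok.shape
    candidates = []
    for ix in range(nx):
        for iy in range(ny):
            if not ok[ix, iy]:
                continue
            m0 = mag[ix, iy]
            is_min = True
            for jx in range(max(0, ix - 1), min(nx, ix + 2)):
                for jy in range(max(0, iy - 1), min(ny, iy + 2)):
                    if (jx, jy) != (ix, iy) and ok[jx, jy] \
                            and mag[jx, jy] < m0:
                        is_min = False
            if is_min:
                candidates.append((ix, iy, m0))

    results = []
    for ix, iy, m0 in candidates:
        J, r, slope_se = _fit_local_map(field, ix, iy)
        center = field.cell_center(ix, iy)
        kind = "unclassified"
        loc = center
        if J is not None:
            # an eigenvalue counts only if it clears both the noise
            # tolerance and three times its sampling standard error
            thr = max(eig_tol, 3.0 * slope_se)
            eig = np.linalg.eigvals(J)
            re = np.sort(eig.real)
            if re[1] < -thr:
                kind = "stable"
            elif re[0] < -thr < thr < re[1]:
                kind = "saddle"
            # a genuine fixed point must have the linear model's zero
            # J (x - center) + r = 0 close by; a distant zero marks a
            # mere valley of weak flow, not a fixed point
            if kind != "unclassified":
                try:
                    shift = -np.linalg.solve(J, r)
                    if np.linalg.norm(shift) <= 1.5 * field.cell:
                        loc = center + shift
                    else:
                        kind = "unclassified"
                except np.linalg.LinAlgError:
                    kind = "unclassified"
        results.append((ix, iy, m0, loc, kind))

    # merge nearby candidates of the same kind, keeping the weakest
    # flow: same-kind minima closer than two cells are unresolvable
    results.sort(key=lambda t: t[2])
    kept: list[tuple[int, int, float, np.ndarray, str]] = []
    for cand in results:
        if any(k[4] == cand[4] and max(abs(k[0] - cand[0]),
                                       abs(k[1] - cand[1])) <= 2
               for k in kept):
            continue
        kept.append(cand)
    return [(loc, kind) for _, _, _, loc, kind in kept]
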