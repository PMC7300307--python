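"""Synthetic fixtures: geometric clouds with known persistence and
MD-like two-state hairpin trajectories.

The trajectory generator emulates the phenomenology of a 10-residue
beta-hairpin miniprotein sampled near its folding transition: a native
state closing one loop contact (residue pair 2-9, 0-based (1, 8)), a
misfolded state closing the neighboring contact (2-8, 0-based (1, 7)),
and an extended noisy unfolded state with essentially no loops, with
discrete Markov switching between states over frames.  Geometry is
built from deterministic per-state templates (a closed polygon for the
hairpin loop, puckered out of plane, plus extended tails) with Gaussian
coordinate noise per frame; there is no force field and no claim to
thermodynamic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud
from .flow import ReducedTrajectory


# ---------------------------------------------------------------------------
# geometric fixtures

def _tilt(points: np.ndarray, angle: float = 0.3) -> np.ndarray:
    """Rotate out of the xy-plane (guards against exact coplanarity of
    the ambient frame, not of the points themselves)."""
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    return points @ R.T


def generate_ring(m: int, radius: float = 5.0, noise: float = 0.0,
                  seed: int = 0) -> PointCloud:
    """m points near a circle of the given radius (A), in a tilted
    plane, with a deterministic 1e-8 A jitter lifting the cocircular
    degeneracy; optional isotropic Gaussian noise on top.

    With zero noise the dominant persistence pair dies at the circle
    radius to within 1e-6 A.
    """
    if m < 3:
        raise ValueError("a ring needs at least 3 points")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    pts = np.c_[radius * np.cos(theta), radius * np.sin(theta), np.zeros(m)]
    pts = pts + rng.normal(scale=1e-8, size=pts.shape)
    if noise > 0:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return PointCloud(_tilt(pts))


def generate_fig1_cloud() -> PointCloud:
    """Six labeled points p1..p6 with a two-loop filtration story.

    A small loop bounded by (p3 p5), (p3 p6), (p5 p6) is born first and
    dies early; a larger pentagonal loop p1-p2-p4-p6-p3 then forms whose
    optimal volume has exactly 3 triangles and whose volume-optimal
    cycle has 5 edges (the 6-edge route through p5 needs 4 triangles and
    is rejected by the minimization).

    Points p3, p1, p2, p4, p6 sit on a circle (chord p3-p6 = 4.0 A, the
    other four chords 4.6 A) and p5 sits 2.8 A outside the chord p3-p6;
    a small deterministic z-offset removes coplanarity.
    """
    chord_small, chord_big, h5 = 4.0, 4.6, 2.8

    def gap(R):
        return 4 * np.arcsin(chord_big / (2 * R)) \
            + np.arcsin(chord_small / (2 * R)) - np.pi

    lo, hi = chord_big / 2 + 1e-9, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    R = 0.5 * (lo + hi)

    phi0 = np.arcsin(chord_small / (2 * R))
    psi = 2 * np.arcsin(chord_big / (2 * R))
    ang = {  # pentagon cycle p3 - p1 - p2 - p4 - p6
        3: np.pi / 2 + phi0,
        1: np.pi / 2 + phi0 + psi,
        2: np.pi / 2 + phi0 + 2 * psi,
        4: np.pi / 2 + phi0 + 3 * psi,
        6: np.pi / 2 - phi0,
    }
    pts = np.zeros((6, 3))
    for label, a in ang.items():
        pts[label - 1, :2] = R * np.cos(a), R * np.sin(a)
    pts[4, :2] = 0.0, R * np.cos(phi0) + h5            # p5 above chord p3-p6
    pts[:, 2] = 0.04 * np.array([1, -2, 2, -1, 3, -3])  # break coplanarity
    return PointCloud(pts, labels=tuple(f"p{i}" for i in range(1, 7)))


# ---------------------------------------------------------------------------
# two-state hairpin trajectories

@dataclass(frozen=True)
class StateSpec:
    """One conformational state: a contact pair closing the hairpin at
    a target distance, or an extended (unfolded) state if contact is
    None."""

    name: str
    contact: tuple[int, int] | None
    contact_distance: float | None = 5.0
    dwell_mean: float = 50.0  # frames


@dataclass(frozen=True)
class TrajectorySpec:
    """Study conditions for the synthetic two-state generator."""

    n: int = 10
    bond_length: float = 3.8           # Angstrom, consecutive C-alpha
    states: tuple[StateSpec, ...] = (
        StateSpec("native", (1, 8), 5.0, 50.0),
        StateSpec("misfolded", (1, 7), 5.0, 50.0),
        StateSpec("unfolded", None, None, 50.0),
    )
    noise_sigma: float = 0.2           # Angstrom, per coordinate
    n_frames: int = 2000
    frame_interval: float = 10.0       # ps
    seed: int = 0
    pucker: float = 0.3                # out-of-plane alternation, Angstrom

    def __post_init__(self) -> None:
        for s in self.states:
            if s.contact is not None:
                i, j = s.contact
                if not (0 <= i < j < self.n):
                    raise ValueError(f"contact pair {s.contact} invalid")
                if s.contact_distance <= self.bond_length / 2:
                    raise ValueError("contact distance geometrically "
                                     "infeasible for this bond length")
            if s.dwell_mean < 1:
                raise ValueError("dwell means must be >= 1 frame")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


def _loop_radius(k: int, bond: float, chord: float) -> float:
    """Circle radius for a closed polygon of k-1 bonds plus one closing
    chord."""
    def gap(R):
        return (k - 1) * 2 * np.arcsin(min(bond / (2 * R), 1.0)) \
            + 2 * np.arcsin(min(chord / (2 * R), 1.0)) - 2 * np.pi

    lo = max(bond, chord) / 2 + 1e-9
    hi = k * bond  # generous upper bound
    if gap(lo) < 0:
        raise ValueError("contact distance geometrically infeasible")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hairpin_template(spec: TrajectorySpec, state: StateSpec) -> np.ndarray:
    """Deterministic coordinates of one state's template chain."""
    n, bond = spec.n, spec.bond_length
    coords = np.zeros((n, 3))
    if state.contact is None:
        # extended chain: gentle non-planar curvature, total turning well
        # below pi so the chain closes no loop
        for i in range(1, n):
            theta = 0.18 * (i - 1)
            phi = 0.15 * np.sin(1.9 * i)
            d = np.array([np.cos(phi) * np.cos(theta),
                          np.cos(phi) * np.sin(theta),
                          np.sin(phi)])
            coords[i] = coords[i - 1] + bond * d
        return coords - coords.mean(axis=0)

    a, b = state.contact
    k = b - a + 1
    rho = _loop_radius(k, bond, state.contact_distance)
    chord_angle = 2 * np.arcsin(state.contact_distance / (2 * rho))
    bond_angle = 2 * np.arcsin(bond / (2 * rho))
    # loop beads a..b on the circle; closing chord between beads a and b
    start = np.pi / 2 + chord_angle / 2
    for off in range(k):
        ang = start + off * bond_angle
        coords[a + off, :2] = rho * np.cos(ang), rho * np.sin(ang)
    # tails extend radially outward from the loop ends
    for i in range(a - 1, -1, -1):
        u = coords[i + 1, :2] / np.linalg.norm(coords[i + 1, :2])
        coords[i, :2] = coords[i + 1, :2] + bond * u
    for i in range(b + 1, n):
        u = coords[i - 1, :2] / np.linalg.norm(coords[i - 1, :2])
        coords[i, :2] = coords[i - 1, :2] + bond * u
    coords[:, 2] = spec.pucker * ((np.arange(n) % 2) * 2 - 1)
    return coords - coords.mean(axis=0)


@dataclass(frozen=True)
class SyntheticTrajectory:
    """Frames, per-frame true state labels, and times (ps)."""

    coords: np.ndarray           # (n_frames, n, 3), Angstrom
    labels: tuple[str, ...]
    times: np.ndarray            # ps
    spec: TrajectorySpec = field(repr=False)

    @property
    def clouds(self) -> list[PointCloud]:
        return [PointCloud(f) for f in self.coords]


def generate_two_state_trajectory(spec: TrajectorySpec) -> SyntheticTrajectory:
    """Markov-switching trajectory over the spec's states.

    The state sequence is a discrete Markov chain whose per-state exit
    probability is 1/dwell_mean (uniform over the other states); frame
    coordinates are the state template plus isotropic Gaussian noise.
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    templates = {s.name: hairpin_template(spec, s) for s in spec.states}
    names = [s.name for s in spec.states]
    state = 0
    labels, frames = [], []
    for _ in range(spec.n_frames):
        labels.append(names[state])
        frame = templates[names[state]].copy()
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(scale=spec.noise_sigma,
                                       size=frame.shape)
        frames.append(frame)
        if len(names) > 1 and rng.random() < 1.0 / spec.states[state].dwell_mean:
            others = [i for i in range(len(names)) if i != state]
            state = others[rng.integers(len(others))]
    times = np.arange(spec.n_frames) * spec.frame_interval
    return SyntheticTrajectory(coords=np.asarray(frames),
                               labels=tuple(labels), times=times, spec=spec)


# ---------------------------------------------------------------------------
# planted reduced-space dynamics

def generate_double_well_reduced(
        seed: int = 0, n_frames: int = 120_000,
        wells: tuple[tuple[float, float], tuple[float, float]] =
        ((20.0, 5.0), (5.0, 20.0)),
        noise: float = 1.5, barrier_curvature: float = 0.1,
        transverse_curvature: float = 0.15,
        frame_interval: float = 10.0,
) -> tuple[ReducedTrajectory, dict]:
    """Langevin steps in a 2-D double-well landscape with a saddle on
    the inter-well line.

    The potential is quartic along the axis joining the wells (minima
    at the wells, barrier at their midpoint) and harmonic transverse to
    it; coordinates are reflected at the axes to keep h nonnegative.
    Returns the trajectory and the planted fixed-point locations.
    """
    rng = np.random.default_rng(seed)
    w1, w2 = np.asarray(wells[0], float), np.asarray(wells[1], float)
    mid = 0.5 * (w1 + w2)
    e1 = (w1 - w2) / np.linalg.norm(w1 - w2)
    e2 = np.array([-e1[1], e1[0]])
    a = 0.5 * np.linalg.norm(w1 - w2)
    b, c = barrier_curvature, transverse_curvature

    h = np.empty((n_frames, 2))
    x = w1.copy()
    xi = rng.normal(size=(n_frames, 2))
    for t in range(n_frames):
        h[t] = x
        u = float((x - mid) @ e1)
        v = float((x - mid) @ e2)
        du = -(b / a**2) * u * (u * u - a * a) + noise * xi[t, 0]
        dv = -c * v + noise * xi[t, 1]
        x = np.abs(x + du * e1 + dv * e2)  # reflect at the h >= 0 boundary
    times = np.arange(n_frames) * frame_interval
    planted = {"stable": [w1.copy(), w2.copy()], "saddle": mid.copy()}
    return ReducedTrajectory(times=times, h=h), planted
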