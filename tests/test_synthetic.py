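"""Synthetic generators: known persistence of geometric fixtures,
trajectory determinism, and chain-geometry sanity."""

import numpy as np
import pytest

from topofold.alpha import build_alpha_filtration
from topofold.cloud import PointCloud
from topofold.persistence import compute_persistence
from topofold.synthetic import (StateSpec, TrajectorySpec, generate_ring,
                                generate_two_state_trajectory,
                                hairpin_template)


def _pairs(cloud):
    return compute_persistence(build_alpha_filtration(cloud))


def test_ring_death_equals_radius():
    pairs = _pairs(generate_ring(20, radius=5.0, noise=0.0, seed=3))
    long_lived = [p for p in pairs if p.lifetime > 1.0]
    assert len(long_lived) == 1
    assert long_lived[0].death == pytest.approx(5.0, abs=1e-6)
    # birth is half the largest chord gap between adjacent points
    gap = 2 * 5.0 * np.sin(np.pi / 20)
    assert long_lived[0].birth == pytest.approx(gap / 2, abs=1e-3)


def test_three_point_ring_single_pair():
    pairs = _pairs(generate_ring(3, radius=4.0, seed=1))
    assert len(pairs) == 1
    assert pairs[0].death == pytest.approx(4.0, abs=1e-6)


def test_ring_deterministic_given_seed():
    a = generate_ring(12, 5.0, noise=0.1, seed=9)
    b = generate_ring(12, 5.0, noise=0.1, seed=9)
    assert np.array_equal(a.coords, b.coords)
    with pytest.raises(ValueError):
        generate_ring(2, 5.0)


def test_six_point_cloud_two_loop_story(fig1_filtration):
    _, _, pairs = fig1_filtration
    assert len(pairs) >= 2
    # the small triangle loop precedes the pentagon loop and also dies
    # before it is born
    assert pairs[0].birth < pairs[1].birth
    assert pairs[0].death < pairs[1].birth
    # the pentagon pair is the dominant (longest-lived) generator
    assert max(pairs, key=lambda p: p.lifetime) == pairs[1]


def test_trajectory_deterministic_and_labeled():
    spec = TrajectorySpec(seed=5, n_frames=100)
    a = generate_two_state_trajectory(spec)
    b = generate_two_state_trajectory(spec)
    assert np.array_equal(a.coords, b.coords)
    assert a.labels == b.labels
    assert a.coords.shape == (100, 10, 3)
    assert set(a.labels) <= {"native", "misfolded", "unfolded"}
    assert np.allclose(np.diff(a.times), spec.frame_interval)


def test_frozen_state_with_zero_noise_is_static():
    spec = TrajectorySpec(
        seed=1, n_frames=20, noise_sigma=0.0,
        states=(StateSpec("native", (1, 8), 5.0, 1e12),))
    traj = generate_two_state_trajectory(spec)
    assert np.all(traj.coords == traj.coords[0])
    assert set(traj.labels) == {"native"}


def test_bond_lengths_stay_near_nominal(two_state_run):
    spec, traj = two_state_run["spec"], two_state_run["traj"]
    bonds = np.linalg.norm(np.diff(traj.coords, axis=1), axis=2)
    # independent endpoint noise gives bond-length sd sqrt(2) sigma;
    # the small extra margin covers the templates' geometric offset
    tol = 3.0 * np.sqrt(2) * spec.noise_sigma + 0.06
    frac = np.mean(np.abs(bonds - spec.bond_length) < tol)
    assert frac >= 0.99


def test_unfolded_tfvs_are_nearly_zero(two_state_run):
    X, labels = two_state_run["X"], two_state_run["labels"]
    norms = np.linalg.norm(X, axis=1)
    folded = np.median(norms[labels != "unfolded"])
    unfolded = np.median(norms[labels == "unfolded"])
    assert unfolded / folded < 0.3


def test_infeasible_contact_distance_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        TrajectorySpec(states=(StateSpec("bad", (1, 8), 1.0),))


def test_hairpin_template_closes_planted_contact():
    spec = TrajectorySpec()
    for state in spec.states:
        t = hairpin_template(spec, state)
        bonds = np.linalg.norm(np.diff(t, axis=0), axis=1)
        assert np.all(np.abs(bonds - spec.bond_length) < 0.1)
        if state.contact is not None:
            i, j = state.contact
            d = np.linalg.norm(t[i] - t[j])
            assert d == pytest.approx(state.contact_distance, abs=0.1)
            # the template's dominant loop uses the planted contact
            pairs = _pairs(PointCloud(t))
            dom = max(pairs, key=lambda p: p.lifetime)
            from topofold.volume import compute_optimal_volume
            fc = build_alpha_filtration(PointCloud(t))
            g = compute_optimal_volume(fc, dom)
            assert tuple(sorted((i, j))) in g.cycle
        else:
            assert _pairs(PointCloud(t)) == []
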