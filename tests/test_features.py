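"""TFV construction, edge indexing, and the comparison features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from topofold.cloud import PointCloud
from topofold.features import (TopologicalFeaturizer, accumulated_bar_length,
                               build_tfv, cartesian_feature, contact_map,
                               distance_map, edge_slot, slot_edge)
from topofold.persistence import PersistencePair
from topofold.volume import Generator


def _gen(edges, birth=1.0, death=2.0):
    return Generator(
        pair=PersistencePair(birth, death, tuple(sorted(edges[0])),
                             (0, 1, 2)),
        volume=frozenset({(0, 1, 2)}),
        cycle=frozenset(tuple(sorted(e)) for e in edges))


def test_tfv_dimension_and_zero_default():
    v = build_tfv([], n=10)
    assert v.values.shape == (45,)
    assert np.all(v.values == 0)


def test_tfv_sums_weights_per_mode():
    gens = [_gen([(0, 1), (1, 2), (0, 2)], birth=1.0, death=2.0),
            _gen([(0, 1), (1, 3), (0, 3)], birth=1.5, death=3.0)]
    death = build_tfv(gens, n=4, mode="death")
    birth = build_tfv(gens, n=4, mode="birth")
    life = build_tfv(gens, n=4, mode="lifetime")
    assert death[(0, 1)] == pytest.approx(5.0)
    assert death[(1, 2)] == pytest.approx(2.0)
    assert birth[(0, 1)] == pytest.approx(2.5)
    assert life[(0, 1)] == pytest.approx(2.5)
    # death-mode dominates birth-mode elementwise since d >= b
    assert np.all(death.values >= birth.values)
    assert np.all(birth.values >= 0)


def test_tfv_rejects_out_of_range_edges():
    with pytest.raises(ValueError, match="out of range"):
        build_tfv([_gen([(0, 5), (0, 1), (1, 5)])], n=4)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(2, 40))
def test_edge_slot_bijection(n):
    m = n * (n - 1) // 2
    slots = [edge_slot(i, j, n) for i in range(n) for j in range(i + 1, n)]
    assert sorted(slots) == list(range(m))
    for s in range(m):
        i, j = slot_edge(s, n)
        assert edge_slot(i, j, n) == s


def test_contact_map_strict_threshold():
    cm = contact_map(PointCloud(np.array([[0.0, 0, 0], [7.9, 0, 0]])))
    assert cm.matrix[0, 1] == 1
    cm = contact_map(PointCloud(np.array([[0.0, 0, 0], [8.0, 0, 0]])))
    assert cm.matrix[0, 1] == 0
    chain = PointCloud(np.array([[0.0, 0, 0], [4, 0, 0], [8, 0, 0]]))
    cm = contact_map(chain)
    assert cm.matrix[0, 1] == cm.matrix[1, 2] == 1
    assert cm.matrix[0, 2] == 0
    assert np.array_equal(cm.matrix, cm.matrix.T)
    # flattened form shares the TFV slot convention
    flat = cm.flattened()
    assert flat[edge_slot(0, 2, 3)] == 0 and flat[edge_slot(0, 1, 3)] == 1
    with pytest.raises(ValueError):
        contact_map(chain, threshold=0.0)


def test_cartesian_feature_alignment():
    rng = np.random.default_rng(3)
    ref = PointCloud(rng.uniform(0, 10, size=(10, 3)))
    assert cartesian_feature(ref).shape == (30,)
    assert np.allclose(cartesian_feature(ref, ref), ref.coords.ravel(),
                       atol=1e-9)
    R = Rotation.from_euler("xyz", [0.4, -1.0, 0.2]).as_matrix()
    moved = ref.transformed(rotation=R, translation=np.array([3.0, -1, 7]))
    assert np.allclose(cartesian_feature(moved, ref), ref.coords.ravel(),
                       atol=1e-6)
    with pytest.raises(ValueError, match="atom count"):
        cartesian_feature(moved, PointCloud(ref.coords[:5]))


def test_distance_map_values():
    pair = PointCloud(np.array([[0.0, 0, 0], [3, 0, 0]]))
    assert np.allclose(distance_map(pair), [[0, 3], [3, 0]])
    chain = PointCloud(np.array([[0.0, 0, 0], [4, 0, 0], [8, 0, 0]]))
    dm = distance_map(chain)
    assert dm[0, 2] == pytest.approx(8.0)
    assert np.all(dm >= 0) and np.allclose(dm, dm.T)


def test_accumulated_bar_length_sums_lifetimes():
    assert accumulated_bar_length([]) == 0.0
    pairs = [PersistencePair(1, 2, (0, 1), (0, 1, 2)),
             PersistencePair(2, 4, (0, 2), (0, 1, 2))]
    assert accumulated_bar_length(pairs) == pytest.approx(3.0)


def test_tfv_invariant_under_rigid_motion():
    rng = np.random.default_rng(9)
    pts = rng.uniform(0, 10, size=(8, 3))
    feat = TopologicalFeaturizer()
    v0 = feat.frame_tfv(PointCloud(pts)).values
    R = Rotation.from_euler("zxz", [1.2, 0.5, -0.8]).as_matrix()
    v1 = feat.frame_tfv(
        PointCloud(pts @ R.T + np.array([-4.0, 2.0, 9.0]))).values
    assert np.allclose(v0, v1, atol=1e-9)


def test_planted_contact_dominates_folded_tfvs(two_state_run):
    # within each folded state, the planted contact's slot should be
    # the largest non-backbone TFV entry in nearly every frame
    X, labels = two_state_run["X"], two_state_run["labels"]
    spec = two_state_run["spec"]
    n = spec.n
    backbone = {edge_slot(i, i + 1, n) for i in range(n - 1)}
    offdiag = np.array(sorted(set(range(n * (n - 1) // 2)) - backbone))
    for state in spec.states:
        if state.contact is None:
            continue
        rows = X[labels == state.name][:, offdiag]
        planted_col = np.where(
            offdiag == edge_slot(*state.contact, n))[0][0]
        hit = (np.argmax(rows, axis=1) == planted_col).mean()
        assert hit >= 0.95, state.name
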