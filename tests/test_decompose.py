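"""NMF/PCA reduction: planted-factor recovery, normalization, rank
selection, determinism, and the basis report."""

import numpy as np
import pytest

from topofold.decompose import (UnitNormNMF, basis_report,
                                dominant_offdiagonal_edge, nmf_decompose,
                                pca_decompose, rank_scan)
from topofold.features import edge_slot


def _planted_rank2(m=45, n=300, seed=0):
    rng = np.random.default_rng(seed)
    W0 = np.zeros((m, 2))
    W0[rng.choice(m, 8, replace=False), 0] = rng.uniform(1, 3, 8)
    W0[rng.choice(m, 8, replace=False), 1] = rng.uniform(1, 3, 8)
    H0 = rng.uniform(0, 10, size=(2, n))
    return W0 @ H0, W0


def test_planted_rank2_recovery():
    V, W0 = _planted_rank2()
    model = nmf_decompose(V, 2)
    assert model.rss < 1e-6 * np.sum(V * V)
    # span of the recovered bases matches the planted span
    q0, _ = np.linalg.qr(W0)
    q1, _ = np.linalg.qr(model.W)
    angles = np.arccos(np.clip(np.linalg.svd(q0.T @ q1)[1], -1, 1))
    assert np.max(angles) < 1e-3


def test_single_column_rank1_exact():
    c = np.array([3.0, 0.0, 4.0])
    V = np.zeros((3, 4))
    V[:, 2] = c
    model = nmf_decompose(V, 1)
    assert np.allclose(model.W[:, 0], c / 5.0, atol=1e-9)
    assert model.H[0, 2] == pytest.approx(5.0, abs=1e-9)
    assert model.rss == pytest.approx(0.0, abs=1e-12)


def test_unit_norm_and_reconstruction_unchanged():
    V, _ = _planted_rank2(seed=3)
    V = V + np.random.default_rng(3).uniform(0, 0.1, V.shape)
    for L in (1, 2, 3, 4):
        model = nmf_decompose(V, L)
        assert np.allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-9)
        assert np.all(model.W >= 0) and np.all(model.H >= 0)
        # rss recomputed from the normalized factors must agree
        resid = V - model.W @ model.H
        assert np.sum(resid * resid) == pytest.approx(model.rss, rel=1e-10)


def test_rss_nonincreasing_in_rank():
    V, _ = _planted_rank2(seed=5)
    rng = np.random.default_rng(6)
    V = V + rng.uniform(0, 0.5, V.shape)
    rss = [nmf_decompose(V, L).rss for L in range(1, 8)]
    norm2 = np.sum(V * V)
    for lo, hi in zip(rss[1:], rss[:-1]):
        assert lo <= hi + 1e-8 * norm2


def test_determinism_bitwise():
    V, _ = _planted_rank2(seed=9)
    a, b = nmf_decompose(V, 3), nmf_decompose(V, 3)
    assert np.array_equal(a.W, b.W) and np.array_equal(a.H, b.H)


def test_invalid_inputs_rejected():
    V = np.ones((4, 5))
    with pytest.raises(ValueError, match="nonnegative"):
        nmf_decompose(-V, 2)
    with pytest.raises(ValueError, match="rank"):
        nmf_decompose(V, 0)
    with pytest.raises(ValueError, match="rank"):
        nmf_decompose(V, 5)
    with pytest.raises(ValueError, match="L_max"):
        rank_scan(V, L_max=2)


def test_rank_scan_finds_planted_rank():
    V, _ = _planted_rank2(n=250)
    scan = rank_scan(V, L_max=6, subsample=200, seed=1)
    assert scan.selected_rank == 2
    assert scan.rss[1] < 1e-6 * np.sum(V * V)
    assert np.all(np.diff(scan.rss) <= 1e-8 * np.sum(V * V))


def test_sklearn_estimator_interface():
    V, _ = _planted_rank2(seed=12)
    est = UnitNormNMF(n_components=2)
    H = est.fit_transform(V.T)  # frames-by-features orientation
    assert H.shape == (V.shape[1], 2)
    assert np.allclose(np.linalg.norm(est.components_, axis=1), 1.0)
    params = est.get_params()
    assert params["n_components"] == 2
    H2 = est.transform(V.T)
    assert np.allclose(H, H2, atol=1e-4 * H.max())


def test_pca_line_blobs_and_reconstruction():
    rng = np.random.default_rng(7)
    # exact 1-D affine line in 3-D
    t = rng.uniform(-5, 5, 100)
    line = np.outer(t, [1.0, 2.0, -1.0]) + [3, 1, 0]
    model = pca_decompose(line, 1)
    assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
    # two well-separated blobs: PC1 splits them with no overlap
    blobs = np.r_[rng.normal(0, 1, (60, 3)), rng.normal(20, 1, (60, 3))]
    m2 = pca_decompose(blobs, 2)
    s = m2.scores[:, 0]
    assert max(s[:60]) < min(s[60:]) or max(s[60:]) < min(s[:60])
    # full-rank reconstruction is exact
    X = rng.uniform(0, 4, (30, 5))
    mf = pca_decompose(X, 5)
    assert np.allclose(mf.scores @ mf.components + mf.mean, X, atol=1e-9)
    # sign convention: largest-magnitude loading entry positive
    for comp in mf.components:
        assert comp[np.argmax(np.abs(comp))] > 0
    with pytest.raises(ValueError):
        pca_decompose(X, 9)


def test_basis_report_thresholds_and_edges():
    n = 10
    W = np.zeros((45, 2))
    W[edge_slot(1, 8, n), 0] = 1.0
    W[edge_slot(1, 7, n), 1] = 0.9
    W[edge_slot(0, 1, n), 1] = 0.44
    W[edge_slot(3, 4, n), 1] = 0.1  # below threshold
    from topofold.decompose import NMFModel
    model = NMFModel(W=W, H=np.ones((2, 3)), rank=2, rss=0.0)
    rep = basis_report(model, n)
    assert rep[0] == [((1, 8), 1.0)]
    assert [e for e, _ in rep[1]] == [(1, 7), (0, 1)]
    assert dominant_offdiagonal_edge(rep[1]) == (1, 7)
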