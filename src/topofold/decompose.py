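"""Dimension reduction of feature matrices by NMF and PCA.

NMF approximates the nonnegative feature matrix V (features x frames)
as W H with W (M x L) and H (L x N) nonnegative, minimizing the
Frobenius residual.  Initialization is the deterministic nonnegative
double SVD (zeros kept) and optimization uses coordinate descent, so
identical inputs give bitwise-identical factors.  After convergence
each basis column w_k is rescaled to unit Euclidean norm with the
inverse factor absorbed into the corresponding H row, leaving W H
unchanged: the bases are dimensionless shape patterns and the
coefficients h carry the Angstrom scale of the features.

The reduced rank is chosen by scanning L = 1..L_max on a random column
subsample and taking the inflection point of the residual-sum-of-squares
curve (the interior rank maximizing the discrete second difference);
the full curve is always returned so the choice can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF, PCA
from sklearn.utils.validation import check_is_fitted

from .features import slot_edge

_NMF_TOL = 1e-4
_NMF_MAX_ITER = 200


@dataclass(frozen=True)
class NMFModel:
    """Nonnegative factorization V ~ W H with unit-norm basis columns."""

    W: np.ndarray      # (M, L), columns unit Euclidean norm, dimensionless
    H: np.ndarray      # (L, N), nonnegative, Angstrom
    rank: int
    rss: float         # squared Frobenius residual ||V - W H||_F^2


@dataclass(frozen=True)
class RankScanResult:
    ranks: np.ndarray
    rss: np.ndarray
    selected_rank: int


@dataclass(frozen=True)
class PCAModel:
    components: np.ndarray          # (L, dim) orthonormal loadings
    scores: np.ndarray              # (N, L)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


class UnitNormNMF(BaseEstimator, TransformerMixin):
    """sklearn-style NMF with deterministic NNDSVD init, coordinate
    descent, and unit-norm basis rescaling.

    Follows the sklearn sample convention: ``fit(X)`` takes X of shape
    (n_frames, M).  ``components_`` has shape (L, M) with unit-norm
    rows; ``transform`` returns the (n_frames, L) coefficients in A.
    """

    def __init__(self, n_components: int = 2, tol: float = _NMF_TOL,
                 max_iter: int = _NMF_MAX_ITER):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_frames, M)")
        if np.any(X < 0):
            raise ValueError("NMF input must be elementwise nonnegative")
        if not 1 <= self.n_components <= min(X.shape):
            raise ValueError(
                f"rank must lie in [1, min(M, N)] = [1, {min(X.shape)}]")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self._nmf = NMF(n_components=self.n_components, init="nndsvd",
                        solver="cd", tol=self.tol, max_iter=self.max_iter,
                        random_state=0)
        import warnings
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum number of "
                                    "iterations.*")
            coef = self._nmf.fit_transform(X)
        norms = np.linalg.norm(self._nmf.components_, axis=1)
        norms[norms == 0] = 1.0
        self.scale_ = norms
        self.components_ = self._nmf.components_ / norms[:, None]
        self.coefficients_ = coef * norms[None, :]
        resid = X - self.coefficients_ @ self.components_
        self.reconstruction_rss_ = float(np.sum(resid * resid))
        self.n_iter_ = self._nmf.n_iter_
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        import warnings
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum number of "
                                    "iterations.*")
            return self._nmf.transform(np.asarray(X, float)) * self.scale_

    def fit_transform(self, X, y=None, **kwargs):
        self.fit(X)
        return self.coefficients_


def nmf_decompose(V: np.ndarray, rank: int, tol: float = _NMF_TOL,
                  max_iter: int = _NMF_MAX_ITER) -> NMFModel:
    """Factorize a (M, N) feature matrix with columns as frames.

    Thin wrapper over :class:`UnitNormNMF` in the features-by-frames
    orientation: returns W (M, L) with unit-norm columns and H (L, N).
    """
    V = np.asarray(V, dtype=float)
    est = UnitNormNMF(n_components=rank, tol=tol, max_iter=max_iter)
    est.fit(V.T)
    return NMFModel(W=est.components_.T, H=est.coefficients_.T,
                    rank=rank, rss=est.reconstruction_rss_)


def rank_scan(V: np.ndarray, L_max: int = 10, subsample: int = 1000,
              seed: int | None = 0) -> RankScanResult:
    """Scan NMF ranks 1..L_max on a random column subsample and select
    the RSS-inflection rank.

    The inflection is the interior rank maximizing the discrete second
    difference rss[L-1] - 2 rss[L] + rss[L+1]; a random data set gives a
    linear RSS decline (zero second difference), so a pronounced bend
    marks the intrinsic rank.
    """
    if L_max < 3:
        raise ValueError("L_max must be at least 3 for an inflection")
    V = np.asarray(V, dtype=float)
    n_cols = V.shape[1]
    if subsample < n_cols:
        rng = np.random.default_rng(seed)
        cols = rng.choice(n_cols, size=subsample, replace=False)
        V = V[:, np.sort(cols)]
    ranks = np.arange(1, L_max + 1)
    rss = np.array([nmf_decompose(V, int(L)).rss for L in ranks])
    second_diff = rss[:-2] - 2 * rss[1:-1] + rss[2:]
    selected = int(ranks[1 + int(np.argmax(second_diff))])
    return RankScanResult(ranks=ranks, rss=rss, selected_rank=selected)


def pca_decompose(X: np.ndarray, n_components: int) -> PCAModel:
    """PCA of a (N, dim) matrix of frame features.

    Columns are mean-centered; scores and loadings come from a full
    SVD.  Each component's sign is fixed so its largest-magnitude
    loading entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if not 1 <= n_components <= min(X.shape):
        raise ValueError("n_components out of range")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    return PCAModel(components=comps, scores=scores,
                    explained_variance=pca.explained_variance_.copy(),
                    explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                    mean=pca.mean_.copy())


def basis_report(model: NMFModel, n: int, threshold: float = 0.2
                 ) -> list[list[tuple[tuple[int, int], float]]]:
    """Per-basis list of (edge pair, weight) with weight > threshold,
    sorted by descending weight.

    Reading a basis as the edges it loads on names the state it
    captures, e.g. by its dominant non-adjacent (non-backbone) edge.
    """
    M = n * (n - 1) // 2
    if model.W.shape[0] != M:
        raise ValueError(f"W has {model.W.shape[0]} rows; expected {M}")
    report = []
    for k in range(model.rank):
        idx = np.where(model.W[:, k] > threshold)[0]
        entries = [(slot_edge(int(s), n), float(model.W[s, k])) for s in idx]
        entries.sort(key=lambda t: -t[1])
        report.append(entries)
    return report


def dominant_offdiagonal_edge(entries, separation: int = 2
                              ) -> tuple[int, int] | None:
    """Top-weighted edge (i, j) with j - i >= separation from one
    basis's report entries; None if absent."""
    for (i, j), _w in entries:
        if j - i >= separation:
            return (i, j)
    return None
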