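"""Time-series-of-graphs (TSG) features.

Each window of a multichannel recording induces a weighted graph on the
channels: the Pearson correlation matrix A(k).  A second, "graph of graphs"
similarity matrix B is built from min-max-normalized pairwise Frobenius
distances between the A(k), and every window is represented by a row of the
adjacency spectral embedding of B,

    Z_hat = U_d diag(sigma_1..sigma_d)^(1/2),

the truncated singular vectors of B scaled by the square root of their
singular values.  Under a random dot product graph model these rows are
consistent estimates of latent positions; here they serve as per-window
feature vectors.  An out-of-sample map places a previously unseen window
into the same space without recomputing the decomposition: with A its
correlation graph and s'(., .) the normalized similarity to each training
graph,

    T(X) = sum_k s'(A, A(k)) [(Z_hat^T Z_hat)^(-1) Z_hat^T]_k .
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dimension import select_dimension

__all__ = [
    "correlation_graph", "correlation_graphs", "build_similarity",
    "SimilarityModel", "TSGEmbedding", "embed", "TSGTransformer",
    "out_of_sample",
]


def correlation_graph(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of one ``(n_channels, w)`` window.

    A zero-variance channel gets zero correlation with every other channel
    (diagonal stays 1) and triggers a warning; the window is kept so the
    graph stack stays aligned with the window labels.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] < 3:
        raise ValueError("window must be (n_channels, w) with w >= 3")
    centered = window - window.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    degenerate = sd <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance channel(s); their "
            "correlations are set to 0", RuntimeWarning, stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    normed = centered / safe_sd[:, None]
    A = normed @ normed.T / window.shape[1]
    A[degenerate, :] = 0.0
    A[:, degenerate] = 0.0
    np.fill_diagonal(A, 1.0)
    np.clip(A, -1.0, 1.0, out=A)
    return (A + A.T) / 2.0


def correlation_graphs(windows: np.ndarray) -> np.ndarray:
    """Stack of correlation graphs, ``(n_windows, n_c, n_c)``."""
    return np.stack([correlation_graph(w) for w in np.asarray(windows, float)])


@dataclass
class SimilarityModel:
    """Pairwise graph similarities for one training window set.

    ``B = 1 - (D - d_min) / (d_max - d_min)`` elementwise, where D holds
    pairwise Frobenius distances between correlation graphs.  With the
    default convention the min runs over all index pairs including k = k',
    so ``d_min = 0``, B has unit diagonal and entries in [0, 1].
    """

    B: np.ndarray
    D: np.ndarray
    d_min: float
    d_max: float


def _pairwise_frobenius(graphs: np.ndarray) -> np.ndarray:
    flat = graphs.reshape(len(graphs), -1)
    sq = (flat ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (flat @ flat.T)
    np.maximum(d2, 0.0, out=d2)
    D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def build_similarity(graphs: np.ndarray, distinct_pairs_min: bool = False) -> SimilarityModel:
    """Graph-of-graphs similarity matrix from a stack of correlation graphs.

    Parameters
    ----------
    graphs : ndarray (n_windows, n_c, n_c)
    distinct_pairs_min : bool, default False
        If True, the normalizing minimum is taken over distinct pairs
        (k != k') instead of all pairs.  The default (all pairs) makes
        d_min = 0 and keeps B within [0, 1] with unit diagonal.
    """
    graphs = np.asarray(graphs, dtype=float)
    if graphs.ndim != 3 or graphs.shape[0] < 2:
        raise ValueError("need a stack of at least 2 graphs")
    D = _pairwise_frobenius(graphs)
    d_max = float(D.max())
    if d_max <= 0:
        raise ValueError(
            "degenerate graph stack: all graphs identical (d_max == d_min)"
        )
    if distinct_pairs_min:
        off = D[~np.eye(len(D), dtype=bool)]
        d_min = float(off.min())
    else:
        d_min = 0.0
    if d_max - d_min <= 0:
        raise ValueError("degenerate graph stack: d_max == d_min")
    B = 1.0 - (D - d_min) / (d_max - d_min)
    return SimilarityModel(B=B, D=D, d_min=d_min, d_max=d_max)


def _signed_svd(B: np.ndarray):
    """SVD of symmetric B with a deterministic sign convention.

    Each left singular vector is flipped so its largest-magnitude entry is
    positive (ties broken by lowest index); the flip is mirrored in V so
    U S V^T still equals B.
    """
    U, s, Vt = np.linalg.svd(B, hermitian=True)
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip, s, Vt * flip[:, None]


@dataclass
class TSGEmbedding:
    """Adjacency spectral embedding of a similarity matrix B."""

    Z_hat: np.ndarray
    singular_values: np.ndarray
    d: int


def embed(similarity: SimilarityModel, d: int | None = None,
          n_elbows: int = 2) -> TSGEmbedding:
    """Scaled-singular-vector embedding of ``similarity.B``.

    If ``d`` is not given it is chosen at the ``n_elbows``-th scree elbow of
    the singular values of B.
    """
    B = similarity.B
    n_w = B.shape[0]
    if n_w < 3:
        raise ValueError("need at least 3 windows to embed")
    U, s, _ = _signed_svd(B)
    if d is None:
        d = select_dimension(s, n_elbows=n_elbows)
    d = int(d)
    if not 1 <= d <= n_w:
        raise ValueError(f"embedding dimension {d} out of range [1, {n_w}]")
    Z = U[:, :d] * np.sqrt(s[:d])
    return TSGEmbedding(Z_hat=Z, singular_values=s[:d].copy(), d=d)


class TSGTransformer(TransformerMixin, BaseEstimator):
    """TSG feature map with out-of-sample extension.

    ``fit`` is transductive: it embeds the training windows jointly and
    stores their representations in ``embedding_``; ``fit_transform``
    returns those rows directly.  ``transform`` maps unseen windows through
    the out-of-sample extension using the training normalizers.

    Parameters
    ----------
    n_elbows : int, default 2
        Scree elbow used for automatic dimension selection.
    n_components : int, optional
        Fixed embedding dimension (overrides elbow selection).
    clip_oos : bool, default True
        Clip out-of-sample similarities to [0, 1] (an unseen window can be
        farther from a training graph than any training pair).
    distinct_pairs_min : bool, default False
        Normalizing-minimum convention, see :func:`build_similarity`.
    precomputed : bool, default False
        If True, ``X`` is a stack of correlation graphs
        ``(n_windows, n_c, n_c)`` instead of raw windows.

    Attributes
    ----------
    graphs_ : training correlation graphs.
    similarity_ : fitted :class:`SimilarityModel` (B, D, normalizers).
    embedding_ : (n_windows, d) training representations Z_hat.
    singular_values_ : retained singular values of B.
    n_components_ : selected dimension d.
    projector_ : (d, n_windows) matrix ``(Z^T Z)^+ Z^T`` of the OOS map.
    """

    def __init__(self, n_elbows: int = 2, n_components: int | None = None,
                 clip_oos: bool = True, distinct_pairs_min: bool = False,
                 precomputed: bool = False):
        self.n_elbows = n_elbows
        self.n_components = n_components
        self.clip_oos = clip_oos
        self.distinct_pairs_min = distinct_pairs_min
        self.precomputed = precomputed

    def _graphs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.precomputed:
            if X.ndim != 3 or X.shape[1] != X.shape[2]:
                raise ValueError("precomputed graphs must be (n_w, n_c, n_c)")
            return X
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, w)")
        return correlation_graphs(X)

    def fit(self, X, y=None):
        graphs = self._graphs(X)
        self.graphs_ = graphs
        self.similarity_ = build_similarity(
            graphs, distinct_pairs_min=self.distinct_pairs_min
        )
        emb = embed(self.similarity_, d=self.n_components, n_elbows=self.n_elbows)
        self.embedding_ = emb.Z_hat
        self.singular_values_ = emb.singular_values
        self.n_components_ = emb.d
        # (Z^T Z)^(-1) Z^T via pseudo-inverse, cutoff 1e-12, tolerating
        # near-zero retained singular values.
        self.projector_ = np.linalg.pinv(self.embedding_, rcond=1e-12)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def _similarity_vectors(self, graphs: np.ndarray) -> np.ndarray:
        train = self.graphs_.reshape(len(self.graphs_), -1)
        test = graphs.reshape(len(graphs), -1)
        sq_tr = (train ** 2).sum(axis=1)
        sq_te = (test ** 2).sum(axis=1)
        d2 = sq_te[:, None] + sq_tr[None, :] - 2.0 * (test @ train.T)
        np.maximum(d2, 0.0, out=d2)
        dist = np.sqrt(d2)
        sim = self.similarity_
        s = 1.0 - (dist - sim.d_min) / (sim.d_max - sim.d_min)
        if self.clip_oos:
            np.clip(s, 0.0, 1.0, out=s)
        return s

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "embedding_")
        graphs = self._graphs(X)
        if graphs.shape[1] != self.graphs_.shape[1]:
            raise ValueError(
                f"channel-count mismatch: fitted with {self.graphs_.shape[1]}, "
                f"got {graphs.shape[1]}"
            )
        return self._similarity_vectors(graphs) @ self.projector_.T


def out_of_sample(x_window: np.ndarray, mapper: TSGTransformer) -> np.ndarray:
    """Out-of-sample embedding of a single ``(n_channels, w)`` window."""
    check_is_fitted(mapper, "embedding_")
    window = np.asarray(x_window, dtype=float)
    if window.ndim != 2:
        raise ValueError("x_window must be a single (n_channels, w) window")
    X = correlation_graph(window) if mapper.precomputed else window
    return mapper.transform(X[None])[0]
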