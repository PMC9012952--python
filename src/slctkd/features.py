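"""Core-tensor feature extraction and subject clustering.

After a Tucker-2 fit, the core tensor ``G (N x N x K)`` can be re-derived
from the data through pseudo-inverses of the shared factors,

    G_k = pinv(S) (X_k - E_k) pinv(B')          (per-subject slice)

and read out along its three fibre directions:

* mode-3 fibres ``G(i, j, :)`` are subject-specific intensities of the
  spatial component i paired with temporal component j;
* mode-1 fibres at a fixed temporal component j form the spatial feature
  matrix ``G_S (N x K)``;
* mode-2 fibres at a fixed spatial component i form the temporal feature
  matrix ``G_B (N x K)``.

The three read-outs are algebraically three views of the same core slice
entries, and the implementation keeps them numerically identical.  The
feature matrices are used to cluster subjects (columns) with k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans

#: relative singular-value cutoff for the factor pseudo-inverses
PINV_RCOND = 1e-10


@dataclass
class FeatureSet:
    """Subject intensities and spatial/temporal feature matrices."""

    intensities: np.ndarray        # length K
    spatial: np.ndarray            # N x K
    temporal: np.ndarray           # N x K
    component_index_i: int
    component_index_j: int


@dataclass
class ClusterResult:
    """k-means subject partition; labels are 1-based, cluster 1 holds subject 1."""

    labels: np.ndarray
    n_clusters: int
    feature_source: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.n_clusters + 1)):
            raise ValueError("labels must cover 1..n_clusters with no empty cluster")


def _pinv_checked(M: np.ndarray, name: str) -> np.ndarray:
    s = linalg.svdvals(M)
    if s.size and s[0] > 0:
        cond = s[0] / s[-1] if s[-1] > 0 else np.inf
        if s[-1] <= PINV_RCOND * s[0]:
            warnings.warn(
                f"factor {name} is rank deficient (condition number {cond:.3e}); "
                "proceeding with a truncated pseudo-inverse",
                RuntimeWarning,
                stacklevel=3,
            )
    return np.linalg.pinv(M, rcond=PINV_RCOND)


def core_from_data(
    X: np.ndarray, E: np.ndarray, S: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Re-derive the core from data: ``G_k = pinv(S) (X_k - E_k) pinv(B')``."""
    X = np.asarray(X, dtype=float)
    E = np.asarray(E, dtype=float)
    S_pinv = _pinv_checked(S, "S")          # N x V
    Bt_pinv = _pinv_checked(B.T, "B")       # T x N
    K = X.shape[2]
    N = S.shape[1]
    G = np.empty((N, N, K))
    for k in range(K):
        G[:, :, k] = S_pinv @ (X[:, :, k] - E[:, :, k]) @ Bt_pinv
    return G


def subject_intensities(
    G: np.ndarray, i: int, j: int, normalize: bool = False
) -> np.ndarray:
    """Mode-3 fibre ``[G_1(i,j), ..., G_K(i,j)]`` (0-based component indices).

    With ``normalize=True`` the vector is scaled to [-1, 1] by its max-abs.
    """
    G = np.asarray(G)
    N = G.shape[0]
    if not (0 <= i < N and 0 <= j < N):
        raise IndexError(f"component indices ({i}, {j}) out of range for N={N}")
    c = np.array(G[i, j, :], dtype=float)
    if normalize:
        m = np.max(np.abs(c))
        if m > 0:
            c = c / m
    return c


def spatial_features(
    X: np.ndarray, E: np.ndarray, S: np.ndarray, B: np.ndarray, j: int
) -> np.ndarray:
    """Spatial feature matrix ``G_S (N x K)`` at temporal component ``j``.

    Row i, column k is ``s~_i . Z_k(:, j)`` with ``Z_k = (X_k - E_k) pinv(B')``
    — identically the (i, j) column read-out of :func:`core_from_data`.
    """
    B = np.asarray(B)
    if not (0 <= j < B.shape[1]):
        raise IndexError(f"temporal component index {j} out of range")
    return core_from_data(X, E, S, B)[:, j, :]


def temporal_features(
    X: np.ndarray, E: np.ndarray, S: np.ndarray, B: np.ndarray, i: int
) -> np.ndarray:
    """Temporal feature matrix ``G_B (N x K)`` at spatial component ``i``.

    Row j, column k is ``M_k(i, :) . b~_j`` with ``M_k = pinv(S)(X_k - E_k)``
    — identically the (i, j) row read-out of :func:`core_from_data`.
    """
    S = np.asarray(S)
    if not (0 <= i < S.shape[1]):
        raise IndexError(f"spatial component index {i} out of range")
    return core_from_data(X, E, S, B)[i, :, :]


def extract_features(
    X: np.ndarray,
    E: np.ndarray,
    S: np.ndarray,
    B: np.ndarray,
    i: int,
    j: int | None = None,
    normalize_intensities: bool = False,
) -> FeatureSet:
    """Intensities plus both feature matrices for a component pair (i, j).

    By default j = i: the intensity of component n is read at the matched
    spatial/temporal diagonal entry of the core.
    """
    j = i if j is None else j
    G = core_from_data(X, E, S, B)
    return FeatureSet(
        intensities=subject_intensities(G, i, j, normalize=normalize_intensities),
        spatial=G[:, j, :],
        temporal=G[i, :, :],
        component_index_i=i,
        component_index_j=j,
    )


def cluster_subjects(
    features: np.ndarray,
    n_clusters: int,
    seed: int | None = 0,
    feature_source: str = "spatial",
    normalize: str = "subject",
) -> ClusterResult:
    """k-means over subjects (columns of an N x K feature matrix).

    Runs 50 restarts of Lloyd's algorithm with the squared-Euclidean
    objective; deterministic given ``seed``.  With ``normalize="subject"``
    (default) each subject's feature column is scaled to unit norm first,
    so the partition reflects the *pattern* of component loadings rather
    than per-subject global amplitude (which varies with overall signal
    scale); ``normalize="none"`` clusters the raw columns.  Labels are
    canonicalised by order of first appearance so cluster 1 always contains
    subject 1.
    """
    features = np.asarray(features, dtype=float)
    K = features.shape[1]
    if n_clusters > K:
        raise ValueError(f"n_clusters={n_clusters} exceeds number of subjects {K}")
    if normalize == "subject":
        norms = np.linalg.norm(features, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        features = features / norms
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    km = KMeans(n_clusters=n_clusters, n_init=50, random_state=seed)
    raw = km.fit_predict(features.T)
    # canonical relabel: first-seen cluster -> 1, next new -> 2, ...
    mapping: dict[int, int] = {}
    labels = np.empty(K, dtype=int)
    for idx, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[idx] = mapping[lab]
    return ClusterResult(labels=labels, n_clusters=n_clusters, feature_source=feature_source)
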