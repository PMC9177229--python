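"""Sample-graph construction for the margin and locality penalties.

Two families of N x N matrices are built from the training set, where N is
the number of samples (samples index the *columns* of the feature matrix X
and of the coefficient matrix A):

* class-margin matrices ``Qw`` (intra-class similarity), ``Qb`` (inter-class
  similarity) and the margin matrix ``S`` combining them, such that
  ``tr(A @ S_sym @ A.T)`` equals the averaged within-class-minus-between-class
  sum of squared code distances;
* a k-nearest-neighbour heat-kernel affinity ``P`` and its graph Laplacian
  ``L = diag(P @ 1) - P``, so that ``tr(A @ L @ A.T)`` penalises codes that
  differ between feature-space neighbours.

Conventions (documented because the field's literature is inconsistent):
``L`` is the positive-semidefinite degree-minus-affinity Laplacian; the
quadratic forms act on the sample (column) index of ``A``; the asymmetric
margin matrix is symmetrised as ``(S + S.T) / 2``, which leaves the scalar
penalty unchanged but makes its gradient exact; self-affinities ``p_ii`` are
excluded; ``sum_ij p_ij ||a_i - a_j||^2 == 2 * tr(A @ L @ A.T)``, and the
factor of two is absorbed into the locality trade-off parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "LabelVector",
    "MarginGraph",
    "LocalityGraph",
    "build_intra_similarity",
    "build_inter_similarity",
    "build_margin_matrix",
    "build_locality_graph",
]


@dataclass(frozen=True)
class LabelVector:
    """Integer class ids per sample, with per-class bookkeeping.

    ``class_ids`` is the ordered distinct classes (first-appearance order of
    ``np.unique``, i.e. sorted); ``class_sizes[k]`` is the number of samples
    in ``class_ids[k]``.
    """

    labels: np.ndarray
    class_ids: np.ndarray = field(init=False)
    class_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        object.__setattr__(self, "labels", labels)
        ids, sizes = np.unique(labels, return_counts=True)
        object.__setattr__(self, "class_ids", ids)
        object.__setattr__(self, "class_sizes", sizes)

    @property
    def n_samples(self) -> int:
        return int(self.labels.size)

    @property
    def n_classes(self) -> int:
        return int(self.class_ids.size)

    def indicator(self) -> np.ndarray:
        """One-hot K x N class-indicator matrix Y aligned with class_ids."""
        Y = (self.labels[None, :] == self.class_ids[:, None]).astype(float)
        return Y


@dataclass(frozen=True)
class MarginGraph:
    """Margin matrices S (as derived) and S_sym = (S + S.T)/2."""

    Qw: np.ndarray
    Qb: np.ndarray
    Qb_diag: np.ndarray
    S: np.ndarray
    S_sym: np.ndarray


@dataclass(frozen=True)
class LocalityGraph:
    """kNN heat-kernel affinity P and PSD Laplacian L = diag(P @ 1) - P."""

    P: np.ndarray
    L: np.ndarray
    k_neighbors: int
    sigma: float


def build_intra_similarity(labels: LabelVector | np.ndarray) -> np.ndarray:
    """Intra-class similarity Qw: q_ij = 1/N_k when i, j share class k."""
    lv = labels if isinstance(labels, LabelVector) else LabelVector(labels)
    same = lv.labels[:, None] == lv.labels[None, :]
    sizes = np.zeros(lv.n_samples)
    for cid, nk in zip(lv.class_ids, lv.class_sizes):
        sizes[lv.labels == cid] = nk
    return np.where(same, 1.0 / sizes[:, None], 0.0)


def build_inter_similarity(labels: LabelVector | np.ndarray) -> np.ndarray:
    """Inter-class similarity Qb: q_ij = 1/(N - N_k) when i is in class k
    and j is not.  Zero matrix for a single class (the complement is empty).

    Note Qb is asymmetric when classes are unbalanced: the row scale depends
    on the *row* sample's class size.
    """
    lv = labels if isinstance(labels, LabelVector) else LabelVector(labels)
    N = lv.n_samples
    if lv.n_classes == 1:
        return np.zeros((N, N))
    diff = lv.labels[:, None] != lv.labels[None, :]
    sizes = np.zeros(N)
    for cid, nk in zip(lv.class_ids, lv.class_sizes):
        sizes[lv.labels == cid] = nk
    return np.where(diff, 1.0 / (N - sizes[:, None]), 0.0)


def build_margin_matrix(
    Qw: np.ndarray, Qb: np.ndarray, n_samples: int | None = None
) -> MarginGraph:
    """Combine Qw and Qb into the margin matrix S.

    S = (1/N) (I - 2 Qw - Qb_diag + 2 Qb), where Qb_diag is the diagonal
    matrix of column sums of Qb.  ``tr(A @ S_sym @ A.T)`` then equals the
    mean over samples of (within-class minus between-class) average squared
    code distance.
    """
    Qw = np.asarray(Qw, dtype=float)
    Qb = np.asarray(Qb, dtype=float)
    if Qw.shape != Qb.shape or Qw.ndim != 2 or Qw.shape[0] != Qw.shape[1]:
        raise ValueError(f"Qw {Qw.shape} and Qb {Qb.shape} must be equal square shapes")
    N = Qw.shape[0]
    if n_samples is not None and n_samples != N:
        raise ValueError(f"n_samples={n_samples} does not match matrix size {N}")
    Qb_diag = np.diag(Qb.sum(axis=0))
    S = (np.eye(N) - 2.0 * Qw - Qb_diag + 2.0 * Qb) / N
    S_sym = (S + S.T) / 2.0
    return MarginGraph(Qw=Qw, Qb=Qb, Qb_diag=Qb_diag, S=S, S_sym=S_sym)


def build_margin_graph(labels: LabelVector | np.ndarray) -> MarginGraph:
    """Convenience wrapper: labels -> MarginGraph."""
    Qw = build_intra_similarity(labels)
    Qb = build_inter_similarity(labels)
    return build_margin_matrix(Qw, Qb)


def _knn_edges(X: np.ndarray, k_neighbors: int) -> np.ndarray:
    """Boolean N x N matrix of the symmetric (OR-rule) kNN relation,
    self-loops excluded, distance ties broken by ascending sample index."""
    N = X.shape[1]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X.T)
    dist, idx = nn.kneighbors(X.T)
    directed = np.zeros((N, N), dtype=bool)
    for j in range(N):
        # drop self (distance 0 to itself is always included in the k+1);
        # with duplicated points "self" may appear at any position, so
        # remove index j explicitly and keep the first k others.
        others = [i for i in idx[j] if i != j][:k_neighbors]
        directed[j, others] = True
    return directed | directed.T


def build_locality_graph(
    X: np.ndarray,
    k_neighbors: int = 5,
    sigma: float | str = "median",
) -> LocalityGraph:
    """Heat-kernel kNN affinity and its graph Laplacian.

    Parameters
    ----------
    X : (d, N) array
        Feature matrix, one sample per column.
    k_neighbors : int
        Neighbourhood size k of the kNN relation (OR-symmetrised).
    sigma : float or "median"
        Heat-kernel bandwidth, in feature-space distance units.  The default
        "median" uses the median Euclidean distance over the graph's edges
        (the median heuristic), which is scale-free.

    Returns
    -------
    LocalityGraph with P symmetric, entries in [0, 1], zero diagonal, and
    L = diag(P @ 1) - P (symmetric PSD, zero row sums).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (features x samples) array")
    N = X.shape[1]
    if N < 2:
        raise ValueError("need at least 2 samples to build a locality graph")
    if not 1 <= k_neighbors <= N - 1:
        raise ValueError(f"k_neighbors must be in [1, {N - 1}], got {k_neighbors}")

    edges = _knn_edges(X, k_neighbors)
    sq = np.sum(X * X, axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X.T @ X)
    np.maximum(d2, 0.0, out=d2)

    if isinstance(sigma, str):
        if sigma != "median":
            raise ValueError(f"unknown sigma rule {sigma!r}")
        edge_d = np.sqrt(d2[edges])
        med = float(np.median(edge_d))
        sigma_val = med if med > 0 else 1.0  # all-coincident fallback
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError(f"sigma must be positive, got {sigma_val}")

    P = np.where(edges, np.exp(-d2 / (2.0 * sigma_val**2)), 0.0)
    np.fill_diagonal(P, 0.0)
    L = np.diag(P.sum(axis=1)) - P
    return LocalityGraph(P=P, L=L, k_neighbors=int(k_neighbors), sigma=sigma_val)
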