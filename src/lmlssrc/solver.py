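"""Alternating closed-form block updates for the LMLS-SRC objective.

The objective jointly learned over dictionary D (d x m, unit-ball atoms),
codes A (m x N, one column per sample) and linear classifier W (K x m) is

    F(D, A, W) = ||X - D A||_F^2
               + lambda1 * ||A||_{2,1}
               + lambda2 * tr(A S_sym A.T)
               + lambda3 * tr(A L A.T)
               + lambda4 * ||W A - Y||_F^2
               + lambda5 * ||W||_F^2,      s.t. ||d_i||_2^2 <= 1  for all i,

with S_sym the symmetrised class-margin matrix and L the kNN graph
Laplacian (see :mod:`lmlssrc.graphs`).  The row-sparsity penalty is the
plain (un-squared) l2,1 norm, handled by iteratively reweighted least
squares: with Omega = diag(1 / (2 ||A_i||_2)) fixed, the penalty is
majorised by lambda1 * tr(A.T Omega A) + const, so each A update cannot
increase F.

Block updates (all exact minimisers of their subproblem):

* A: stationarity gives the Sylvester equation  M A + A G = R  with
  M = D.T D + lambda1 Omega + lambda4 W.T W  (m x m),
  G = lambda2 S_sym + lambda3 L  (N x N),
  R = D.T X + lambda4 W.T Y,
  solved through symmetric eigendecompositions of M and G.
* D: block-coordinate descent over atoms with Euclidean projection onto the
  unit ball; its fixed point satisfies the Lagrange-dual (KKT) form
  D = X A.T (A A.T + Theta)^{-1} with multipliers Theta on active atoms.
* W: ridge regression  W = lambda4 Y A.T (lambda4 A A.T + lambda5 I)^{-1}.

The training loop alternates D -> A -> W (refreshing Omega just before each
A update) until the relative objective change falls below ``delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "Hyperparameters",
    "FitTrace",
    "NumericalError",
    "update_row_weights",
    "update_coefficients",
    "update_dictionary",
    "update_classifier",
    "evaluate_objective",
    "fit_lmls",
]


class NumericalError(RuntimeError):
    """A linear system in a block update is singular or indefinite."""


@dataclass(frozen=True)
class Hyperparameters:
    """Trade-off parameters and loop controls.

    lambda1 : weight of the l2,1 row-sparsity penalty on A.
    lambda2 : weight of the class-margin term tr(A S_sym A.T).
    lambda3 : weight of the locality term tr(A L A.T); note
        sum_ij p_ij ||a_i - a_j||^2 = 2 tr(A L A.T), the factor 2 is
        absorbed here.
    lambda4 : weight of the classifier fit ||W A - Y||_F^2.
    lambda5 : ridge on W.
    delta : relative-objective convergence tolerance.
    maxiter : maximum number of outer iterations.
    eps_row : floor on row norms inside the IRLS weights (keeps Omega
        finite on all-zero rows).
    seed : RNG seed governing initialisation.
    """

    lambda1: float = 1.0
    lambda2: float = 0.1
    lambda3: float = 0.1
    lambda4: float = 1.0
    lambda5: float = 0.1
    delta: float = 1e-4
    maxiter: int = 50
    eps_row: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.maxiter < 1:
            raise ValueError("maxiter must be >= 1")
        if self.eps_row <= 0:
            raise ValueError("eps_row must be positive")

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3": self.lambda3,
            "lambda4": self.lambda4,
            "lambda5": self.lambda5,
            "delta": self.delta,
            "maxiter": self.maxiter,
            "eps_row": self.eps_row,
            "seed": self.seed,
        }


@dataclass
class FitTrace:
    """Per-iteration objective values and convergence status."""

    objective_values: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.objective_values)


def update_row_weights(A: np.ndarray, eps_row: float = 1e-8) -> np.ndarray:
    """IRLS weights for the l2,1 penalty: Omega_ii = 1/(2 max(||A_i||, eps))."""
    row_norms = np.linalg.norm(A, axis=1)
    return np.diag(1.0 / (2.0 * np.maximum(row_norms, eps_row)))


def update_coefficients(
    X: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    Y: np.ndarray,
    Omega: np.ndarray,
    S_sym: np.ndarray,
    L: np.ndarray,
    hp: Hyperparameters,
    G_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Exact minimiser of the Omega-fixed coefficient subproblem.

    Solves the Sylvester-type stationarity system M A + A G = R.  ``G_eig``
    may carry a precomputed eigendecomposition ``(eigvals, eigvecs)`` of
    G = lambda2 S_sym + lambda3 L (S and L are fixed across the fit, so one
    decomposition serves every iteration).

    Raises
    ------
    NumericalError
        If M + g_j I is singular or indefinite for some eigenvalue g_j of G
        (the subproblem would be unbounded below); raising lambda1 fixes it.
    """
    M = D.T @ D + hp.lambda1 * Omega + hp.lambda4 * (W.T @ W)
    R = D.T @ X + hp.lambda4 * (W.T @ Y)
    if G_eig is None:
        G = hp.lambda2 * S_sym + hp.lambda3 * L
        g, U = scipy.linalg.eigh(G)
    else:
        g, U = G_eig
    mu, V = scipy.linalg.eigh((M + M.T) / 2.0)
    denom = mu[:, None] + g[None, :]
    if np.min(denom) <= 1e-12 * max(1.0, float(np.max(np.abs(denom)))):
        raise NumericalError(
            "coefficient update: the system matrix M + g_j I is singular or "
            "indefinite (min eigenvalue sum "
            f"{np.min(denom):.3e}); increase lambda1 (or lambda4/lambda5) to "
            "regularize"
        )
    B = (V.T @ R @ U) / denom
    return V @ B @ U.T


def update_dictionary(
    X: np.ndarray,
    D: np.ndarray,
    A: np.ndarray,
    n_sweeps: int = 3,
    tol: float | None = None,
) -> np.ndarray:
    """Minimise ||X - D A||_F^2 subject to ||d_i||^2 <= 1 per atom.

    Block-coordinate descent over atoms: each atom moves to its
    unconstrained optimum given the others and is projected onto the unit
    ball.  Monotone in the reconstruction objective; the fixed point
    satisfies the KKT form D = X A.T (A A.T + Theta)^{-1}.  Atoms whose
    coefficient row is all-zero are left unchanged (their contribution to
    the objective is nil).  When ``tol`` is given, sweeping stops early
    once no atom moves by more than ``tol`` (otherwise exactly
    ``n_sweeps`` sweeps run — a few suffice inside the outer loop, where
    exact subproblem solutions are not required for monotone descent).
    """
    D = np.array(D, dtype=float, copy=True)
    AAt = A @ A.T
    XAt = X @ A.T
    row_sq = np.diag(AAt)
    m = D.shape[1]
    for _ in range(n_sweeps):
        max_move = 0.0
        # residual contribution of atom i is tracked implicitly:
        # XAt[:, i] - D @ AAt[:, i] + d_i * row_sq[i]
        for i in range(m):
            if row_sq[i] <= 0.0:
                continue
            v = XAt[:, i] - D @ AAt[:, i] + D[:, i] * row_sq[i]
            v /= row_sq[i]
            nv = np.linalg.norm(v)
            new = v / nv if nv > 1.0 else v
            if tol is not None:
                max_move = max(max_move, float(np.max(np.abs(new - D[:, i]))))
            D[:, i] = new
        if tol is not None and max_move <= tol:
            break
    return D


def update_classifier(
    A: np.ndarray, Y: np.ndarray, lambda4: float, lambda5: float
) -> np.ndarray:
    """Ridge classifier update W = lambda4 Y A.T (lambda4 A A.T + lambda5 I)^{-1}."""
    if lambda4 <= 0 and lambda5 <= 0:
        raise ValueError("classifier update needs lambda4 > 0 or lambda5 > 0")
    m = A.shape[0]
    Mw = lambda4 * (A @ A.T) + lambda5 * np.eye(m)
    return np.linalg.solve(Mw, lambda4 * (A @ Y.T)).T


def l21_norm(A: np.ndarray) -> float:
    """Sum of row-wise Euclidean norms."""
    return float(np.sum(np.linalg.norm(A, axis=1)))


def evaluate_objective(
    X: np.ndarray,
    D: np.ndarray,
    A: np.ndarray,
    W: np.ndarray,
    Y: np.ndarray,
    S_sym: np.ndarray,
    L: np.ndarray,
    hp: Hyperparameters,
) -> tuple[float, dict[str, float]]:
    """Objective value and per-term breakdown.

    Returns ``(F, terms)`` where ``terms`` holds the raw (unweighted)
    values: reconstruction ||X-DA||_F^2, the l2,1 norm of A, the margin and
    locality traces, the classifier misfit and the W ridge.
    """
    if X.shape != (D.shape[0], A.shape[1]) or W.shape != (Y.shape[0], D.shape[1]):
        raise ValueError(
            f"inconsistent shapes: X{X.shape}, D{D.shape}, A{A.shape}, "
            f"W{W.shape}, Y{Y.shape}"
        )
    terms = {
        "reconstruction": float(np.linalg.norm(X - D @ A) ** 2),
        "l21": l21_norm(A),
        "margin": float(np.trace(A @ S_sym @ A.T)),
        "locality": float(np.einsum("ij,ij->", A @ L, A)),
        "classifier": float(np.linalg.norm(W @ A - Y) ** 2),
        "w_ridge": float(np.linalg.norm(W) ** 2),
    }
    F = (
        terms["reconstruction"]
        + hp.lambda1 * terms["l21"]
        + hp.lambda2 * terms["margin"]
        + hp.lambda3 * terms["locality"]
        + hp.lambda4 * terms["classifier"]
        + hp.lambda5 * terms["w_ridge"]
    )
    return F, terms


def _init_blocks(
    X: np.ndarray,
    labels: np.ndarray,
    n_atoms: int,
    n_classes: int,
    hp: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded, sample-order-independent initialisation.

    Atoms are training columns picked by class-stratified sampling; within
    each class, candidate columns are ranked by a lexicographic sort of
    their feature values, so a permutation of the training samples yields
    the same atoms.  Selected atoms are scaled onto the unit sphere.  A is
    the ridge-regression code of X on D, W an identity padded/truncated to
    K x m.
    """
    rng = np.random.default_rng(hp.seed)
    d, N = X.shape
    class_ids = np.unique(labels)
    K = class_ids.size
    # per-class quota, round-robin remainder in class order
    base, extra = divmod(n_atoms, K)
    quotas = {cid: base + (1 if k < extra else 0) for k, cid in enumerate(class_ids)}
    cols: list[np.ndarray] = []
    for cid in class_ids:
        members = X[:, labels == cid]
        order = np.lexsort(members[::-1])  # lexicographic by feature values
        members = members[:, order]
        q = quotas[cid]
        if q <= members.shape[1]:
            pick = rng.choice(members.shape[1], size=q, replace=False)
        else:
            pick = rng.choice(members.shape[1], size=q, replace=True)
        cols.append(members[:, np.sort(pick)])
    D = np.concatenate(cols, axis=1)[:, :n_atoms]
    norms = np.linalg.norm(D, axis=0)
    D = D / np.maximum(norms, 1e-12)
    ridge = max(hp.lambda1, 1e-8)
    A = np.linalg.solve(D.T @ D + ridge * np.eye(n_atoms), D.T @ X)
    W = np.eye(n_classes, n_atoms)
    return D, A, W


def fit_lmls(
    X: np.ndarray,
    labels: np.ndarray,
    hp: Hyperparameters,
    S_sym: np.ndarray,
    L: np.ndarray,
    n_atoms: int | None = None,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, FitTrace]:
    """Alternating-minimisation training loop.

    Parameters
    ----------
    X : (d, N) feature matrix, samples as columns.
    labels : (N,) integer class ids.
    hp : Hyperparameters.
    S_sym, L : the margin and Laplacian matrices built on the training set.
    n_atoms : dictionary size m; default N (one atom per training sample).
    init : optional (D0, A0, W0) overriding the default initialisation.

    Returns
    -------
    (D, A, W, trace) with D satisfying the unit-ball atom constraint and
    ``trace.objective_values`` the per-iteration F values (index 0 is the
    objective at initialisation).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    d, N = X.shape
    if labels.shape != (N,):
        raise ValueError("labels length must match the number of columns of X")
    class_ids = np.unique(labels)
    K = class_ids.size
    m = N if n_atoms is None else int(n_atoms)
    if m < 1:
        raise ValueError("n_atoms must be >= 1")
    Y = (labels[None, :] == class_ids[:, None]).astype(float)

    if init is None:
        D, A, W = _init_blocks(X, labels, m, K, hp)
    else:
        D, A, W = (np.array(b, dtype=float, copy=True) for b in init)

    G = hp.lambda2 * S_sym + hp.lambda3 * L
    G_eig = scipy.linalg.eigh(G)

    trace = FitTrace()
    F_prev, _ = evaluate_objective(X, D, A, W, Y, S_sym, L, hp)
    trace.objective_values.append(F_prev)
    n_increases = 0
    for _ in range(hp.maxiter):
        D = update_dictionary(X, D, A)
        Omega = update_row_weights(A, hp.eps_row)
        A = update_coefficients(X, D, W, Y, Omega, S_sym, L, hp, G_eig=G_eig)
        W = update_classifier(A, Y, hp.lambda4, hp.lambda5)
        F, _ = evaluate_objective(X, D, A, W, Y, S_sym, L, hp)
        trace.objective_values.append(F)
        rel = abs(F - F_prev) / max(abs(F_prev), 1e-300)
        if F > F_prev * (1 + 1e-6):
            n_increases += 1
            if n_increases >= 3:
                warnings.warn(
                    "objective increased for 3 consecutive iterations; trace: "
                    f"{trace.objective_values}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                n_increases = 0
        else:
            n_increases = 0
        F_prev = F
        if rel < hp.delta:
            trace.converged = True
            break
    return D, A, W, trace
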