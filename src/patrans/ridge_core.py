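"""Ridge estimation of voxel-by-voxel linear transformations.

Given z-scored pattern matrices X (input region, N_X voxels x N_s stimuli)
and Y (output region, N_Y x N_s), the transformation estimate is the ridge
solution

    T_lam = Y X' (X X' + lam I)^{-1},

the unique minimiser of ||M X - Y||_F^2 + lam ||M||_F^2.  The
regularisation weight lam is chosen by leave-one-stimulus-out
cross-validation.  Rather than refitting N_s times per candidate, the
leave-one-out residual sum of squares is computed with the hat-matrix
identity

    Lambda(alpha) = || A(alpha) (I - H(alpha)) Y' ||_F^2,

where H(alpha) = X'(XX' + alpha I)^{-1} X is the N_s x N_s hat matrix of
the ridge fit and A(alpha) is diagonal with entries 1/(1 - h_ii(alpha)).
(The identity inside H acts on the N_X-dimensional voxel space; the outer
identity and A are N_s x N_s.)  For z-scored output columns
||Y_col||^2 = N_Y, so the leverage-corrected residual sum doubles as the
numerator of the goodness-of-fit

    GOF = 100 (1 - Lambda(lam) / (N_Y N_s)),

the cross-validated percentage of output-pattern variance explained by
the linear mapping.  GOF is reported unclipped: negative values mean the
cross-validated fit predicts worse than the zero map, which is
informative and should not be hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh, LinAlgError

from .patterns_io import PatternMatrix

__all__ = [
    "TransformEstimate",
    "HatDiagnostics",
    "GofResult",
    "LambdaSelection",
    "LeverageError",
    "default_lambda_grid",
    "estimate_transform",
    "hat_diagnostics",
    "loocv_objective",
    "select_lambda",
    "select_lambda_kfold",
    "compute_gof",
    "fit_transform",
]


class LeverageError(ValueError):
    """A leverage h_ii >= 1: alpha too small for the data rank."""


class LambdaSelection(NamedTuple):
    lam: float
    grid: np.ndarray
    curve: np.ndarray  # Lambda(alpha) per grid candidate


@dataclass(frozen=True)
class HatDiagnostics:
    """Hat matrix H(alpha), its diagonal leverages and 1/(1-h_ii) weights."""

    H: np.ndarray
    leverage: np.ndarray
    A_weights: np.ndarray


@dataclass(frozen=True)
class GofResult:
    gof_percent: float
    per_stimulus_gof: np.ndarray
    per_stimulus_sq_residual: np.ndarray


@dataclass(frozen=True)
class TransformEstimate:
    """A fitted transformation with its selected lam and fit metrics."""

    T_hat: np.ndarray
    lam: float
    gof_percent: float
    per_stimulus_sq_residual: np.ndarray
    lambda_grid: np.ndarray
    loocv_curve: np.ndarray

    @property
    def per_stimulus_gof(self) -> np.ndarray:
        n_y = self.T_hat.shape[0]
        return 100.0 * (1.0 - self.per_stimulus_sq_residual / n_y)


def _values(m: PatternMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, PatternMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def default_lambda_grid(lo: float = 1e-2, hi: float = 1e4, n: int = 61) -> np.ndarray:
    """Log-spaced candidate grid for the regularisation weight."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def estimate_transform(
    X: PatternMatrix | np.ndarray,
    Y: PatternMatrix | np.ndarray,
    lam: float,
) -> np.ndarray:
    """Ridge solution T_lam = Y X'(XX' + lam I)^{-1} via a Cholesky solve.

    ``lam = 0`` is admitted only when XX' is invertible (ordinary least
    squares); otherwise a singularity error is raised.
    """
    Xv, Yv = _values(X), _values(Y)
    if Xv.shape[1] != Yv.shape[1]:
        raise ValueError(
            f"X has {Xv.shape[1]} stimuli but Y has {Yv.shape[1]}"
        )
    if lam < 0:
        raise ValueError("lam must be non-negative")
    K = Xv @ Xv.T
    K[np.diag_indices_from(K)] += lam
    try:
        c = cho_factor(K, lower=True)
    except LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"XX' + lam I is singular at lam={lam}; "
            "rank-deficient X needs lam > 0"
        ) from exc
    # T' = (XX' + lam I)^{-1} X Y'
    return cho_solve(c, Xv @ Yv.T).T


class _RidgeEigen:
    """Eigendecomposition of XX' shared across a grid of candidates."""

    def __init__(self, X: np.ndarray):
        self.X = X
        d, Q = eigh(X @ X.T)
        self.d = np.clip(d, 0.0, None)
        self.Q = Q
        self.G = Q.T @ X  # (N_X, N_s) in the eigenbasis

    def projector(self, lam: float) -> np.ndarray:
        """X'(XX' + lam I)^{-1} as an (N_s, N_X) matrix; T_hat = Y @ projector."""
        w = 1.0 / (self.d + lam)
        return self.G.T @ (self.Q * w).T

    def leverages(self, alpha: float) -> np.ndarray:
        w = 1.0 / (self.d + alpha)
        return np.einsum("ki,k,ki->i", self.G, w, self.G)

    def residual_matrix(self, alpha: float, Y: np.ndarray) -> np.ndarray:
        """(I - H(alpha)) Y', shape (N_s, N_Y)."""
        w = 1.0 / (self.d + alpha)
        GY = self.G @ Y.T  # (N_X, N_Y)
        return Y.T - self.G.T @ (w[:, None] * GY)

    def objective(self, alpha: float, Y: np.ndarray) -> float:
        h = self.leverages(alpha)
        if np.any(h >= 1.0):
            raise LeverageError(
                f"leverage h_ii >= 1 at alpha={alpha}; "
                "increase the regularisation"
            )
        R = self.residual_matrix(alpha, Y)
        a = 1.0 / (1.0 - h)
        return float(np.sum((a[:, None] * R) ** 2))


def hat_diagnostics(
    X: PatternMatrix | np.ndarray, alpha: float
) -> HatDiagnostics:
    """Hat matrix H(alpha) = X'(XX'+alpha I)^{-1}X with leverages."""
    Xv = _values(X)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    eig = _RidgeEigen(Xv)
    w = 1.0 / (eig.d + alpha)
    H = eig.G.T @ (w[:, None] * eig.G)
    h = np.diag(H).copy()
    if np.any(h >= 1.0):
        raise LeverageError(f"leverage h_ii >= 1 at alpha={alpha}")
    return HatDiagnostics(H=H, leverage=h, A_weights=1.0 / (1.0 - h))


def loocv_objective(
    X: PatternMatrix | np.ndarray,
    Y: PatternMatrix | np.ndarray,
    alpha: float,
) -> float:
    """Leverage-corrected sum of squared leave-one-stimulus-out residuals.

    Equals the explicit loop that refits the transformation N_s times,
    each time holding one stimulus out, at a fraction of the cost.
    """
    Xv, Yv = _values(X), _values(Y)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return _RidgeEigen(Xv).objective(alpha, Yv)


def select_lambda(
    X: PatternMatrix | np.ndarray,
    Y: PatternMatrix | np.ndarray,
    grid: Sequence[float] | np.ndarray | None = None,
) -> LambdaSelection:
    """Pick lam as the grid argmin of the leave-one-out objective.

    Ties go to the smallest lam (less shrinkage at equal CV error).  A
    warning is emitted when the argmin sits at a grid endpoint, since the
    true optimum may lie outside the searched range.
    """
    Xv, Yv = _values(X), _values(Y)
    grid_arr = default_lambda_grid() if grid is None else np.asarray(grid, float)
    if grid_arr.size < 1:
        raise ValueError("empty candidate grid")
    if np.any(grid_arr <= 0):
        raise ValueError("grid candidates must be positive")
    eig = _RidgeEigen(Xv)
    curve = np.array([eig.objective(a, Yv) for a in grid_arr])
    order = np.argsort(grid_arr)
    best = order[int(np.argmin(curve[order]))]  # smallest lam among ties
    if best in (order[0], order[-1]) and grid_arr.size > 1:
        warnings.warn(
            f"selected lam={grid_arr[best]:g} is a grid endpoint; "
            "consider widening the grid",
            stacklevel=2,
        )
    return LambdaSelection(float(grid_arr[best]), grid_arr, curve)


def select_lambda_kfold(
    X: PatternMatrix | np.ndarray,
    Y: PatternMatrix | np.ndarray,
    grid: Sequence[float] | np.ndarray | None = None,
    k: int = 10,
    seed: int | None = None,
) -> LambdaSelection:
    """k-fold variant: argmin of summed held-out squared residuals.

    Stimuli are shuffled once (seeded) and split into k contiguous folds.
    ``k = N_s`` reproduces the leave-one-out selection.
    """
    Xv, Yv = _values(X), _values(Y)
    n_s = Xv.shape[1]
    if k < 2 or k > n_s:
        raise ValueError(f"k={k} must be in [2, N_s={n_s}]")
    grid_arr = default_lambda_grid() if grid is None else np.asarray(grid, float)
    if grid_arr.size < 1:
        raise ValueError("empty candidate grid")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_s)
    folds = np.array_split(perm, k)
    curve = np.zeros(grid_arr.size)
    for fold in folds:
        keep = np.setdiff1d(np.arange(n_s), fold)
        Xtr, Ytr = Xv[:, keep], Yv[:, keep]
        Xte, Yte = Xv[:, fold], Yv[:, fold]
        K = Xtr @ Xtr.T
        for gi, alpha in enumerate(grid_arr):
            Ka = K.copy()
            Ka[np.diag_indices_from(Ka)] += alpha
            T = cho_solve(cho_factor(Ka, lower=True), Xtr @ Ytr.T).T
            curve[gi] += float(np.sum((T @ Xte - Yte) ** 2))
    order = np.argsort(grid_arr)
    best = order[int(np.argmin(curve[order]))]
    return LambdaSelection(float(grid_arr[best]), grid_arr, curve)


def compute_gof(
    X: PatternMatrix | np.ndarray,
    Y: PatternMatrix | np.ndarray,
    lam: float,
) -> GofResult:
    """Cross-validated percentage goodness-of-fit at a given lam.

    ``GOF = 100 (1 - Lambda(lam) / (N_Y N_s))``; requires z-scored Y
    columns so that each column's squared norm equals N_Y.  The
    per-stimulus vector ``100 (1 - r_i / N_Y)`` (with r_i the
    leverage-corrected held-out squared residual of stimulus i) supports
    per-stimulus contrasts; its mean is the overall GOF.
    """
    Xv, Yv = _values(X), _values(Y)
    if lam <= 0:
        raise ValueError("lam must be positive")
    n_y, n_s = Yv.shape
    eig = _RidgeEigen(Xv)
    h = eig.leverages(lam)
    if np.any(h >= 1.0):
        raise LeverageError(f"leverage h_ii >= 1 at lam={lam}")
    R = eig.residual_matrix(lam, Yv)
    r = np.sum(R**2, axis=1) / (1.0 - h) ** 2  # per-stimulus LOO residual
    gof = 100.0 * (1.0 - float(r.sum()) / (n_y * n_s))
    return GofResult(
        gof_percent=gof,
        per_stimulus_gof=100.0 * (1.0 - r / n_y),
        per_stimulus_sq_residual=r,
    )


def fit_transform(
    X: PatternMatrix | np.ndarray,
    Y: PatternMatrix | np.ndarray,
    grid: Sequence[float] | np.ndarray | None = None,
    kfold: int | None = None,
    seed: int | None = None,
) -> TransformEstimate:
    """Full pipeline: select lam, estimate T_lam, compute GOF.

    ``kfold`` switches lam selection from leave-one-stimulus-out to
    seeded k-fold cross-validation.
    """
    if kfold is None:
        sel = select_lambda(X, Y, grid)
    else:
        sel = select_lambda_kfold(X, Y, grid, k=kfold, seed=seed)
    T = estimate_transform(X, Y, sel.lam)
    gof = compute_gof(X, Y, sel.lam)
    return TransformEstimate(
        T_hat=T,
        lam=sel.lam,
        gof_percent=gof.gof_percent,
        per_stimulus_sq_residual=gof.per_stimulus_sq_residual,
        lambda_grid=sel.grid,
        loocv_curve=sel.curve,
    )
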