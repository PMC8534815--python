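"""Ridge-regularized GLS estimators for the linear mixed model.

Three estimators of the fixed effects, all in the V^{-1} metric after
blockwise whitening:

* ``ridge_full`` — full-model ridge, beta = (X'V^{-1}X + kI)^{-1} X'V^{-1}Y;
  solved in the dual (N x N) form when p > N.
* ``ridge_submodel`` — the sub-model estimator of beta1 fit on X1 only under
  the restriction beta2 = 0.
* ``ridge_full_beta1`` — the full-model estimator of beta1 obtained by
  projecting out the sparse block X2 (Frisch–Waugh in the V^{-1} metric):
  beta1 = (X1'V^{-1/2} M V^{-1/2} X1 + kI)^{-1} X1'V^{-1/2} M V^{-1/2} Y with
  M = I - V^{-1/2}X2 (X2'V^{-1}X2)^{-1} X2'V^{-1/2}.  When X2'V^{-1}X2 is
  singular (always for p2 >= N) the inner inverse is replaced per
  ``inner_inverse``: ``"ridge"`` adds the same k, ``"pinv"`` uses the
  Moore–Penrose inverse.

``select_k`` chooses k by subject-level K-fold cross-validation of the
marginal-mean prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .lmm import (
    LongitudinalDataset,
    MarginalCovariance,
    RankDeficiencyError,
    ValidationError,
    _whitened,
)

__all__ = [
    "RidgeConfig",
    "EstimatorResult",
    "ridge_full",
    "ridge_submodel",
    "ridge_full_beta1",
    "select_k",
]

#: default cross-validation grid for the ridge tuning parameter
DEFAULT_K_GRID = np.logspace(-4, 2, 50)


@dataclass
class RidgeConfig:
    """Ridge tuning: fixed k, CV grid, fold count and CV seed."""

    k: float = 0.0
    k_grid: np.ndarray = field(default_factory=lambda: DEFAULT_K_GRID.copy())
    cv_folds: int = 5
    cv_seed: int = 0

    def __post_init__(self):
        self.k_grid = np.asarray(self.k_grid, float).ravel()
        if self.k < 0:
            raise ValidationError("k must be >= 0")
        if self.k_grid.size and np.any(self.k_grid < 0):
            raise ValidationError("k_grid entries must be >= 0")


@dataclass
class EstimatorResult:
    """A named estimate of the non-sparse block beta1 with its tuning values."""

    name: str
    beta1: np.ndarray
    k: float | None = None
    alpha: float | None = None
    meta: dict = field(default_factory=dict)

    _NAMES = ("RFM", "RSM", "RPT", "RSE", "RPS", "LASSO", "aLASSO")

    def __post_init__(self):
        if self.name not in self._NAMES:
            raise ValidationError(f"unknown estimator name {self.name!r}")
        self.beta1 = np.asarray(self.beta1, float).ravel()


def _ridge_solve(Xw: np.ndarray, yw: np.ndarray, k: float) -> np.ndarray:
    """Solve (Xw'Xw + kI) b = Xw'yw, in the dual form when p > N."""
    N, p = Xw.shape
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k == 0:
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < p:
            raise RankDeficiencyError(
                "Gram matrix singular at k=0; use the ridge path (k > 0)"
            )
        return beta
    if p <= N:
        A = Xw.T @ Xw + k * np.eye(p)
        c, low = linalg.cho_factor(A, lower=True)
        return linalg.cho_solve((c, low), Xw.T @ yw)
    # dual: beta = Xw'(Xw Xw' + kI)^{-1} yw, identical to the primal solution
    K = Xw @ Xw.T + k * np.eye(N)
    c, low = linalg.cho_factor(K, lower=True)
    return Xw.T @ linalg.cho_solve((c, low), yw)


def ridge_full(data: LongitudinalDataset, V: MarginalCovariance,
               k: float) -> np.ndarray:
    """Full-model ridge-GLS coefficient vector (length p); GLS when k = 0."""
    Xw, yw = _whitened(data, V)
    return _ridge_solve(Xw, yw, float(k))


def ridge_submodel(data: LongitudinalDataset, V: MarginalCovariance,
                   k: float) -> EstimatorResult:
    """Sub-model estimator of beta1: ridge-GLS on the non-sparse columns X1."""
    if data.p1 < 1:
        raise ValidationError("sub-model requires at least one non-sparse column")
    X1w = V.whiten(data.X1)
    yw = V.whiten(data.y)
    return EstimatorResult("RSM", _ridge_solve(X1w, yw, float(k)), k=float(k))


def _project_out(X2w: np.ndarray, M: np.ndarray, k: float,
                 inner_inverse: str) -> np.ndarray:
    """Apply M_{X2} = I - X2w (X2w'X2w)^{-1} X2w' to M (whitened arrays).

    The inner inverse follows ``inner_inverse`` when X2w'X2w is singular.
    """
    N, p2 = X2w.shape
    if inner_inverse == "pinv":
        U, s, _ = np.linalg.svd(X2w, full_matrices=False)
        r = int(np.sum(s > s[0] * max(N, p2) * np.finfo(float).eps)) if s.size else 0
        Ur = U[:, :r]
        return M - Ur @ (Ur.T @ M)
    if inner_inverse != "ridge":
        raise ValidationError("inner_inverse must be 'ridge' or 'pinv'")
    if p2 < N:
        A = X2w.T @ X2w
        try:
            c, low = linalg.cho_factor(A, lower=True)
            return M - X2w @ linalg.cho_solve((c, low), X2w.T @ M)
        except np.linalg.LinAlgError:
            pass
    if k == 0:
        return _project_out(X2w, M, k, "pinv")
    # (X2w'X2w + kI)^{-1} X2w' == X2w'(X2w X2w' + kI)^{-1}: N x N solve
    K = X2w @ X2w.T + k * np.eye(N)
    c, low = linalg.cho_factor(K, lower=True)
    return M - (X2w @ X2w.T) @ linalg.cho_solve((c, low), M)


def ridge_full_beta1(data: LongitudinalDataset, V: MarginalCovariance, k: float,
                     inner_inverse: str = "ridge") -> EstimatorResult:
    """Full-model estimator of beta1 with the sparse block projected out."""
    if data.p1 < 1 or data.p2 < 1:
        raise ValidationError("ridge_full_beta1 requires p1 >= 1 and p2 >= 1")
    k = float(k)
    X1w = V.whiten(data.X1)
    X2w = V.whiten(data.X2)
    yw = V.whiten(data.y)
    M = _project_out(X2w, np.column_stack([X1w, yw]), k, inner_inverse)
    MX1, My = M[:, :-1], M[:, -1]
    C = X1w.T @ MX1 + k * np.eye(data.p1)
    b = X1w.T @ My
    try:
        c, low = linalg.cho_factor(0.5 * (C + C.T), lower=True)
        beta1 = linalg.cho_solve((c, low), b)
    except np.linalg.LinAlgError:
        beta1, *_ = np.linalg.lstsq(C, b, rcond=None)
    return EstimatorResult("RFM", beta1, k=k,
                           meta={"inner_inverse": inner_inverse})


def select_k(data: LongitudinalDataset, V: MarginalCovariance,
             cfg: RidgeConfig) -> float:
    """Subject-level K-fold CV choice of k for the full-model ridge fit.

    For each k on the grid the full ridge estimator is fit on the training
    subjects and scored by the squared prediction error of the marginal mean
    X beta on the held-out subjects (raw response scale).  Returns the grid
    argmin; ties and duplicates resolve to the first (smallest) occurrence.
    """
    grid = cfg.k_grid
    if grid.size == 0:
        raise ValidationError("k_grid is empty")
    if cfg.cv_folds < 2 or cfg.cv_folds > data.n:
        raise ValidationError("cv_folds must be in [2, n]")
    Xw, yw = _whitened(data, V)
    slices = data.subject_slices()
    rng = np.random.default_rng(cfg.cv_seed)
    order = rng.permutation(data.n)
    folds = np.array_split(order, cfg.cv_folds)
    sse = np.zeros(grid.size)
    for fold in folds:
        test_rows = np.concatenate([np.arange(s.start, s.stop)
                                    for s in (slices[i] for i in fold)])
        mask = np.ones(data.N, bool)
        mask[test_rows] = False
        U, s, Vt = np.linalg.svd(Xw[mask], full_matrices=False)
        Uty = U.T @ yw[mask]
        W = data.X[test_rows] @ Vt.T          # (n_test, r)
        y_test = data.y[test_rows]
        for j, k in enumerate(grid):
            shrink = s / (s ** 2 + k) if k > 0 else np.divide(
                1.0, s, out=np.zeros_like(s), where=s > s[0] * 1e-12)
            pred = W @ (shrink * Uty)
            sse[j] += np.sum((y_test - pred) ** 2)
    return float(grid[int(np.argmin(sse))])
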