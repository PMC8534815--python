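"""Linear mixed model core.

The model for subject ``i`` with ``n_i`` repeated measures is

    Y_i = X_i beta + Z_i a_i + eps_i,
    a_i ~ N(0, G),  eps_i ~ N(0, sigma^2 I),

so marginally ``Y_i ~ N(X_i beta, V_i)`` with ``V_i = Z_i G Z_i' + sigma^2 I``
and zero covariance across subjects.  This module holds the data containers,
the block-diagonal marginal covariance with per-subject Cholesky factors, the
generalized least squares fit, the marginal Gaussian log-likelihood, and
maximum-likelihood estimation of the variance components (G, sigma^2).

The fixed-effect columns are partitioned into a "non-sparse" block X1 (the p1
coefficients of scientific interest) and a "sparse" block X2 (the p2
coefficients believed to be zero); all downstream estimators target beta1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "ValidationError",
    "RankDeficiencyError",
    "ConvergenceError",
    "LongitudinalDataset",
    "VarianceStructure",
    "MarginalCovariance",
    "build_marginal_covariance",
    "gls_fit",
    "marginal_loglik",
    "fit_variance_components",
]

# smallest admissible eigenvalue for positive-definiteness checks
_PD_TOL = 1e-10


class ValidationError(ValueError):
    """Invalid input data, dimensions, or variance parameters."""


class RankDeficiencyError(np.linalg.LinAlgError):
    """X'V^{-1}X is singular; a ridge fit (k > 0) is required."""


class ConvergenceError(RuntimeError):
    """Variance-component optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class LongitudinalDataset:
    """Stacked longitudinal data with a non-sparse/sparse column partition.

    Rows must be grouped contiguously by subject.  ``x1_idx``/``x2_idx`` are
    disjoint integer index sets covering ``0..p-1``; X1 = X[:, x1_idx] holds
    the non-sparse predictors and X2 = X[:, x2_idx] the sparse ones.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    groups: np.ndarray
    x1_idx: np.ndarray
    x2_idx: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.Z = np.atleast_2d(np.asarray(self.Z, float))
        self.groups = np.asarray(self.groups)
        self.x1_idx = np.asarray(self.x1_idx, int).ravel()
        self.x2_idx = np.asarray(self.x2_idx, int).ravel()
        N = self.y.shape[0]
        if self.X.shape[0] != N or self.Z.shape[0] != N or self.groups.shape[0] != N:
            raise ValidationError("y, X, Z and groups must share the row count")
        idx = np.concatenate([self.x1_idx, self.x2_idx])
        if len(idx) != self.p or len(np.unique(idx)) != self.p or (
            len(idx) and (idx.min() < 0 or idx.max() >= self.p)
        ):
            raise ValidationError("x1_idx and x2_idx must disjointly cover 0..p-1")
        # contiguous subject blocks
        codes = self._codes = np.unique(self.groups, return_inverse=True)[1]
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], change, [N]])
        if len(np.unique(codes[starts[:-1]])) != len(starts) - 1:
            raise ValidationError("rows must be grouped contiguously by subject")
        self._starts = starts

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of subjects."""
        return len(self._starts) - 1

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def p1(self) -> int:
        return len(self.x1_idx)

    @property
    def p2(self) -> int:
        return len(self.x2_idx)

    @property
    def n_i(self) -> np.ndarray:
        return np.diff(self._starts)

    @property
    def X1(self) -> np.ndarray:
        return self.X[:, self.x1_idx]

    @property
    def X2(self) -> np.ndarray:
        return self.X[:, self.x2_idx]

    def subject_slices(self):
        return [slice(a, b) for a, b in zip(self._starts[:-1], self._starts[1:])]

    def iter_subjects(self):
        for s in self.subject_slices():
            yield self.y[s], self.X[s], self.Z[s]

    @classmethod
    def from_blocks(cls, blocks, x1_idx, x2_idx=None):
        """Build from a list of per-subject ``(y_i, X_i, Z_i)`` triples."""
        ys, Xs, Zs, gs = [], [], [], []
        for i, (yi, Xi, Zi) in enumerate(blocks):
            yi = np.asarray(yi, float).ravel()
            if len(yi) < 1:
                raise ValidationError("each subject needs at least one row")
            ys.append(yi)
            Xs.append(np.atleast_2d(np.asarray(Xi, float)))
            Zs.append(np.atleast_2d(np.asarray(Zi, float)))
            gs.append(np.full(len(yi), i))
        X = np.vstack(Xs)
        p = X.shape[1]
        x1_idx = np.asarray(x1_idx, int)
        if x2_idx is None:
            x2_idx = np.setdiff1d(np.arange(p), x1_idx)
        return cls(np.concatenate(ys), X, np.vstack(Zs), np.concatenate(gs),
                   x1_idx, x2_idx)


@dataclass
class VarianceStructure:
    """Random-effect covariance G (q x q, PSD) and error variance sigma^2."""

    G: np.ndarray
    sigma2: float
    boundary: bool = False
    info: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.G = np.atleast_2d(np.asarray(self.G, float))
        self.sigma2 = float(self.sigma2)
        if self.G.shape[0] != self.G.shape[1]:
            raise ValidationError("G must be square")
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise ValidationError("G must be symmetric")
        if self.G.size and np.linalg.eigvalsh(self.G).min() < -_PD_TOL:
            raise ValidationError("G must be positive semidefinite")
        if not self.sigma2 > 0:
            raise ValidationError("sigma2 must be > 0")

    @property
    def q(self) -> int:
        return self.G.shape[0]


class MarginalCovariance:
    """Block-diagonal marginal covariance V with per-subject Cholesky factors.

    V_i = Z_i G Z_i' + sigma^2 I.  Only the small per-subject blocks are ever
    formed; subjects sharing the same (n_i, Z_i) share one factor.  All
    V^{-1}-weighted products go through ``whiten`` (left-multiplication of
    stacked arrays by blockdiag(L_i^{-1}) where V_i = L_i L_i').
    """

    def __init__(self, data: LongitudinalDataset, vs: VarianceStructure):
        if vs.q != data.q:
            raise ValidationError(
                f"G is {vs.q}x{vs.q} but the random-effect design has q={data.q}"
            )
        self._slices = data.subject_slices()
        self._n_i = data.n_i
        cache: dict = {}
        self._keys = []
        self._L = {}
        self._Linv = {}
        logdet = 0.0
        for s in self._slices:
            Zi = data.Z[s]
            key = (Zi.shape[0], Zi.tobytes())
            if key not in cache:
                Vi = Zi @ vs.G @ Zi.T + vs.sigma2 * np.eye(Zi.shape[0])
                try:
                    L = np.linalg.cholesky(Vi)
                except np.linalg.LinAlgError as e:  # pragma: no cover - guarded by vs
                    raise ValidationError("marginal covariance block not PD") from e
                if np.min(np.diag(L)) ** 2 < _PD_TOL:
                    raise ValidationError("marginal covariance block nearly singular")
                cache[key] = (L, linalg.solve_triangular(L, np.eye(L.shape[0]),
                                                         lower=True))
            self._keys.append(key)
            logdet += 2.0 * np.sum(np.log(np.diag(cache[key][0])))
        for key, (L, Linv) in cache.items():
            self._L[key] = L
            self._Linv[key] = Linv
        self._logdet = logdet

    @property
    def logdet(self) -> float:
        """log det V (sum of the per-subject block log-determinants)."""
        return self._logdet

    @property
    def n_blocks(self) -> int:
        return len(self._slices)

    def blocks(self):
        """Dense per-subject blocks V_i (small matrices; for diagnostics)."""
        return [self._L[k] @ self._L[k].T for k in self._keys]

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Apply blockdiag(L_i^{-1}) to the rows of a stacked vector/matrix."""
        M = np.asarray(M, float)
        out = np.empty_like(M, dtype=float)
        for s, key in zip(self._slices, self._keys):
            out[s] = self._Linv[key] @ M[s]
        return out

    def solve(self, M: np.ndarray) -> np.ndarray:
        """V^{-1} M via the per-subject factors."""
        M = np.asarray(M, float)
        out = np.empty_like(M, dtype=float)
        for s, key in zip(self._slices, self._keys):
            Linv = self._Linv[key]
            out[s] = Linv.T @ (Linv @ M[s])
        return out

    def quad(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """A' V^{-1} B for stacked arrays A, B."""
        return self.whiten(A).T @ self.whiten(B)


def build_marginal_covariance(data: LongitudinalDataset,
                              vs: VarianceStructure) -> MarginalCovariance:
    """Build the block marginal covariance V_i = Z_i G Z_i' + sigma^2 I."""
    return MarginalCovariance(data, vs)


def _whitened(data: LongitudinalDataset, V: MarginalCovariance):
    return V.whiten(data.X), V.whiten(data.y)


def gls_fit(data: LongitudinalDataset, V: MarginalCovariance) -> np.ndarray:
    """Generalized least squares: beta = (X'V^{-1}X)^{-1} X'V^{-1} Y."""
    Xw, yw = _whitened(data, V)
    beta, _, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < data.p:
        raise RankDeficiencyError(
            "X'V^{-1}X is singular (rank %d < p=%d); use the ridge path (k > 0)"
            % (rank, data.p)
        )
    return beta


def marginal_loglik(beta: np.ndarray, data: LongitudinalDataset,
                    V: MarginalCovariance) -> float:
    """Marginal Gaussian log-likelihood sum_i log N(Y_i; X_i beta, V_i)."""
    beta = np.asarray(beta, float).ravel()
    if beta.shape[0] != data.p:
        raise ValidationError(f"beta has length {len(beta)}, expected p={data.p}")
    rw = V.whiten(data.y - data.X @ beta)
    return -0.5 * (data.N * np.log(2.0 * np.pi) + V.logdet + rw @ rw)


def _theta_to_vs(theta: np.ndarray, q: int) -> VarianceStructure:
    # theta = (log sigma2, log-Cholesky of G): diagonal entries on log scale
    sigma2 = float(np.exp(theta[0]))
    L = np.zeros((q, q))
    pos = 1
    for j in range(q):
        L[j, j] = np.exp(theta[pos])
        pos += 1
        L[j, :j] = theta[pos:pos + j]
        pos += j
    return VarianceStructure(L @ L.T, sigma2)


def fit_variance_components(data: LongitudinalDataset, *, start=None,
                            maxiter: int = 500,
                            boundary_tol: float = 1e-6) -> VarianceStructure:
    """Maximum-likelihood (G, sigma^2) by optimizing the profile likelihood.

    beta is profiled out by GLS at each candidate (G, sigma^2); the
    log-Cholesky parameterization keeps G PSD throughout.  Deterministic
    given the starting point.  Raises ``ConvergenceError`` on optimizer
    failure and flags (near-)singular G as a boundary estimate.
    """
    q = data.q
    if data.n < 2:
        raise ValidationError("variance components need at least two subjects")
    if data.N <= q + 1:
        raise ValidationError("N must exceed q + 1")
    if not np.any(data.Z):
        raise ValidationError("random-effect design is identically zero")

    # moment-based start: split the OLS residual variance between G and sigma2
    b0, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
    v0 = max(float(np.var(data.y - data.X @ b0)), 1e-8)
    if start is None:
        theta0 = np.zeros(1 + q * (q + 1) // 2)
        theta0[0] = np.log(v0 / 2.0)
        pos = 1
        for j in range(q):
            theta0[pos] = 0.5 * np.log(v0 / (2.0 * q))
            pos += 1 + j
    else:
        theta0 = np.asarray(start, float)

    trace = []

    def nll(theta):
        try:
            vs = _theta_to_vs(theta, q)
            V = MarginalCovariance(data, vs)
            Xw, yw = _whitened(data, V)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            r = yw - Xw @ beta
            val = 0.5 * (data.N * np.log(2.0 * np.pi) + V.logdet + r @ r)
        except (ValidationError, np.linalg.LinAlgError):
            val = 1e12
        trace.append((theta.copy(), val))
        return val

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": maxiter * len(theta0),
                                     "xatol": 1e-8, "fatol": 1e-10})
    if not res.success:
        raise ConvergenceError(
            f"variance-component optimization did not converge: {res.message}",
            trace=trace,
        )
    vs = _theta_to_vs(res.x, q)
    eigs = np.linalg.eigvalsh(vs.G)
    scale = max(float(np.var(data.y)), vs.sigma2, float(eigs.max()), 1e-12)
    boundary = bool(eigs.min() < boundary_tol * scale
                    or vs.sigma2 < boundary_tol * scale)
    if boundary:
        warnings.warn("variance-component estimate on/near the boundary "
                      "(singular G or vanishing sigma2)", RuntimeWarning)
    vs.boundary = boundary
    vs.info = {"loglik": -res.fun, "n_iter": res.nit, "n_eval": len(trace)}
    return vs
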