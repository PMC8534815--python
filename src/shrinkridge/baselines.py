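"""LASSO and adaptive LASSO baselines on the V-whitened stacked design.

The LMM covariance is removed first: with V_i = L_i L_i', the whitened data
(Xw_i, Yw_i) = (L_i^{-1} X_i, L_i^{-1} Y_i) have unit-covariance errors, so
an ordinary l1-penalized squared-error fit on the stacked whitened design is
the natural LASSO analogue of the ridge-GLS estimators.  The adaptive LASSO
reweights the penalty by 1/|pilot_j|^gamma and is fit by column rescaling of
the same solver.  Penalties are chosen by subject-level K-fold
cross-validation at the minimum mean CV error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .lmm import LongitudinalDataset, MarginalCovariance, ValidationError
from .ridge import EstimatorResult

__all__ = ["WhitenedDesign", "whiten", "lasso_fit", "alasso_fit"]


@dataclass
class WhitenedDesign:
    """Stacked design premultiplied by blockdiag(L_i^{-1})."""

    Xw: np.ndarray
    Yw: np.ndarray
    groups: np.ndarray
    x1_idx: np.ndarray
    x2_idx: np.ndarray

    @property
    def N(self) -> int:
        return self.Yw.shape[0]

    @property
    def p(self) -> int:
        return self.Xw.shape[1]


def whiten(data: LongitudinalDataset, V: MarginalCovariance) -> WhitenedDesign:
    """Whiten the stacked data by the per-subject Cholesky factors of V."""
    return WhitenedDesign(V.whiten(data.X), V.whiten(data.y),
                          data.groups.copy(), data.x1_idx.copy(),
                          data.x2_idx.copy())


def _alpha_path(Xw, Yw, n_alphas=50, eps=1e-3):
    N = Xw.shape[0]
    amax = np.max(np.abs(Xw.T @ Yw)) / N
    if amax <= 0:
        raise ValidationError("degenerate design: X'Y is identically zero")
    return np.logspace(np.log10(amax), np.log10(amax * eps), n_alphas)


def _subject_folds(groups, folds, seed):
    uniq = np.unique(groups)
    if folds < 2 or folds > len(uniq):
        raise ValidationError("folds must be in [2, n subjects]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    for part in np.array_split(order, folds):
        test = np.isin(groups, uniq[part])
        yield ~test, test


def _cv_lasso(Xw, Yw, groups, folds, seed, n_alphas=50):
    if not np.any(Xw):
        raise ValidationError("degenerate (all-zero) design")
    alphas = _alpha_path(Xw, Yw, n_alphas)
    sse = np.zeros(len(alphas))
    for train, test in _subject_folds(groups, folds, seed):
        model = Lasso(alpha=1.0, fit_intercept=False, max_iter=5000,
                      warm_start=True)
        for j, a in enumerate(alphas):
            model.set_params(alpha=a)
            model.fit(Xw[train], Yw[train])
            r = Yw[test] - Xw[test] @ model.coef_
            sse[j] += r @ r
    best = float(alphas[int(np.argmin(sse))])
    final = Lasso(alpha=best, fit_intercept=False, max_iter=20000)
    final.fit(Xw, Yw)
    return final.coef_, best


def lasso_fit(w: WhitenedDesign, folds: int = 10, seed: int = 0,
              n_alphas: int = 50) -> EstimatorResult:
    """l1-penalized fit on the whitened design, penalty chosen by CV."""
    coef, alpha = _cv_lasso(w.Xw, w.Yw, w.groups, folds, seed, n_alphas)
    return EstimatorResult("LASSO", coef[w.x1_idx],
                           meta={"penalty": alpha, "coef_full": coef})


def alasso_fit(w: WhitenedDesign, pilot: np.ndarray, folds: int = 10,
               seed: int = 0, gamma: float = 1.0,
               n_alphas: int = 50) -> EstimatorResult:
    """Adaptive LASSO: penalty weights 1/|pilot_j|^gamma via column rescaling."""
    pilot = np.asarray(pilot, float).ravel()
    if pilot.shape[0] != w.p:
        raise ValidationError("pilot must have length p")
    if np.any(pilot == 0):
        raise ValidationError("pilot has exact zeros; cannot form 1/|pilot|^gamma")
    scale = np.abs(pilot) ** gamma
    coef_s, alpha = _cv_lasso(w.Xw * scale, w.Yw, w.groups, folds, seed, n_alphas)
    coef = coef_s * scale
    return EstimatorResult("aLASSO", coef[w.x1_idx],
                           meta={"penalty": alpha, "gamma": gamma,
                                 "coef_full": coef})
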