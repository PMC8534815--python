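"""scikit-learn style estimator classes.

``RidgeLMM`` fits the full-model ridge-GLS coefficients of a linear mixed
model; ``ShrinkageRidgeLMM`` additionally partitions the columns into
non-sparse/sparse blocks and produces the sub-model, pretest, Stein and
positive-part Stein combinations of the two fits.  Both follow the sklearn
estimator contract (``get_params``/``set_params``, ``fit`` returning self,
fitted attributes with trailing underscores) so they compose with clone,
pipelines and model selection; the grouping structure and random-effect
design are passed to ``fit`` alongside X and y.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .lmm import (
    LongitudinalDataset,
    ValidationError,
    VarianceStructure,
    build_marginal_covariance,
    fit_variance_components,
)
from .ridge import DEFAULT_K_GRID, RidgeConfig, ridge_full, ridge_full_beta1, \
    ridge_submodel, select_k
from .shrinkage import combine_all, lrt_statistic

__all__ = ["RidgeLMM", "ShrinkageRidgeLMM"]


class RidgeLMM(RegressorMixin, BaseEstimator):
    """Ridge-penalized GLS for linear mixed models.

    Parameters
    ----------
    k : float or "cv"
        Ridge tuning parameter; ``"cv"`` selects it by subject-level K-fold
        cross-validation over ``k_grid``.
    k_grid, cv_folds, cv_seed : CV configuration (used when ``k="cv"``).
    G, sigma2 : known variance components; when ``G`` is None both are
        estimated by maximum likelihood at fit time.
    """

    def __init__(self, k="cv", k_grid=None, cv_folds=5, cv_seed=0,
                 G=None, sigma2=None):
        self.k = k
        self.k_grid = k_grid
        self.cv_folds = cv_folds
        self.cv_seed = cv_seed
        self.G = G
        self.sigma2 = sigma2

    # ------------------------------------------------------------------
    def _build(self, X, y, groups, Z):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).ravel()
        if groups is None:
            raise ValidationError("groups (subject ids per row) is required")
        if Z is None:
            Z = np.ones((len(y), 1))
        x1, x2 = self._partition(X.shape[1])
        data = LongitudinalDataset(y, X, Z, np.asarray(groups), x1, x2)
        if self.G is not None:
            vs = VarianceStructure(np.asarray(self.G, float),
                                   1.0 if self.sigma2 is None else self.sigma2)
        else:
            vs = fit_variance_components(data)
        return data, vs

    def _partition(self, p):
        return np.arange(p), np.arange(p, p)

    def _choose_k(self, data, V):
        if self.k == "cv":
            grid = DEFAULT_K_GRID if self.k_grid is None else np.asarray(self.k_grid)
            cfg = RidgeConfig(k_grid=grid, cv_folds=self.cv_folds,
                              cv_seed=self.cv_seed)
            return select_k(data, V, cfg)
        return float(self.k)

    # ------------------------------------------------------------------
    def fit(self, X, y, groups=None, Z=None):
        data, vs = self._build(X, y, groups, Z)
        V = build_marginal_covariance(data, vs)
        self.k_ = self._choose_k(data, V)
        self.coef_ = ridge_full(data, V, self.k_)
        self.G_, self.sigma2_ = vs.G, vs.sigma2
        self.n_features_in_ = data.p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.atleast_2d(np.asarray(X, float)) @ self.coef_


class ShrinkageRidgeLMM(RidgeLMM):
    """Pretest / Stein-type shrinkage ridge estimation of the beta1 block.

    ``sparse_idx`` names the X columns whose coefficients are believed zero
    (the X2 block); everything else is the target block X1.  ``fit``
    computes the full-model (RFM) and sub-model (RSM) estimates of beta1,
    the likelihood-ratio statistic Ln for the restriction, and the pretest
    (RPT), Stein (RSE) and positive-part Stein (RPS) combinations; the
    ``method`` parameter selects which one populates ``coef1_``.

    Attributes
    ----------
    coef1_ : the selected estimate of beta1.
    estimates_ : dict of all computed estimates (name -> vector).
    Ln_, critical_ : the test statistic and chi2_{p2, alpha} critical value.
    """

    _METHODS = {"fm": "RFM", "sm": "RSM", "pt": "RPT", "se": "RSE", "ps": "RPS"}

    def __init__(self, sparse_idx=(), method="ps", alpha=0.05, k="cv",
                 k_grid=None, cv_folds=5, cv_seed=0, G=None, sigma2=None,
                 inner_inverse="ridge"):
        super().__init__(k=k, k_grid=k_grid, cv_folds=cv_folds,
                         cv_seed=cv_seed, G=G, sigma2=sigma2)
        self.sparse_idx = sparse_idx
        self.method = method
        self.alpha = alpha
        self.inner_inverse = inner_inverse

    def _partition(self, p):
        x2 = np.asarray(self.sparse_idx, int)
        return np.setdiff1d(np.arange(p), x2), x2

    def fit(self, X, y, groups=None, Z=None):
        if self.method not in self._METHODS:
            raise ValidationError(f"method must be one of {set(self._METHODS)}")
        data, vs = self._build(X, y, groups, Z)
        if data.p2 < 1:
            raise ValidationError("sparse_idx must name at least one column")
        V = build_marginal_covariance(data, vs)
        self.k_ = self._choose_k(data, V)
        rsm = ridge_submodel(data, V, self.k_)
        rfm = ridge_full_beta1(data, V, self.k_,
                               inner_inverse=self.inner_inverse)
        beta_full = ridge_full(data, V, self.k_ if data.p > data.N or
                               self.k_ > 0 else 0.0)
        beta_sub = np.zeros(data.p)
        beta_sub[data.x1_idx] = rsm.beta1
        test = lrt_statistic(data, V, beta_full, beta_sub, alpha=self.alpha)
        ests = combine_all(rfm, rsm, test)
        self.estimates_ = {name: e.beta1 for name, e in ests.items()}
        self.Ln_ = test.Ln
        self.critical_ = test.critical
        self.G_, self.sigma2_ = vs.G, vs.sigma2
        self.x1_idx_, self.x2_idx_ = data.x1_idx, data.x2_idx
        want = self._METHODS[self.method]
        if want not in self.estimates_:
            raise ValidationError(
                f"{want} undefined here (p2={data.p2}, Ln={test.Ln:.3g})")
        self.coef1_ = self.estimates_[want]
        self.n_features_in_ = data.p
        return self

    def predict(self, X):
        """Marginal-mean prediction from the non-sparse block, X1 beta1."""
        check_is_fitted(self, "coef1_")
        X = np.atleast_2d(np.asarray(X, float))
        return X[:, self.x1_idx_] @ self.coef1_
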