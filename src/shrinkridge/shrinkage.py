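"""Pretest and Stein-type shrinkage combinations of the full and sub-model fits.

The restriction H0: beta2 = 0 is assessed by the likelihood-ratio statistic

    Ln = 2 [ l(beta_full | Y) - l(beta_sub | Y) ],

with l the marginal Gaussian log-likelihood at the plugged-in coefficient
vectors (variance components held fixed).  Under H0 and k -> 0, Ln is
asymptotically chi-square with p2 degrees of freedom.  The combined
estimators of beta1 are

* pretest (RPT):  RFM - (RFM - RSM) 1{Ln <= d_{n,alpha}},
* Stein (RSE):    RSM + (RFM - RSM)(1 - (p2-2)/Ln),        p2 >= 3,
* positive (RPS): RSM + (RFM - RSM)(1 - (p2-2)/Ln)_+,      p2 >= 3,

where d_{n,alpha} is the upper-alpha quantile of chi2_{p2}.  RSE can
over-shrink past RSM (negative weight); RPS floors the weight at zero and is
always on the segment between RSM and RFM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lmm import LongitudinalDataset, MarginalCovariance, ValidationError, marginal_loglik
from .ridge import EstimatorResult

__all__ = [
    "TestResult",
    "lrt_statistic",
    "pretest_estimator",
    "stein_shrinkage",
    "positive_shrinkage",
    "combine_all",
]

_LN_TOL = 1e-8


@dataclass
class TestResult:
    """The Ln statistic with its chi-square reference quantities."""

    __test__ = False  # keep pytest from collecting this as a test class

    Ln: float
    p2: int
    alpha: float

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.p2 < 1:
            raise ValidationError("p2 must be >= 1")

    @property
    def critical(self) -> float:
        """d_{n,alpha}: upper-alpha quantile of chi2 with p2 df."""
        return float(stats.chi2.ppf(1.0 - self.alpha, self.p2))

    @property
    def reject(self) -> bool:
        return self.Ln > self.critical


def lrt_statistic(data: LongitudinalDataset, V: MarginalCovariance,
                  beta_full: np.ndarray, beta_sub: np.ndarray,
                  alpha: float = 0.05, strict_ln: bool = False) -> TestResult:
    """Likelihood-ratio statistic for H0: beta2 = 0 at plug-in estimates.

    Both coefficient vectors must have length p (the sub-model padded with
    zeros on the sparse columns).  With ridge plug-ins Ln can come out
    slightly negative; it is clipped at zero with a warning unless
    ``strict_ln`` requests an error.
    """
    beta_full = np.asarray(beta_full, float).ravel()
    beta_sub = np.asarray(beta_sub, float).ravel()
    if beta_full.shape != beta_sub.shape or beta_full.shape[0] != data.p:
        raise ValidationError("beta_full and beta_sub must both have length p")
    ln = 2.0 * (marginal_loglik(beta_full, data, V)
                - marginal_loglik(beta_sub, data, V))
    if ln < 0.0:
        if ln < -_LN_TOL * max(1.0, abs(ln)):
            msg = f"Ln = {ln:.3g} < 0 under ridge plug-in estimates; clipped to 0"
            if strict_ln:
                raise ValidationError(msg)
            warnings.warn(msg, RuntimeWarning)
        ln = 0.0
    return TestResult(float(ln), data.p2, alpha)


def pretest_estimator(rfm: EstimatorResult, rsm: EstimatorResult,
                      test: TestResult) -> EstimatorResult:
    """Pretest: the sub-model if Ln <= d_{n,alpha}, else the full model."""
    chosen = rsm if test.Ln <= test.critical else rfm
    return EstimatorResult("RPT", chosen.beta1.copy(), k=rfm.k, alpha=test.alpha,
                           meta={"Ln": test.Ln, "critical": test.critical,
                                 "chose": chosen.name})


def _shrinkage_weight(test: TestResult) -> float:
    if test.p2 < 3:
        raise ValidationError("Stein-type shrinkage requires p2 >= 3")
    if test.Ln <= 0.0:
        raise ValidationError(
            "Ln = 0: shrinkage weight 1 - (p2-2)/Ln is undefined"
        )
    return 1.0 - (test.p2 - 2) / test.Ln


def stein_shrinkage(rfm: EstimatorResult, rsm: EstimatorResult,
                    test: TestResult) -> EstimatorResult:
    """Stein-type: RSM + (RFM - RSM)(1 - (p2-2)/Ln); may over-shrink."""
    w = _shrinkage_weight(test)
    beta1 = rsm.beta1 + (rfm.beta1 - rsm.beta1) * w
    return EstimatorResult("RSE", beta1, k=rfm.k, alpha=test.alpha,
                           meta={"Ln": test.Ln, "weight": w})


def positive_shrinkage(rfm: EstimatorResult, rsm: EstimatorResult,
                       test: TestResult) -> EstimatorResult:
    """Positive-part Stein: weight floored at 0, a convex combination."""
    w = max(0.0, _shrinkage_weight(test))
    beta1 = rsm.beta1 + (rfm.beta1 - rsm.beta1) * w
    return EstimatorResult("RPS", beta1, k=rfm.k, alpha=test.alpha,
                           meta={"Ln": test.Ln, "weight": w})


def combine_all(rfm: EstimatorResult, rsm: EstimatorResult,
                test: TestResult) -> dict[str, EstimatorResult]:
    """All five estimators of beta1 from one (RFM, RSM, Ln) triple."""
    out = {"RFM": rfm, "RSM": rsm, "RPT": pretest_estimator(rfm, rsm, test)}
    if test.p2 >= 3 and test.Ln > 0.0:
        out["RSE"] = stein_shrinkage(rfm, rsm, test)
        out["RPS"] = positive_shrinkage(rfm, rsm, test)
    return out
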