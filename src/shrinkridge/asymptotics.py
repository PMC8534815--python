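"""Asymptotic bias, covariance and risk of the five beta1 estimators.

Frame: local alternatives beta2 = kappa / sqrt(n), a limit matrix
B = lim n^{-1} X'V^{-1}X partitioned conformably with (beta1, beta2), and a
ridge drift k/n -> lambda0.  Writing

    B22.1 = B22 - B21 B11^{-1} B12,      B11.2 = B11 - B12 B22^{-1} B21,
    delta = B11^{-1} B12 kappa,          Phi = B11^{-1} B12 B22.1^{-1} B21 B11^{-1},
    Delta = kappa' B22.1 kappa           (noncentrality of the limiting Ln),

the joint limit of the centered, sqrt(n)-scaled estimators is

    phi2 = sqrt(n)(RSM - beta1) ~ N(-gamma, B11^{-1}),   independent of
    omega = sqrt(n) hat beta2   ~ N(kappa, B22.1^{-1}),
    phi3  = B11^{-1} B12 omega  (so phi3 ~ N(delta, Phi)),
    phi1  = phi2 + phi3         (sqrt(n)(RFM - beta1) ~ N(-mu112, B11.2^{-1})),
    Ln -> omega' B22.1 omega    ~ chi2_{p2}(Delta),

with mu112 the ridge-drift bias of the full model, gamma = mu112 + delta.
The asymptotic distributional bias ADB = lim E[phi*], the (mean-square)
covariance Cov = lim E[phi* phi*'], the quadratic bias AQDB = ADB' B11.2 ADB
and the risk R = tr(Q Cov) of each estimator follow from the Judge–Bock
moment identities for normal vectors times functions of noncentral
chi-square variates; every closed form here is cross-validated against
Monte-Carlo sampling of the joint limit (``mc_reference``).

Note on notation: the inverse-moment symbol E[chi_v^{-2j}(Delta)] means the
j-th inverse moment E[(chi2_v(Delta))^{-j}] — the only reading under which
the central closed forms 1/(v-2) and 1/((v-2)(v-4)) hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import integrate, special, stats

from .lmm import ValidationError

__all__ = [
    "AsymptoticDesign",
    "chi2_cdf",
    "inv_moment",
    "adb_all",
    "aqdb_all",
    "cov_all",
    "risk_all",
    "stein_dominance_condition",
    "mc_reference",
]

ESTIMATORS = ("RFM", "RSM", "RPT", "RSE", "RPS")


# ----------------------------------------------------------------------
# noncentral chi-square building blocks
# ----------------------------------------------------------------------

def chi2_cdf(x: float, v: int, delta: float = 0.0) -> float:
    """H_v(x; Delta): noncentral chi-square CDF (central when Delta = 0)."""
    if v < 1 or int(v) != v:
        raise ValidationError("v must be a positive integer")
    if delta < 0 or x < 0:
        raise ValidationError("x and delta must be >= 0")
    if delta == 0:
        return float(stats.chi2.cdf(x, v))
    return float(stats.ncx2.cdf(x, v, delta))


def _poisson_weights(lam: float):
    if lam == 0.0:
        return np.array([0]), np.array([1.0])
    # tail mass beyond lam + 25 sqrt(lam) + 25 is far below 1e-14
    mmax = int(np.ceil(lam + 25.0 * np.sqrt(lam) + 25.0))
    m = np.arange(mmax + 1)
    logw = -lam + m * np.log(lam) - special.gammaln(m + 1)
    return m, np.exp(logw)


def inv_moment(j: int, v: int, delta: float = 0.0, trunc=None,
               method: str = "series") -> float:
    """E[(chi2_v(Delta))^{-j}], optionally truncated by an indicator.

    ``trunc=(c, side)`` computes E[(chi2)^{-j} 1{chi2 <= c}] for
    ``side="below"`` or the complementary tail for ``side="above"``.
    The default method expands the noncentral law as a Poisson(Delta/2)
    mixture of central chi-squares, for which the (truncated) inverse
    moments are exact: E[(chi2_w)^{-j} 1{<=c}] = 2^{-j} Gamma(w/2-j) /
    Gamma(w/2) * H_{w-2j}(c).  ``method="quad"`` integrates the density
    directly and is kept as an independent cross-check.
    """
    if j < 1 or int(j) != j:
        raise ValidationError("j must be a positive integer")
    if v <= 2 * j:
        raise ValidationError(
            f"inverse moment diverges: need v > 2j (got v={v}, j={j})"
        )
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    c, side = np.inf, None
    if trunc is not None:
        c, side = trunc
        if side not in ("below", "above"):
            raise ValidationError("trunc side must be 'below' or 'above'")
        if not c > 0:
            raise ValidationError("truncation threshold must be > 0")
    if method == "quad":
        dist = stats.chi2(v) if delta == 0 else stats.ncx2(v, delta)
        lo, hi = (0.0, c) if side == "below" else (
            (c, np.inf) if side == "above" else (0.0, np.inf))
        val, _ = integrate.quad(lambda x: x ** (-j) * dist.pdf(x), lo, hi,
                                limit=200)
        return float(val)
    m, w = _poisson_weights(delta / 2.0)
    df = v + 2 * m
    coef = np.exp(special.gammaln(df / 2.0 - j) - special.gammaln(df / 2.0)) / 2.0 ** j
    if side is None:
        frac = 1.0
    elif side == "below":
        frac = stats.chi2.cdf(c, df - 2 * j)
    else:
        frac = stats.chi2.sf(c, df - 2 * j)
    return float(np.sum(w * coef * frac))


# ----------------------------------------------------------------------
# design container
# ----------------------------------------------------------------------

@dataclass(eq=False)
class AsymptoticDesign:
    """The limit quantities entering the bias/risk formulas.

    Parameters
    ----------
    B : (p, p) symmetric positive-definite limit of n^{-1} X'V^{-1}X.
    p1 : size of the non-sparse block (p2 = p - p1).
    kappa : local-alternative vector (length p2).
    lambda0 : ridge drift lim k/n (default 0, the CV-selected-k regime).
    beta : limit coefficient vector (length p); required when lambda0 > 0.
    Q : (p1, p1) PD weight matrix for the risk trace (default identity).
    beta2_offset : the lim(sqrt(n) beta2 - kappa) term in mu112; zero under
        the local alternatives and by default.
    """

    B: np.ndarray
    p1: int
    kappa: np.ndarray
    lambda0: float = 0.0
    beta: np.ndarray | None = None
    Q: np.ndarray | None = None
    beta2_offset: np.ndarray | None = None

    def __post_init__(self):
        self.B = np.asarray(self.B, float)
        self.kappa = np.asarray(self.kappa, float).ravel()
        p = self.B.shape[0]
        if self.B.shape != (p, p) or not np.allclose(self.B, self.B.T, atol=1e-8):
            raise ValidationError("B must be square symmetric")
        if np.linalg.eigvalsh(self.B).min() <= 0:
            raise ValidationError("B must be positive definite")
        if not 1 <= self.p1 < p:
            raise ValidationError("need 1 <= p1 < p")
        if self.kappa.shape[0] != self.p2:
            raise ValidationError("kappa must have length p2")
        if self.lambda0 < 0:
            raise ValidationError("lambda0 must be >= 0")
        if self.lambda0 > 0 and self.beta is None:
            raise ValidationError("beta is required when lambda0 > 0")
        if self.Q is None:
            self.Q = np.eye(self.p1)
        self.Q = np.asarray(self.Q, float)
        if self.Q.shape != (self.p1, self.p1) or np.linalg.eigvalsh(self.Q).min() <= 0:
            raise ValidationError("Q must be p1 x p1 positive definite")

    # -- partitions ----------------------------------------------------
    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def p2(self) -> int:
        return self.p - self.p1

    @cached_property
    def B11(self):
        return self.B[: self.p1, : self.p1]

    @cached_property
    def B12(self):
        return self.B[: self.p1, self.p1:]

    @cached_property
    def B21(self):
        return self.B[self.p1:, : self.p1]

    @cached_property
    def B22(self):
        return self.B[self.p1:, self.p1:]

    @cached_property
    def B11_inv(self):
        return np.linalg.inv(self.B11)

    @cached_property
    def B22_inv(self):
        return np.linalg.inv(self.B22)

    @cached_property
    def B22_1(self):
        """Schur complement B22 - B21 B11^{-1} B12 (PD)."""
        S = self.B22 - self.B21 @ self.B11_inv @ self.B12
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValidationError("B22.1 is not positive definite")
        return S

    @cached_property
    def B11_2(self):
        """Schur complement B11 - B12 B22^{-1} B21 (PD)."""
        S = self.B11 - self.B12 @ self.B22_inv @ self.B21
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValidationError("B11.2 is not positive definite")
        return S

    @cached_property
    def delta(self):
        """delta = B11^{-1} B12 kappa."""
        return self.B11_inv @ self.B12 @ self.kappa

    @cached_property
    def Phi(self):
        return self.B11_inv @ self.B12 @ np.linalg.inv(self.B22_1) \
            @ self.B21 @ self.B11_inv

    @cached_property
    def noncentrality(self):
        """Delta = kappa' B22.1 kappa (noncentrality of the limiting Ln)."""
        return float(self.kappa @ self.B22_1 @ self.kappa)

    @cached_property
    def mu(self):
        """Ridge drift bias mu = -lambda0 B^{-1} beta (zero when lambda0=0)."""
        if self.lambda0 == 0.0 or self.beta is None:
            return np.zeros(self.p)
        return -self.lambda0 * np.linalg.solve(self.B, np.asarray(self.beta, float))

    @cached_property
    def mu112(self):
        """mu11.2 = mu1 - B12 B22^{-1} (beta2_offset - mu2)."""
        mu1, mu2 = self.mu[: self.p1], self.mu[self.p1:]
        off = (np.zeros(self.p2) if self.beta2_offset is None
               else np.asarray(self.beta2_offset, float).ravel())
        return mu1 - self.B12 @ self.B22_inv @ (off - mu2)

    @cached_property
    def gamma(self):
        return self.mu112 + self.delta


# ----------------------------------------------------------------------
# closed-form ADB / covariance / risk
# ----------------------------------------------------------------------

def _moments(design: AsymptoticDesign, alpha: float):
    """All chi-square CDF values and inverse moments the formulas need."""
    p2, D = design.p2, design.noncentrality
    d = p2 - 2
    c = float(stats.chi2.ppf(1.0 - alpha, p2))
    m = {
        "c": c, "d": d,
        "H2c": chi2_cdf(c, p2 + 2, D),
        "H4c": chi2_cdf(c, p2 + 4, D),
    }
    if p2 >= 3:
        m.update(
            H2d=chi2_cdf(d, p2 + 2, D),
            H4d=chi2_cdf(d, p2 + 4, D),
            E2m1=inv_moment(1, p2 + 2, D),
            E2m2=inv_moment(2, p2 + 2, D),
            E4m1=inv_moment(1, p2 + 4, D),
            E4m2=inv_moment(2, p2 + 4, D),
            E2m1_le=inv_moment(1, p2 + 2, D, trunc=(d, "below")),
            E2m2_le=inv_moment(2, p2 + 2, D, trunc=(d, "below")),
            E4m1_le=inv_moment(1, p2 + 4, D, trunc=(d, "below")),
            E4m2_le=inv_moment(2, p2 + 4, D, trunc=(d, "below")),
        )
        # E_j[u] and E_j[u^2] for u(x) = (1 - d/x) 1{x <= d}  (u <= 0)
        m["E2u"] = m["H2d"] - d * m["E2m1_le"]
        m["E2u2"] = m["H2d"] - 2 * d * m["E2m1_le"] + d ** 2 * m["E2m2_le"]
        m["E4u2"] = m["H4d"] - 2 * d * m["E4m1_le"] + d ** 2 * m["E4m2_le"]
    return m


def adb_all(design: AsymptoticDesign, alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Asymptotic distributional bias vectors (length p1) per estimator."""
    m = _moments(design, alpha)
    mu, dv, d = design.mu112, design.delta, m["d"]
    out = {
        "RFM": -mu,
        "RSM": -design.gamma,
        "RPT": -mu - dv * m["H2c"],
    }
    if design.p2 >= 3:
        E2m1_gt = m["E2m1"] - m["E2m1_le"]
        out["RSE"] = -mu - d * dv * m["E2m1"]
        out["RPS"] = -mu - dv * (m["H2d"] + d * E2m1_gt)
    return out


def cov_all(design: AsymptoticDesign, alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Asymptotic mean-square (bias-inclusive) covariance matrices."""
    m = _moments(design, alpha)
    mu, dv, g = design.mu112, design.delta, design.gamma
    Phi, d = design.Phi, m["d"]
    B112_inv = np.linalg.inv(design.B11_2)
    B11_inv = design.B11_inv
    mm = np.outer(mu, mu)
    dd = np.outer(dv, dv)
    md = np.outer(mu, dv) + np.outer(dv, mu)
    gd = np.outer(g, dv) + np.outer(dv, g)
    out = {
        "RFM": B112_inv + mm,
        "RSM": B11_inv + np.outer(g, g),
        "RPT": B112_inv + mm + md * m["H2c"] - Phi * m["H2c"]
               + dd * (2 * m["H2c"] - m["H4c"]),
    }
    if design.p2 >= 3:
        cov_se = (B112_inv + mm + d * md * m["E2m1"]
                  - d * Phi * (2 * m["E2m1"] - d * m["E2m2"])
                  + d * dd * (2 * m["E2m1"] - 2 * m["E4m1"] + d * m["E4m2"]))
        out["RSE"] = cov_se
        out["RPS"] = (cov_se + gd * m["E2u"] - Phi * m["E2u2"] - dd * m["E4u2"])
    return out


def aqdb_all(design: AsymptoticDesign, alpha: float = 0.05) -> dict[str, float]:
    """Quadratic bias ADB' B11.2 ADB per estimator."""
    W = design.B11_2
    return {name: float(b @ W @ b) for name, b in adb_all(design, alpha).items()}


def risk_all(design: AsymptoticDesign, alpha: float = 0.05,
             return_cov: bool = False):
    """Risk tr(Q Cov) per estimator; optionally also the covariances."""
    covs = cov_all(design, alpha)
    risks = {name: float(np.trace(design.Q @ C)) for name, C in covs.items()}
    return (risks, covs) if return_cov else risks


def stein_dominance_condition(design: AsymptoticDesign) -> bool:
    """Sufficient condition for RSE to dominate RFM at every Delta.

    The classical requirement on the shrinkage constant d = p2 - 2 in the
    tr(Q Cov) risk is d <= 2 (tr(Q Phi) / ch_max(Q Phi) - 2): the spectrum of
    Q Phi must be high-dimensional enough relative to d.  Outside this
    condition the Stein estimator can be beaten by the full model at
    intermediate Delta even though p2 >= 3.
    """
    QPhi = design.Q @ design.Phi
    ev = np.linalg.eigvalsh(0.5 * (QPhi + QPhi.T))
    if ev.max() <= 0:
        return False
    return design.p2 - 2 <= 2 * (ev.sum() / ev.max() - 2)


# ----------------------------------------------------------------------
# Monte-Carlo reference: sample the joint limit distribution directly
# ----------------------------------------------------------------------

def mc_reference(design: AsymptoticDesign, n_draws: int = 10 ** 6,
                 rng=None, alpha: float = 0.05,
                 chunk: int = 200_000) -> dict[str, dict]:
    """Estimate ADB and risk by simulating the limit distribution.

    Draws (omega, phi2) from the joint normal limit, forms the five
    estimator limits explicitly from their definitions (indicator and
    shrinkage weights applied to Ln = omega' B22.1 omega), and averages.
    This path shares no code with the closed-form evaluators and serves as
    their correctness oracle; returned values carry Monte-Carlo standard
    errors.
    """
    rng = np.random.default_rng(rng)
    p1, p2 = design.p1, design.p2
    d = p2 - 2
    c = float(stats.chi2.ppf(1.0 - alpha, p2))
    Lo = np.linalg.cholesky(np.linalg.inv(design.B22_1))
    L2 = np.linalg.cholesky(design.B11_inv)
    A = design.B11_inv @ design.B12
    acc_sum = {k: np.zeros(p1) for k in ESTIMATORS}
    acc_sq = {k: np.zeros(p1) for k in ESTIMATORS}
    acc_q = {k: 0.0 for k in ESTIMATORS}
    acc_q2 = {k: 0.0 for k in ESTIMATORS}
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        omega = design.kappa + rng.standard_normal((b, p2)) @ Lo.T
        phi2 = -design.gamma + rng.standard_normal((b, p1)) @ L2.T
        phi3 = omega @ A.T
        phi1 = phi2 + phi3
        Ln = np.einsum("ij,jk,ik->i", omega, design.B22_1, omega)
        draws = {
            "RFM": phi1,
            "RSM": phi2,
            "RPT": phi1 - phi3 * (Ln <= c)[:, None],
        }
        if p2 >= 3:
            w = 1.0 - d / Ln
            draws["RSE"] = phi2 + phi3 * w[:, None]
            draws["RPS"] = phi2 + phi3 * np.maximum(w, 0.0)[:, None]
        for name, phi in draws.items():
            acc_sum[name] += phi.sum(axis=0)
            acc_sq[name] += (phi ** 2).sum(axis=0)
            q = np.einsum("ij,jk,ik->i", phi, design.Q, phi)
            acc_q[name] += q.sum()
            acc_q2[name] += (q ** 2).sum()
        done += b
    out = {}
    for name in draws:
        mean_q = acc_q[name] / n_draws
        var_q = acc_q2[name] / n_draws - mean_q ** 2
        adb = acc_sum[name] / n_draws
        var_adb = acc_sq[name] / n_draws - adb ** 2
        out[name] = {
            "adb": adb,
            "adb_se": np.sqrt(np.maximum(var_adb, 0.0) / n_draws),
            "risk": mean_q,
            "risk_se": float(np.sqrt(max(var_q, 0.0) / n_draws)),
        }
    return out
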