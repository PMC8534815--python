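"""Monte Carlo relative-efficiency study of the five beta1 estimators.

One simulation cell fixes (n, n_i, p1, p2, rho, Delta*, alpha, reps).  Each
replication draws predictors row-wise from N(0, Sigma_x) with unit variances
and equicorrelation rho, random effects a_i ~ N(0, 0.5 I2) on a random
intercept plus a standardized time slope (Z_i = [1, t_j], t_j equally spaced
in [-1, 1]), and unit-variance Gaussian errors.  The coefficient vector has
p1 ones, Delta* in the first sparse coordinate and zeros elsewhere, so
||beta - beta0|| = Delta* measures the violation of the restriction
beta2 = 0.  Estimation uses the true variance components by default (the
theory conditions on V), with k chosen per replication by subject-level CV.

Performance is summarized by MSE over the beta1 block and by the relative
mean-squared efficiency RMSE(est) = MSE(RFM) / MSE(est): values above one
favor the estimator over the full-model ridge fit.  The condition number
index CNI (largest/smallest eigenvalue of X'V^{-1}X) flags multicollinearity
when it exceeds 30; it is +inf (flagged) whenever p > N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lmm import (
    LongitudinalDataset,
    MarginalCovariance,
    ValidationError,
    VarianceStructure,
    build_marginal_covariance,
    fit_variance_components,
)
from .ridge import RidgeConfig, ridge_full, ridge_full_beta1, ridge_submodel, select_k
from .shrinkage import combine_all, lrt_statistic

__all__ = [
    "SimulationCell",
    "SimulationReport",
    "make_beta",
    "generate_dataset",
    "cni",
    "run_cell",
    "sweep",
    "plot_rmse",
]

CNI_FLAG_THRESHOLD = 30.0


@dataclass
class SimulationCell:
    """One (n, n_i, p1, p2, rho, Delta*) Monte Carlo configuration."""

    n: int = 60
    ni: int = 6
    p1: int = 5
    p2: int = 40
    rho: float = 0.3
    delta_star: float = 0.0
    reps: int = 1000
    alpha: float = 0.05
    seed: int = 0
    k_policy: str = "per_rep"
    k_fixed: float = 1.0
    k_grid: np.ndarray = field(default_factory=lambda: np.logspace(-4, 2, 50))
    cv_folds: int = 5
    inner_inverse: str = "ridge"
    ln_fit: str = "ridge"
    variance_components: str = "known"
    baselines: tuple = ()
    cni_reps: int | None = None   # None: every rep when p <= 300, else 5

    def __post_init__(self):
        if self.n < 2 or self.ni < 1 or self.reps < 1:
            raise ValidationError("need n >= 2, ni >= 1, reps >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must be in [0, 1)")
        if self.delta_star < 0:
            raise ValidationError("delta_star must be >= 0")
        if self.k_policy not in ("per_rep", "fixed"):
            raise ValidationError("k_policy must be 'per_rep' or 'fixed'")
        self.k_grid = np.asarray(self.k_grid, float)

    @property
    def p(self) -> int:
        return self.p1 + self.p2


@dataclass
class SimulationReport:
    """Per-estimator MSE/RMSE with Monte-Carlo standard errors for one cell."""

    cell: SimulationCell
    mse: dict
    mse_se: dict
    rmse: dict
    rmse_se: dict
    cni_mean: float
    cni_sd: float
    multicollinear: bool
    n_failed: int
    ks: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        c = self.cell
        rows = []
        for name in self.mse:
            rows.append({
                "n": c.n, "ni": c.ni, "p1": c.p1, "p2": c.p2, "rho": c.rho,
                "delta_star": c.delta_star, "CNI_mean": self.cni_mean,
                "estimator": name, "MSE": self.mse[name],
                "RMSE": self.rmse[name], "MC_SE": self.rmse_se[name],
                "reps": c.reps, "seed": c.seed,
            })
        return pd.DataFrame(rows)


def make_beta(p1: int, p2: int, delta_star: float) -> np.ndarray:
    """p1 ones, Delta* in the first sparse slot, zeros after: ||b-b0||=Delta*."""
    if p1 < 1 or p2 < 1 or delta_star < 0:
        raise ValidationError("need p1 >= 1, p2 >= 1, delta_star >= 0")
    beta = np.zeros(p1 + p2)
    beta[:p1] = 1.0
    beta[p1] = delta_star
    return beta


def _z_block(ni: int) -> np.ndarray:
    """Random intercept + equally spaced time slope on [-1, 1]."""
    t = np.linspace(-1.0, 1.0, ni) if ni > 1 else np.zeros(1)
    return np.column_stack([np.ones(ni), t])


def true_variance(q: int = 2, g: float = 0.5, sigma2: float = 1.0) -> VarianceStructure:
    """The generating variance components: G = g I_q, sigma^2."""
    return VarianceStructure(g * np.eye(q), sigma2)


def generate_dataset(cell: SimulationCell, rep_seed: int):
    """Draw one replication: (dataset, true beta, true variance structure)."""
    rng = np.random.default_rng([cell.seed & 0x7FFFFFFF, rep_seed])
    n, ni, p = cell.n, cell.ni, cell.p
    N = n * ni
    beta = make_beta(cell.p1, cell.p2, cell.delta_star)
    # equicorrelated rows: x = sqrt(rho) g 1 + sqrt(1-rho) e
    e = rng.standard_normal((N, p))
    gshare = rng.standard_normal((N, 1))
    X = math.sqrt(cell.rho) * gshare + math.sqrt(1.0 - cell.rho) * e
    vs = true_variance()
    Zb = _z_block(ni)
    Z = np.tile(Zb, (n, 1))
    a = rng.standard_normal((n, 2)) * math.sqrt(0.5)
    eps = rng.standard_normal(N)
    y = X @ beta + np.einsum("ij,sj->si", Zb, a).reshape(N) \
        + eps * math.sqrt(vs.sigma2)
    groups = np.repeat(np.arange(n), ni)
    data = LongitudinalDataset(y, X, Z, groups,
                               x1_idx=np.arange(cell.p1),
                               x2_idx=np.arange(cell.p1, p))
    return data, beta, vs


def cni(data: LongitudinalDataset, V: MarginalCovariance):
    """Condition number index of X'V^{-1}X; (+inf, True) when singular."""
    if data.p > data.N:
        return math.inf, True
    sv = np.linalg.svd(V.whiten(data.X), compute_uv=False)
    smin = sv[-1] ** 2
    if smin <= sv[0] ** 2 * 1e-14:
        return math.inf, True
    ratio = float(sv[0] ** 2 / smin)
    return ratio, ratio > CNI_FLAG_THRESHOLD


def _estimate_all(data, V, cell, cfg):
    """One replication's five estimates of beta1 (dict name -> vector)."""
    if cell.k_policy == "per_rep":
        k = select_k(data, V, cfg)
    else:
        k = cell.k_fixed
    rsm = ridge_submodel(data, V, k)
    rfm = ridge_full_beta1(data, V, k, inner_inverse=cell.inner_inverse)
    if cell.ln_fit == "gls" and data.p <= data.N:
        beta_full = ridge_full(data, V, 0.0)
        sub = ridge_submodel(data, V, 0.0)
    else:
        beta_full = ridge_full(data, V, k)
        sub = rsm
    beta_sub = np.zeros(data.p)
    beta_sub[data.x1_idx] = sub.beta1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        test = lrt_statistic(data, V, beta_full, beta_sub, alpha=cell.alpha)
    ests = combine_all(rfm, rsm, test)
    if "RSE" not in ests:       # Ln == 0: shrinkage weight floors to the sub-model
        ests["RSE"] = rsm
        ests["RPS"] = rsm
    out = {name: ests[name].beta1 for name in ("RFM", "RSM", "RPT", "RSE", "RPS")}
    if cell.baselines:
        from .baselines import alasso_fit, lasso_fit, whiten
        w = whiten(data, V)
        rng_seed = (cell.seed ^ 0x5D) & 0x7FFFFFFF
        if "lasso" in cell.baselines:
            out["LASSO"] = lasso_fit(w, folds=10, seed=rng_seed).beta1
        if "alasso" in cell.baselines:
            pilot = ridge_full(data, V, k if k > 0 else 1e-4)
            out["aLASSO"] = alasso_fit(w, pilot, folds=10, seed=rng_seed).beta1
    return out, k, test.Ln


def run_cell(cell: SimulationCell) -> SimulationReport:
    """Run one cell: generate, estimate, accumulate MSE/RMSE/CNI."""
    beta1_true = make_beta(cell.p1, cell.p2, cell.delta_star)[: cell.p1]
    cfg = RidgeConfig(k=cell.k_fixed, k_grid=cell.k_grid,
                      cv_folds=cell.cv_folds, cv_seed=cell.seed & 0x7FFFFFFF)
    sq_err: dict[str, list] = {}
    ks, cnis = [], []
    n_cni = cell.cni_reps if cell.cni_reps is not None else (
        cell.reps if cell.p <= 300 else 5)
    failures = 0
    vs_known = true_variance()
    for rep in range(cell.reps):
        try:
            data, _, _ = generate_dataset(cell, rep)
            if cell.variance_components == "ml":
                vs = fit_variance_components(data)
            else:
                vs = vs_known
            V = build_marginal_covariance(data, vs)
            if rep < n_cni:
                cnis.append(cni(data, V)[0])
            ests, k, _ = _estimate_all(data, V, cell, cfg)
            ks.append(k)
            for name, b1 in ests.items():
                sq_err.setdefault(name, []).append(
                    float(np.sum((b1 - beta1_true) ** 2)))
        except Exception:
            failures += 1
            if failures > max(1, cell.reps // 100):
                raise
    mse, mse_se, rmse, rmse_se = {}, {}, {}, {}
    err_fm = np.asarray(sq_err["RFM"])
    R = len(err_fm)
    for name, errs in sq_err.items():
        errs = np.asarray(errs)
        mse[name] = float(errs.mean())
        mse_se[name] = float(errs.std(ddof=1) / math.sqrt(R))
        rmse[name] = float(err_fm.mean() / errs.mean())
        # delta-method SE of the MSE ratio from the paired per-rep errors
        ratio = rmse[name]
        cov = np.cov(err_fm, errs)
        var_ratio = (cov[0, 0] - 2 * ratio * cov[0, 1] + ratio ** 2 * cov[1, 1]) \
            / (errs.mean() ** 2 * R)
        rmse_se[name] = float(math.sqrt(max(var_ratio, 0.0)))
    cnis = np.asarray(cnis, float)
    finite = cnis[np.isfinite(cnis)]
    cni_mean = float(cnis.mean()) if len(cnis) else math.nan
    cni_sd = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
    return SimulationReport(cell=cell, mse=mse, mse_se=mse_se, rmse=rmse,
                            rmse_se=rmse_se, cni_mean=cni_mean, cni_sd=cni_sd,
                            multicollinear=bool(np.any(~np.isfinite(cnis))
                                                or (len(finite) and
                                                    finite.mean() > CNI_FLAG_THRESHOLD)),
                            n_failed=failures, ks=np.asarray(ks))


def sweep(cells, n_jobs: int = 1, master_seed: int | None = None) -> pd.DataFrame:
    """Run a grid of cells and return one tidy long-format table.

    With ``master_seed`` set, each cell's seed is derived deterministically
    from (master_seed, a digest of the cell's parameters), so per-cell
    results do not depend on grid ordering or parallel scheduling.
    """
    import hashlib
    import json

    cells = list(cells)
    if master_seed is not None:
        def _derive(c):
            payload = {k: v for k, v in vars(c).items() if k != "seed"}
            digest = hashlib.sha256(
                json.dumps(payload, sort_keys=True, default=str).encode()
            ).digest()
            key = int.from_bytes(digest[:4], "big")
            return replace(c, seed=int(np.random.SeedSequence(
                [master_seed, key]).generate_state(1)[0] & 0x7FFFFFFF))
        cells = [_derive(c) for c in cells]
    if not cells:
        return pd.DataFrame(columns=["n", "ni", "p1", "p2", "rho", "delta_star",
                                     "CNI_mean", "estimator", "MSE", "RMSE",
                                     "MC_SE", "reps", "seed"])
    if n_jobs != 1:
        from joblib import Parallel, delayed
        reports = Parallel(n_jobs=n_jobs)(delayed(run_cell)(c) for c in cells)
    else:
        reports = [run_cell(c) for c in cells]
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)


def plot_rmse(table: pd.DataFrame, ax=None):
    """Basic RMSE-vs-Delta* line plot, one line per estimator."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, grp in table.groupby("estimator"):
        grp = grp.sort_values("delta_star")
        ax.plot(grp["delta_star"], grp["RMSE"], marker="o", label=name)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"$\Delta^*$")
    ax.set_ylabel("RMSE (MSE(RFM)/MSE)")
    ax.legend()
    return ax
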