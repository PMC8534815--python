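"""Long-format CSV input, report output, and the cluster-bootstrap RPE.

The long table holds one row per measurement occasion with a subject id
column, the response, the fixed-effect covariates and the random-effect
design columns.  A schema mapping names the columns:

    subject: id          response: y
    x1: [fitness, fat]   x2: [smoke, gender, time]   z: [const, time]

The sub-model partition (x1 vs x2) is supplied by the user; selecting it is
outside this package's scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import (
    LongitudinalDataset,
    MarginalCovariance,
    ValidationError,
    build_marginal_covariance,
    fit_variance_components,
)
from .ridge import RidgeConfig, ridge_full, ridge_full_beta1, ridge_submodel, select_k
from .shrinkage import combine_all, lrt_statistic

__all__ = ["read_long_csv", "write_long_csv", "write_report", "bootstrap_rpe",
           "fit_all_estimators"]

REPORT_COLUMNS = ["n", "ni", "p1", "p2", "rho", "delta_star", "CNI_mean",
                  "estimator", "MSE", "RMSE", "MC_SE", "reps", "seed"]


def _schema_columns(schema: dict):
    subject = schema["subject"]
    response = schema["response"]
    x1 = list(schema.get("x1", []))
    x2 = list(schema.get("x2", []))
    z = list(schema.get("z", []))
    if not x1:
        raise ValidationError("schema must name at least one x1 column")
    return subject, response, x1, x2, z


def read_long_csv(path, schema: dict) -> LongitudinalDataset:
    """Read a long-format CSV into a LongitudinalDataset.

    Rows are grouped by the subject column preserving within-subject order;
    missing values in any required column raise an error naming the rows.
    A ``z`` entry ``"const"`` (no matching column) becomes an intercept.
    """
    subject, response, x1, x2, z = _schema_columns(schema)
    df = pd.read_csv(path)
    needed = [subject, response, *x1, *x2, *[c for c in z if c in df.columns]]
    missing = [c for c in [subject, response, *x1, *x2] if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    na_rows = df.index[df[needed].isna().any(axis=1)].tolist()
    if na_rows:
        raise ValidationError(f"missing values in required columns at rows {na_rows}")
    # stable-group rows by subject (first-appearance order)
    df = df.loc[df[subject].map(
        {s: i for i, s in enumerate(df[subject].drop_duplicates())}
    ).sort_values(kind="stable").index]
    X = df[x1 + x2].to_numpy(float)
    zcols = []
    for c in z:
        if c in df.columns:
            zcols.append(df[c].to_numpy(float))
        elif c == "const":
            zcols.append(np.ones(len(df)))
        else:
            raise ValidationError(f"unknown z column {c!r}")
    Z = np.column_stack(zcols) if zcols else np.ones((len(df), 1))
    return LongitudinalDataset(
        df[response].to_numpy(float), X, Z, df[subject].to_numpy(),
        x1_idx=np.arange(len(x1)), x2_idx=np.arange(len(x1), len(x1) + len(x2)))


def write_long_csv(data: LongitudinalDataset, path, schema: dict) -> None:
    """Inverse of read_long_csv (for round-trips and synthetic exports)."""
    subject, response, x1, x2, z = _schema_columns(schema)
    df = pd.DataFrame({subject: data.groups, response: data.y})
    for j, c in enumerate(x1 + x2):
        df[c] = data.X[:, j]
    for j, c in enumerate(z):
        if c != "const":
            df[c] = data.Z[:, j]
    df.to_csv(path, index=False)


def write_report(report: pd.DataFrame, path, precision: int | str = 4) -> None:
    """Write a tidy report as TSV with a fixed column order."""
    cols = [c for c in REPORT_COLUMNS if c in report.columns] \
        + [c for c in report.columns if c not in REPORT_COLUMNS]
    out = report[cols]
    if precision == "full":
        out.to_csv(path, sep="\t", index=False)
    else:
        out.to_csv(path, sep="\t", index=False,
                   float_format=f"%.{int(precision)}g")


def fit_all_estimators(data: LongitudinalDataset, V: MarginalCovariance,
                       k: float | None = None, alpha: float = 0.05,
                       cfg: RidgeConfig | None = None, cv_seed: int = 0,
                       inner_inverse: str = "ridge"):
    """All five beta1 estimates on one dataset; k by CV unless given."""
    cfg = cfg or RidgeConfig(cv_seed=cv_seed)
    if k is None:
        k = select_k(data, V, cfg)
    rsm = ridge_submodel(data, V, k)
    if data.p2 >= 1:
        rfm = ridge_full_beta1(data, V, k, inner_inverse=inner_inverse)
        beta_full = ridge_full(data, V, k) if data.p <= data.N \
            else ridge_full(data, V, max(k, 1e-8))
        beta_sub = np.zeros(data.p)
        beta_sub[data.x1_idx] = rsm.beta1
        test = lrt_statistic(data, V, beta_full, beta_sub, alpha=alpha)
        ests = combine_all(rfm, rsm, test)
    else:
        ests, test = {"RFM": rsm, "RSM": rsm}, None
    return ests, float(k), test


def bootstrap_rpe(data: LongitudinalDataset, B: int = 1000, alpha: float = 0.05,
                  seed: int = 0, k: float | None = None,
                  variance_components: str = "ml",
                  identity_resample: bool = False) -> pd.DataFrame:
    """Cluster-bootstrap relative prediction errors against the full model.

    Resamples whole subjects with replacement B times; on each resample all
    estimators are computed and scored by the mean squared prediction error
    MSPE = (Y - X1 b1)'(Y - X1 b1) on the resample.  Reports the mean RPE
    per estimator, RPE = MSPE(est) / MSPE(RFM), so RPE(RFM) = 1 and values
    below one favor the estimator.  ``identity_resample`` forces the
    original sample (degenerate bootstrap, B = 1).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if data.p1 < 1 or data.p2 < 1:
        raise ValidationError("bootstrap_rpe needs p1 >= 1 and p2 >= 1")
    rng = np.random.default_rng(seed)
    blocks = [(data.y[s], data.X[s], data.Z[s]) for s in data.subject_slices()]
    if variance_components == "ml":
        vs = fit_variance_components(data)
    else:
        vs = variance_components  # a VarianceStructure passed directly
    if identity_resample:
        B = 1
    rpe_acc: dict[str, list] = {}
    for b in range(B):
        idx = (np.arange(data.n) if identity_resample
               else rng.integers(0, data.n, data.n))
        boot = LongitudinalDataset.from_blocks(
            [blocks[i] for i in idx], data.x1_idx, data.x2_idx)
        V = build_marginal_covariance(boot, vs)
        ests, _, _ = fit_all_estimators(boot, V, k=k, alpha=alpha,
                                        cv_seed=int(rng.integers(2 ** 31)))
        X1 = boot.X1
        mspe = {}
        for name, est in ests.items():
            r = boot.y - X1 @ est.beta1
            mspe[name] = r @ r
        for name in mspe:
            rpe_acc.setdefault(name, []).append(mspe[name] / mspe["RFM"])
    rows = [{"estimator": name,
             "RPE": float(np.mean(v)),
             "RPE_se": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
             "B": len(v)}
            for name, v in rpe_acc.items()]
    return pd.DataFrame(rows)
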