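import numpy as np
import pytest

from shrinkridge import (
    LongitudinalDataset,
    VarianceStructure,
    build_marginal_covariance,
)


def make_dataset(rng, n=4, ni=3, p1=2, p2=3, q=2, beta=None, g=0.5, sigma2=1.0,
                 rho=0.0):
    """Small random longitudinal instance drawn from the generating model."""
    p = p1 + p2
    N = n * ni
    if beta is None:
        beta = np.concatenate([np.ones(p1), np.zeros(p2)])
    shared = rng.standard_normal((N, 1))
    X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((N, p))
    t = np.linspace(-1, 1, ni) if ni > 1 else np.zeros(1)
    Zb = np.column_stack([np.ones(ni), t])[:, :q]
    Z = np.tile(Zb, (n, 1))
    a = rng.standard_normal((n, q)) * np.sqrt(g)
    y = X @ beta + (Z * np.repeat(a, ni, axis=0)).sum(axis=1) \
        + rng.standard_normal(N) * np.sqrt(sigma2)
    data = LongitudinalDataset(y, X, Z, np.repeat(np.arange(n), ni),
                               x1_idx=np.arange(p1),
                               x2_idx=np.arange(p1, p))
    vs = VarianceStructure(g * np.eye(q), sigma2)
    return data, np.asarray(beta, float), vs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_problem(rng):
    """A (data, beta, vs, V) tuple with p < N and well-conditioned design."""
    data, beta, vs = make_dataset(rng, n=6, ni=4, p1=2, p2=3)
    return data, beta, vs, build_marginal_covariance(data, vs)


def dense_V(data, vs):
    """Dense N x N marginal covariance assembled by direct block arithmetic."""
    import scipy.linalg as sla

    blocks = [Z @ vs.G @ Z.T + vs.sigma2 * np.eye(len(y))
              for y, X, Z in data.iter_subjects()]
    return sla.block_diag(*blocks)


def dominance_design(rng, p1=6, p2=4, delta=None, jitter=0.05):
    """Random design inside the Stein-dominance domain (near-isotropic Phi).

    B has aI / bI diagonal blocks coupled through c sqrt(ab) U with U
    column-orthonormal, plus a small Wishart jitter; resampled until the
    tr/ch_max dominance condition holds.
    """
    from shrinkridge import AsymptoticDesign
    from shrinkridge.asymptotics import stein_dominance_condition

    p = p1 + p2
    while True:
        a, b = rng.uniform(0.5, 2.0, 2)
        c = rng.uniform(0.2, 0.6)
        U = np.linalg.qr(rng.standard_normal((p1, p2)))[0]
        B = np.zeros((p, p))
        B[:p1, :p1] = a * np.eye(p1)
        B[p1:, p1:] = b * np.eye(p2)
        B[:p1, p1:] = c * np.sqrt(a * b) * U
        B[p1:, :p1] = B[:p1, p1:].T
        W = rng.standard_normal((p, p))
        B = B + jitter * (W @ W.T) / p
        kappa = rng.standard_normal(p2)
        des = AsymptoticDesign(B, p1, kappa)
        if delta is not None:
            kappa = (np.zeros(p2) if delta == 0
                     else kappa * np.sqrt(delta / des.noncentrality))
            des = AsymptoticDesign(B, p1, kappa)
        if stein_dominance_condition(des):
            return des


def random_design(rng, p1=3, p2=5, delta=None, lambda0=0.0):
    """Random valid AsymptoticDesign, optionally scaled to a target Delta."""
    from shrinkridge import AsymptoticDesign

    p = p1 + p2
    A = rng.standard_normal((p, p))
    B = A @ A.T + p * np.eye(p)
    kappa = rng.standard_normal(p2)
    beta = rng.standard_normal(p) if lambda0 > 0 else None
    base = AsymptoticDesign(B, p1, kappa, lambda0=lambda0, beta=beta)
    if delta is not None:
        kappa = (np.zeros(p2) if delta == 0
                 else kappa * np.sqrt(delta / base.noncentrality))
    return AsymptoticDesign(B, p1, kappa, lambda0=lambda0, beta=beta)
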