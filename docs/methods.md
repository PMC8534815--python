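# Methods

## Model and estimators

The data are longitudinal: subject *i* contributes *nᵢ* rows, `Yᵢ = Xᵢβ +
Zᵢaᵢ + εᵢ` with Gaussian random effects `aᵢ ~ N(0, G)` and errors
`εᵢ ~ N(0, σ²I)`, independent across subjects. All estimation works in the
marginal model `Y ~ N(Xβ, V)`, `V = blockdiag(ZᵢGZᵢᵀ + σ²I)`. Every
V⁻¹-weighted product is computed blockwise through the per-subject Cholesky
factor `Vᵢ = LᵢLᵢᵀ` ("whitening"); the full N×N covariance is never formed,
and subjects sharing the same (nᵢ, Zᵢ) share one factor. Blocks are
required to be positive definite with tolerance 1e-10 on the smallest
eigenvalue.

The fixed-effect columns are partitioned by the user (or the simulation
design) into a target block X₁ (p₁ columns) and a sparse block X₂ (p₂
columns) whose coefficients are suspected to be zero. The five estimators
of β₁ are the full-model ridge estimator (RFM; sparse block projected out
in the V⁻¹ metric), the sub-model ridge estimator (RSM; sparse block
dropped), and their pretest (RPT), Stein (RSE, p₂ ≥ 3) and positive-part
Stein (RPS) combinations driven by the likelihood-ratio statistic Ln.
Equations are in the README; implementation notes:

- **Ridge solves.** `(XᵀV⁻¹X + kI)β = XᵀV⁻¹Y` is solved primally for
  p ≤ N and through the algebraically identical dual (N×N) system for
  p > N. At k = 0 the solve is least squares on the whitened design and a
  rank-deficiency error directs the caller to the ridge path.
- **Projection for RFM.** `M_{X₂} = I − V^{-1/2}X₂(X₂ᵀV⁻¹X₂)⁻¹X₂ᵀV^{-1/2}`
  requires an inner inverse that does not exist when rank(X₂ᵀV⁻¹X₂) < p₂
  (always for p₂ ≥ N). Default policy `ridge`: replace it by
  `(X₂ᵀV⁻¹X₂ + kI)⁻¹` with the same tuning k (computed via the Woodbury
  identity as an N×N solve when p₂ > N); this keeps a single tuning
  parameter and reduces to the exact inverse at k = 0. Alternative
  `pinv`: Moore–Penrose, i.e. projection onto the exact column span.
- **Choosing k.** Subject-level K-fold cross-validation (default 5 folds,
  50 log-spaced grid points in [1e-4, 1e2]): fit the full ridge model on
  the training subjects, score the squared prediction error of the
  marginal mean Xβ̂ on held-out subjects on the raw response scale, take
  the grid argmin, breaking ties toward the smallest k (less bias).
  Selection is deterministic given the CV seed. The simulation engine
  re-selects k each replication (`k_policy="per_rep"`); a fixed k is
  available.
- **Ln.** `Ln = 2[ℓ(β̂_full) − ℓ(β̂_sub)]` where ℓ is the marginal Gaussian
  log-likelihood at plug-in coefficients with the variance components held
  fixed, and the sub-model vector is zero-padded on X₂. With ridge
  plug-ins (not MLEs) Ln can be marginally negative; it is clipped at zero
  with a warning (`strict_ln` raises instead). With k → 0 and known V, Ln
  is exactly the GLS likelihood-ratio statistic and is χ²_{p₂} under the
  restriction — the calibration the test suite verifies at n = 400.
- **Variance components.** The theory conditions on V, so the simulation
  plugs in the generating (G, σ²) by default (`variance_components:
  known|ml`). For real data, maximum likelihood (not REML, keeping Ln a
  plain likelihood ratio): Nelder–Mead on the profile likelihood in a
  log-Cholesky parameterization (G stays PSD by construction, σ² > 0 by
  the log link), β profiled out by GLS at each evaluation. Estimates with
  singular Ĝ or vanishing σ̂² are flagged as boundary cases.

## Asymptotic bias and risk

Under local alternatives `β₂ = κ/√n`, with `B = lim n⁻¹XᵀV⁻¹X` partitioned
conformably, the joint limit used throughout is

- `ω = √n β̂₂ ~ N(κ, B₂₂.₁⁻¹)` with `B₂₂.₁ = B₂₂ − B₂₁B₁₁⁻¹B₁₂`,
- `φ₂ = √n(RSM − β₁) ~ N(−γ, B₁₁⁻¹)` independent of ω,
- `φ₃ = B₁₁⁻¹B₁₂ω`, `φ₁ = φ₂ + φ₃ = √n(RFM − β₁)`,
- `Ln → ωᵀB₂₂.₁ω ~ χ²_{p₂}(Δ)` with **Δ = κᵀB₂₂.₁κ**.

The bias (ADB), quadratic bias (AQDB = ADBᵀB₁₁.₂ADB), mean-square
covariance and risk `tr(Q·Cov)` of all five estimators follow from the
Judge–Bock identities `E[ω g(Ln)] = κ E[g(χ²_{p₂+2}(Δ))]` and
`E[ωωᵀ g(Ln)] = B₂₂.₁⁻¹E[g(χ²_{p₂+2})] + κκᵀE[g(χ²_{p₂+4})]`. The
positive-part corrections use `u(x) = (1 − (p₂−2)/x)·1{x ≤ p₂−2}`:

```
Cov(RPS) = Cov(RSE) + (γδᵀ + δγᵀ)E₂[u] − Φ E₂[u²] − δδᵀ E₄[u²]
```

with `δ = B₁₁⁻¹B₁₂κ`, `Φ = B₁₁⁻¹B₁₂B₂₂.₁⁻¹B₂₁B₁₁⁻¹` and `E_j[·]` the
expectation under χ²_{p₂+j}(Δ). Because these long expressions are easy
to mistranscribe, every closed form is cross-validated against
`mc_reference`, which samples (ω, φ₂) from the joint limit directly and
averages the estimator definitions — the decisive correctness check, run
at 10⁶ draws in the acceptance suite.

Notational conventions adopted (documented because the field's notation is
inconsistent): `E(χ_v^{-2j}(Δ))` denotes the j-th inverse moment
`E[(χ²_v(Δ))^{-j}]` — the only reading under which the central closed
forms `1/(v−2)` and `1/((v−2)(v−4))` hold — and the noncentrality is
`Δ = κᵀB₂₂.₁κ`, the value under which the limiting Ln, the Proposition
sampler and the moment identities are mutually consistent. The ridge
drift λ₀ = lim k/n enters as `μ = −λ₀B⁻¹β` with
`μ₁₁.₂ = μ₁ + B₁₂B₂₂⁻¹μ₂` (the `√nβ₂ − κ` term vanishes under the local
alternatives; a caller override exists). λ₀ defaults to 0, the regime of
CV-selected k growing slower than n; the sampler-based validation is only
claimed there, because how the ridge drift propagates into the limit of
ω is not settled.

Inverse moments, truncated or not, are evaluated by the exact
Poisson(Δ/2)-mixture series over central χ² inverse moments
(`E[(χ²_w)^{-j}1{≤c}] = 2^{-j}Γ(w/2−j)/Γ(w/2)·H_{w−2j}(c)`), accurate to
~1e-12 with a deterministic tail cutoff; adaptive quadrature of the
noncentral density is retained as an independent cross-check
(`method="quad"`). Moments require v > 2j, hence p₂ ≥ 3 for the shrinkage
estimators.

**A limitation worth knowing.** The claim "R(RSE) ≤ R(RFM) for all Δ" is
not true for arbitrary positive-definite B: Stein dominance in the
tr(Q·Cov) risk requires the classical spectral condition
`p₂ − 2 ≤ 2(tr(QΦ)/ch_max(QΦ) − 2)` (exposed as
`stein_dominance_condition`). Outside it, RSE can lose to RFM by a small
margin at intermediate Δ — our formulas, validated by the sampler,
exhibit this. `R(RPS) ≤ R(RSE)` needs no condition. The dominance tests
therefore draw random designs satisfying the condition (a near-isotropic
Φ family); the positive-part ordering is tested on generic designs.

## Synthetic-data design

One simulation cell fixes (n, nᵢ, p₁, p₂, ρ, Δ*, α, reps). Defaults are
the study conditions: predictors drawn rowwise i.i.d. N(0, Σx) with unit
variances and equicorrelation ρ ∈ {0.3, 0.7, 0.9}; `β` has p₁ ones, Δ* in
the first sparse coordinate and zeros elsewhere (so ‖β − β₀‖ = Δ*);
`G = 0.5·I₂`, σ² = 1; n ∈ {60, 100}; α = 0.05. Where the design is
under-determined the package fixes: nᵢ = 6 visits (a common longitudinal
panel length, recorded in every report), random effects on an intercept
plus a standardized time slope `Zᵢ = [1, tⱼ]`, tⱼ equally spaced in
[−1, 1], and zero predictor means. Replications are seeded as
(cell seed, rep index) through a SeedSequence, so every dataset is
byte-reproducible and cells are order-independent under a master seed.

Per replication: build V from the true (G, σ²), select k by CV, compute
all five β₁ estimates (plus optional LASSO/aLASSO on the whitened
design), and accumulate squared error on the β₁ block — the quantity all
five estimators target. Reports carry MSE, RMSE = MSE(RFM)/MSE(est) with
a delta-method Monte-Carlo SE for the paired ratio, the mean condition
number index CNI = λ_max/λ_min of XᵀV⁻¹X (+∞ sentinel and a
multicollinearity flag when p > N or CNI > 30), and the count of failed
replications (a cell aborts beyond 1% failures).

What the generator does **not** emulate: non-Gaussian or heteroscedastic
errors, unbalanced panels, missingness, serial correlation beyond the
random effects, non-equicorrelated predictor dependence, and measured
(non-random) covariates. Passing tests therefore certify the estimators'
behavior under the idealized design, not robustness to those departures.
Because the published efficiency tables depend on within-subject layout
and tuning details that the design leaves open, the reproduction checks
assert direction and approximate magnitude (a factor-two band) rather
than printed-digit agreement; with p₂ ≥ N the projected full-model
estimator additionally depends on the inner-inverse policy, and relative
efficiencies there are policy-dependent.

## Baselines and bootstrap

LASSO and adaptive LASSO are fit with coordinate descent (scikit-learn)
on the V-whitened stacked design — the transform that makes the
comparison with the ridge-GLS estimators fair — with the penalty chosen
by subject-level 10-fold CV at the minimum mean CV error over a 50-point
log-spaced path. The adaptive weights are `1/|pilot|` with the CV-ridge
full-model fit as pilot, implemented by column rescaling. Raw-scale
fitting is available by whitening with V = I.

For real long-format data the user supplies the X₁/X₂ partition (column
selection procedures are out of scope). `bootstrap_rpe` resamples whole
subjects with replacement (cluster bootstrap), recomputes every estimator
on each resample, scores the mean squared prediction error
`(Y − X₁β̂₁)ᵀ(Y − X₁β̂₁)` on the resample, and reports the mean relative
prediction error against RFM (RPE < 1 favors the estimator; RPE(RFM) ≡ 1).

## Problem sizes used in the shipped checks

Unit and property tests run on deliberately small instances (n ≤ 60).
The end-to-end suite uses 10⁶-draw sampler validation of the asymptotic
formulas, 2000 replications at n = 400 for the χ² calibration of Ln, 400
replications per simulation cell, and 10 ML fits at n = 200 for
variance-component recovery. The acceptance script uses 1000
replications per standard cell and 300 for the p₂ = 1000 cell — sizes
chosen to put the Monte-Carlo SE of each reported RMSE well inside the
bands being checked while keeping a single-core run in minutes.
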