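# Methods

`hvarnet` implements a hierarchical Bayesian vector autoregressive (VAR)
model for multi-subject, multi-condition effective connectivity, together
with Granger-causality network construction, the nuisance preprocessing the
model expects, and a synthetic-study generator used as the test harness.
This note records the model, the numerical choices, and the design
decisions taken where more than one reasonable reading existed.

## Model

For subject `s` with `R` ROI-mean time series `Y(t)` and binary condition
indicators `W_c(t)` (one condition active per scan), the condition-switching
VAR(K) is

    Y(t) = Σ_k Σ_c W_c(t) Φ_{c,k}^{(s)} Y(t−k) + e(t),
    e(t) ~ N(0, Σ_τ),  Σ_τ = diag(1/τ_1 … 1/τ_R),

with `Φ_{c,k}^{(s)}(target, source)` the influence of the past value of
*source* on the current value of *target*, and the noise covariance shared
across subjects. The indicator switch means the condition presented at
time `t` selects the coefficients used to predict `Y(t)`; lagged values
from the previous condition block enter the new block's coefficients
immediately (the literal reading of the switching model), and no
hemodynamic-delay shift is applied to the indicators.

Subject coefficients decompose as `φ^{(s)} = φ + ξ^{(s)}` with group-level
coefficients `φ` and subject deviations `ξ^{(s)} ~ N(0, D)`,
`D = diag(1/d_j)` quantifying between-subject variability per coefficient.
With `G` groups, `φ` is the concatenation `[φ_Grp1 … φ_GrpG]` and each
subject's fixed-effects design is expanded by `A^{(s)} = [0 … I_q … 0]`
into its group's slot; each group has its own `D`.

The group coefficients carry a Bayesian elastic-net prior:

    φ_j | τ, α_j, λ₂ ~ N(0, 1/(τ_h(j) (α_j + λ₂))),
    α_j | λ₂, γ ~ (α_j/(α_j+λ₂))^{1/2} InvGamma(1, γ/2),
    λ₂ ~ Gamma(r_λ, h_λ),  γ ~ Gamma(r_γ, h_γ),
    τ_r ~ Gamma(r_τ, h_τ),  d_j ~ Gamma(r_d, h_d),

where `τ_h(j)` is the noise precision of coefficient `j`'s *target* ROI.
Integrating out the inverse-Gaussian latents gives (verified symbolically
and by numerical quadrature in the test suite)

    p(φ_j | τ, λ₂, γ) ∝ exp{ −½ ( 2 √(γ τ_h(j)) |φ_j| + λ₂ τ_h(j) φ_j² ) },

an elastic-net penalty with L1 weight `√(γ τ_h(j))` and L2 weight
`λ₂ τ_h(j)` (in the ½-convention objective). With deviations fixed at
zero, the conditional posterior mode of `φ` is therefore an elastic-net
penalized least-squares estimate; the test suite confirms the mode against
a coordinate-descent solver to 1e−4 (observed ≈ 1e−14). Note the L1
constant is `2√(γτ)` per |φ_j| inside the ½-bracket, not `√(2γτ)`; the
latter form sometimes quoted for this hierarchy does not reproduce the
marginal density (the quadrature test distinguishes the two decisively).

## Gibbs sampler

Seven blocks are cycled in fixed order (φ, ξ, α, τ, λ₂, γ, d):

* **φ** — normal, precision `X'I_τ⁻¹X + V_τ⁻¹V_Φ⁻¹`. Because `Σ_τ` and the
  prior are diagonal, the conditional factorizes exactly over (group,
  target ROI); each block is sampled by Cholesky factorization-and-solve
  (explicit matrix inversion is never formed anywhere in the sampler).
  Equivalence of the block algebra with the global stacked-matrix formula
  is unit-tested on a dense instance.
* **ξ** — normal, factorizing over (subject, target ROI).
* **α_j** — inverse-Gaussian with mean `√(γ/(τ_h(j) φ_j²))` and shape `γ`.
  This (mean, shape) convention is the one that makes the conditional
  proportional to the joint posterior; it is locked by a
  Metropolis-oracle Kolmogorov–Smirnov test and by joint-distribution
  validation. `φ_j²` is floored at 1e−12: the conditional degenerates at
  exactly zero, an event of measure zero but reachable at initialization.
* **τ_r** — Gamma with shape `(n_r + m_r + 2 r_τ)/2`, where `n_r` counts
  residual entries for ROI `r` (equal to `(T−K)·S` when every subject has
  one session) and `m_r = G·C·K·R` counts the coefficients tied to `τ_r`
  through the prior; the rate adds the residual and prior quadratic forms.
  Using actual counts generalizes the two-condition closed form `2RK` to
  any number of conditions and to session-boundary row dropping.
* **λ₂** — Gamma(r_λ, ½Σ_j τ_h(j) φ_j² + h_λ). The shape is `r_λ`, not
  `r_λ + q/2`: the `(α_j+λ₂)^{±1/2}` factors from the φ-prior normalizer
  and the α-prior correction cancel exactly in the joint. The
  `r_λ + q/2` form (appropriate for a pure ridge prior) is available as
  `variant="printed"`; joint-distribution validation flags it at |z| ≈ 40.
* **γ** — Gamma(r_γ + n_coef, ½Σ_j α_j⁻¹ + h_γ).
* **d_j** — Gamma(r_d + S_g/2, ½Σ_{s∈g} (ξ_j^{(s)})² + h_d), per group.
  The alternative printed form `Gamma(S_g(r_d−½)+1, … + S_g h_d)` is
  likewise exposed as a variant and flagged by the same validation; at the
  default `r_d = 1` the shapes coincide and only the rates differ.

Initialization is neutral and reproducible: φ = ξ = 0, τ = d = α = 1,
λ₂ = γ = 1. Default hyperparameters are weakly informative, shape 1 and
rate 0.01 for every Gamma prior, with `r_d = 1` (any `r_d ≤ ½` is rejected
so the printed-variant shape stays positive). The update order is fixed as
listed; no random-scan option is offered. Chains are reproducible bitwise
under a fixed seed.

### Joint-distribution validation

The sampler is validated end-to-end by a getting-it-right comparison on a
minimal model (R = 2, K = 1, C = 2, S = 2, T = 30 split over two
15-scan sessions): the marginal-conditional simulator (prior draw, then
data draw) and the successive-conditional simulator (one Gibbs cycle, then
a fresh data draw) must agree in distribution. First and second moments of
a 14-function panel are compared by z-score (iid standard errors on one
side, batch means on the other); all |z| < 4 at 50,000 sweeps.

Two configuration details matter here. First, the (λ₂, γ, α) prior block
is sampled *exactly* by joint rejection — propose from the uncorrected
hierarchy and accept the whole block with probability
`Π_j √(α_j/(α_j+λ₂)) ≤ 1` — so the simulated prior is identical to the
joint the conditionals are derived from. Second, the validation uses
hyperparameters Gamma(3,3) for τ and Gamma(40,2) for λ₂, γ and d rather
than the shipped defaults: the check is valid at any hyperparameter
setting, and this one keeps every panel moment finite and keeps the prior
mass of explosive VAR draws negligible. With diffuse priors the prior
places real mass on coefficient sets with companion spectral radius well
above 1; the simulated series then grow so large that the φ and ξ
conditionals are numerically pinned at their current values, and the
successive chain, while still correct in distribution, mixes too slowly
for any finite-length comparison to be informative.

## Granger-causality networks

A directed edge source → target is drawn when the lag-joint posterior of
the K coefficients `[Φ_{c,1}(r′,r) … Φ_{c,K}(r′,r)]` excludes the origin
at the chosen level (default 0.95). The primary rule builds a
K-dimensional empirical histogram (per-dimension bin count
`ceil(N^{1/(K+2)})` clipped to [10, 50], range padded 5% beyond the sample
extremes and forced to include the origin) and finds the smallest density
threshold whose super-level set holds at least `level` of the draws — the
highest-density region. The edge is significant when the origin's bin
falls outside that set. In the symmetric one-dimensional case this
reduces to the usual central-interval rule, and on bivariate normal draws
it agrees with the analytic Mahalanobis-ellipse rule in ≥ 98% of
calibration replicates. A literal fixed-height contour rule (origin bin
below 0.025 of the peak) is available for comparison, and for K > 3 the
decision falls back to a Gaussian Mahalanobis test, flagged in the edge
diagnostics. Degenerate zero-variance draws are decided analytically.

Condition and group contrasts apply the same rule to per-draw, per-lag
coefficient differences; subject networks use `φ + ξ^{(s)}` draws. No
multiple-comparison correction is applied across the R² edge tests by
default (an optional Bonferroni-style level adjustment exists), and
self-edges are tested and reported like any other edge, marked separately
in exports. Between-subject variability is summarized by the posterior
mean of `1/d_j` mapped back to (condition, lag, source, target) with a
top-3 extraction per group, and ROI noise variances `1/τ_r` are tabulated
at quantiles 0.025, 0.50, 0.975.

## Preprocessing

Expected condition responses, drift, and seasonal components are removed
per subject, per session, per ROI by OLS before VAR fitting. The
condition regressors convolve each indicator with a canonical double-gamma
HRF (response peak delay 6 s, undershoot delay 16 s, dispersion 1 s,
undershoot ratio 1/6, length 32 s, onset 0 — all configurable),
peak-normalized to 1. Drift uses Legendre polynomials up to order 3 on a
[−1, 1] grid (orthogonalized for conditioning; the fitted span, hence the
residuals, equals that of ordinary polynomials), with the order-0 column
serving as an explicit intercept. Seasonal sine/cosine pairs are added at
configured frequencies; any frequency at or above Nyquist (1/(2·TR)) is
dropped with a logged warning — at TR = 2 s the Nyquist limit is 0.25 Hz,
so a "above 0.5 Hz" cardiac band is unrepresentable and the default is a
single low-frequency pair at 0.01 Hz. Sessions are detrended
independently (baselines differ between sessions) and re-concatenated with
boundaries recorded; the VAR design later drops the first K scans of every
session so no lagged regressor crosses a session boundary.

## Synthetic studies

The generator runs the model forward. Ground truth is sparse: self-lags
of 0.3 on the first lag, a chosen number of cross-edges at ±effect_size
placed uniformly over (condition, lag, ordered pair) slots, rescaled per
condition (lag-k matrices by `s^k`) if the companion spectral radius
exceeds 0.9. Per subject, deviations are drawn independently per
coefficient (diagonal D) and redrawn (cap 50) until every condition's
realized coefficients are stationary; each session is simulated from a
200-step warm-up under its opening condition (discarded; at radius ≤ 0.9
the remaining initialization bias is far below 1% of the stationary
variance), then iterated with the condition switch and diagonal Gaussian
noise. The default study shape mirrors a typical motor-task block
experiment: two conditions alternating in 12-scan blocks within 48-scan
sessions, two groups. Seeds fully determine every output.

What the generator does *not* emulate: hemodynamic convolution in the
generative path (simulation is at the VAR level the model assumes),
scanner drift or physiological noise (the preprocessing tests inject these
separately), non-stationarities within blocks, and spatial structure
across ROIs beyond the VAR dependence. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness to real-fMRI model misspecification.

## Numerical choices

* Stationary covariance: the power series `Σ_i M^i Σ (M^i)'` on the
  companion embedding is truncated when the largest absolute entry of a
  term drops below 1e−10 (cap 10,000 terms); it matches the exact
  discrete-Lyapunov solution to < 1e−8 on randomized stable systems.
* Geweke convergence z-scores compare the first 10% against the last 50%
  of a chain with spectral density at zero estimated by a
  Bartlett-windowed autocovariance sum (bandwidth ≈ 2·n^{1/3}); constant
  chains yield NaN rather than an error.
* Conditional normal draws: Cholesky of the precision matrix, two
  triangular solves; a non-positive-definite precision raises with a
  diagnostic rather than silently regularizing.
* All tabular outputs are plain text (CSV/TSV/JSON/YAML) with 10
  significant digits, so runs are diffable and reproducible byte-for-byte
  under a fixed seed.

## Problem sizes used in the validation suite

The shipped checks run at desk scale by design: getting-it-right at
R = 2, K = 1, S = 2, T = 30 with 50,000 sweeps; conditional-moment oracles
at 20,000 draws; parameter recovery at R = 3, K = 1, S = 12, T = 240 with
5,000 Gibbs sweeps (2,500 burn-in, thin 2); credible-region calibration on
200 replicates of 4,000 draws; covariance identity on 100 random systems
plus one 50,000-step simulation. A full-scale analysis protocol
(80,000 sweeps, 60,000 burn-in, thin 5 → 4,000 retained draws) is the
package default for real studies and is exercised structurally (retained
draw count) rather than at full length.

## Known limitations

* The φ/ξ conditional factorization relies on diagonal `Σ_τ`; a full
  noise covariance would couple target ROIs and is deliberately out of
  scope, matching the model's stated assumption that `Σ_τ` is diagonal
  and shared across participants.
* The HDR histogram rule is reliable for K ≤ 3; the K > 3 Mahalanobis
  fallback assumes approximate posterior normality of lag-joint draws.
* No model-order selection is automated: fit VAR(1), inspect residual
  autocorrelation, and increase the order if needed.
* The printed-variant conditionals for λ₂ and d are provided for
  comparison only; they are not the conditionals of the model's joint
  posterior and fail joint-distribution validation.
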