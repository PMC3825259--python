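"""Elastic-net shrinkage priors and the Gibbs sampler for the hierarchical VAR.

Model (all conditionals derived from the joint posterior):

    y^(s) | phi, xi^(s), tau  ~  N(X^(s) phi + Z^(s) xi^(s), Sigma_tau (x) I)
    phi | V_tau, V_Phi        ~  N(0, V_tau V_Phi)
    xi^(s) | D                ~  N(0, D),  D = diag(1/d_j)  (per group)
    tau_r ~ Gamma(r_tau, h_tau),   d_j ~ Gamma(r_d, h_d)
    alpha_j | lambda2, gamma  ~  (alpha_j/(alpha_j+lambda2))^(1/2) InvGamma(1, gamma/2)
    lambda2 ~ Gamma(r_lam, h_lam),   gamma ~ Gamma(r_gam, h_gam)

with V_tau = diag(1/tau_h(j)) assigning each coefficient the noise precision
of its *target* ROI, and V_Phi = diag(1/(alpha_j + lambda2)).  Marginalizing
the inverse-Gaussian latents alpha gives a conditional posterior mode for
phi equal to an elastic-net penalized least-squares estimate (L1 weight
sqrt(gamma * tau_h(j)), L2 weight lambda2 * tau_h(j) / 2 per coefficient).

Seven full-conditional blocks are cycled in the fixed order
(phi, xi, alpha, tau, lambda2, gamma, d).  The phi and xi conditionals
factorize exactly over target ROIs (and subjects) because Sigma_tau and the
priors are diagonal; the sampler exploits that block structure, and all
normal draws use Cholesky factorization-and-solve (never an explicit
inverse).

For lambda2 and d, two variants are provided.  The default ``"joint"``
variant uses the conditionals implied by the joint posterior above:
lambda2 ~ Gamma(r_lam, rate) (the (alpha_j+lambda2)^(+-1/2) normalizing
factors of the phi and alpha priors cancel exactly) and
d_j ~ Gamma(r_d + S_g/2, rate).  The ``"printed"`` variant reproduces the
forms sometimes quoted for this hierarchy — lambda2 shape r_lam + q/2 and
d_j ~ Gamma(S_g (r_d - 1/2) + 1, rate with S_g * h_d) — which are *not* the
conditionals of the joint above; joint-distribution validation (the
getting-it-right test in :mod:`hvarnet.validate`) passes only for the
default variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .design import ConfigurationError, DesignStack, ModelSpec

logger = logging.getLogger("hvarnet")

#: floor for phi_j^2 in the alpha conditional (the inverse-Gaussian mean
#: degenerates at exactly zero, reachable at initialization)
PHI_SQ_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperParams:
    """Shape/rate pairs of every Gamma prior in the hierarchy.

    ``r_tau``/``h_tau`` may be scalars or per-ROI arrays.  ``r_d`` must
    exceed 1/2 so the printed-variant d shape stays positive for all S.
    Defaults are weakly informative: shape 1, rate 0.01 everywhere.
    """

    r_tau: float | np.ndarray = 1.0
    h_tau: float | np.ndarray = 0.01
    r_lambda: float = 1.0
    h_lambda: float = 0.01
    r_gamma: float = 1.0
    h_gamma: float = 0.01
    r_d: float = 1.0
    h_d: float = 0.01

    def __post_init__(self):
        for name in ("r_tau", "h_tau", "r_lambda", "h_lambda", "r_gamma",
                     "h_gamma", "r_d", "h_d"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ConfigurationError(f"hyperparameter {name} must be positive")
        if np.any(np.asarray(self.r_d) <= 0.5):
            raise ConfigurationError("r_d must be > 1/2")

    def tau_prior(self, R: int) -> tuple[np.ndarray, np.ndarray]:
        return (np.broadcast_to(np.asarray(self.r_tau, dtype=float), (R,)),
                np.broadcast_to(np.asarray(self.h_tau, dtype=float), (R,)))


@dataclass(frozen=True)
class SamplerConfig:
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ConfigurationError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class ModelState:
    """All sampled unknowns at one sweep."""

    phi: np.ndarray       # (G*q,)
    xi: np.ndarray        # (S, q)
    tau: np.ndarray       # (R,)
    d: np.ndarray         # (G, q)
    alpha: np.ndarray     # (G*q,)
    lambda2: float
    gamma: float

    @classmethod
    def initial(cls, spec: ModelSpec, S: int) -> "ModelState":
        """Neutral, reproducible initialization inside the support."""
        return cls(phi=np.zeros(spec.G * spec.q), xi=np.zeros((S, spec.q)),
                   tau=np.ones(spec.R), d=np.ones((spec.G, spec.q)),
                   alpha=np.ones(spec.G * spec.q), lambda2=1.0, gamma=1.0)

    def copy(self) -> "ModelState":
        return ModelState(self.phi.copy(), self.xi.copy(), self.tau.copy(),
                          self.d.copy(), self.alpha.copy(),
                          float(self.lambda2), float(self.gamma))

    def validate(self):
        for name in ("tau", "d", "alpha"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.lambda2 <= 0 or self.gamma <= 0:
            raise ValueError("lambda2 and gamma must be strictly positive")


# ---------------------------------------------------------------------------
# precomputed sufficient structures
# ---------------------------------------------------------------------------


class StudyPrecomp:
    """Per-target-ROI sufficient statistics of a :class:`DesignStack`.

    The regression for target ROI r involves only the p = C*K*R regressor
    columns shared across targets (the compact lag matrix L_s) and the
    coefficients targeting r, so Gram matrices are precomputed once per
    subject and reused every sweep.
    """

    def __init__(self, stack: DesignStack):
        spec = stack.spec
        self.spec = spec
        self.stack = stack
        self.S = stack.S
        self.group_of = [stack.group_index(s) for s in range(self.S)]
        self.L = [stack.lag_matrix(s) for s in range(self.S)]
        self.Yt = [np.column_stack([stack.target_response(s, r)
                                    for r in range(spec.R)])
                   for s in range(self.S)]
        self.G_s = [L.T @ L for L in self.L]
        self.b_s = [L.T @ Yt for L, Yt in zip(self.L, self.Yt)]  # (p, R)
        self.subjects_in_group = [stack.subjects_in_group(g) for g in range(spec.G)]
        self.A_g = [sum(self.G_s[s] for s in self.subjects_in_group[g])
                    if self.subjects_in_group[g] else np.zeros((spec.p, spec.p))
                    for g in range(spec.G)]
        self.B_g = [sum(self.b_s[s] for s in self.subjects_in_group[g])
                    if self.subjects_in_group[g] else np.zeros((spec.p, spec.R))
                    for g in range(spec.G)]
        self.n_resid = sum(L.shape[0] for L in self.L)  # usable rows per ROI
        # coefficient-index maps
        self.idx_gr = np.stack([
            np.stack([spec.block_indices(g, r) for r in range(spec.R)])
            for g in range(spec.G)])                     # (G, R, p)
        self.idx_r = np.stack([np.arange(spec.p) * spec.R + r
                               for r in range(spec.R)])  # (R, p)
        self.n_coef = spec.G * spec.q
        self.tau_of = np.array([spec.target_of_coef(j) for j in range(self.n_coef)])
        self.m_r = np.array([(self.tau_of == r).sum() for r in range(spec.R)])

    def tau_h(self, tau: np.ndarray) -> np.ndarray:
        """V_tau^{-1} diagonal: noise precision tied to each coefficient."""
        return tau[self.tau_of]


def _as_precomp(stack) -> StudyPrecomp:
    if isinstance(stack, StudyPrecomp):
        return stack
    if isinstance(stack, DesignStack):
        pre = getattr(stack, "_precomp", None)
        if pre is None:
            pre = StudyPrecomp(stack)
            stack._precomp = pre
        return pre
    raise TypeError("expected DesignStack or StudyPrecomp")


def _sample_mvn_precision(rng: np.random.Generator, A: np.ndarray,
                          rhs: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Draw from N(A^{-1} rhs, (scale * A)^{-1}) via Cholesky solves."""
    try:
        U = cholesky(A, lower=False)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "conditional precision matrix is not positive definite "
            f"(min diag {np.min(np.diag(A)):.3g})") from exc
    mean = cho_solve((U, False), rhs)
    z = rng.standard_normal(A.shape[0])
    return mean + solve_triangular(U, z, lower=False) / math.sqrt(scale)


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------


def sample_phi(rng: np.random.Generator, state: ModelState, stack,
               hyper: HyperParams) -> np.ndarray:
    """Draw the group connectivity vector phi from its normal full
    conditional N(mu_phi, V) with precision X' I_tau^{-1} X + V_tau^{-1}
    V_Phi^{-1}, exploiting its exact factorization over (group, target ROI).
    """
    pre = _as_precomp(stack)
    spec = pre.spec
    phi = state.phi.copy()
    for g in range(spec.G):
        for r in range(spec.R):
            idx = pre.idx_gr[g, r]
            A = pre.A_g[g] + np.diag(state.alpha[idx] + state.lambda2)
            rhs = pre.B_g[g][:, r].copy()
            for s in pre.subjects_in_group[g]:
                rhs -= pre.G_s[s] @ state.xi[s][pre.idx_r[r]]
            phi[idx] = _sample_mvn_precision(rng, A, rhs, scale=state.tau[r])
    return phi


def sample_xi(rng: np.random.Generator, state: ModelState, stack,
              hyper: HyperParams) -> np.ndarray:
    """Draw all subject deviations from their normal full conditionals,
    independently per subject (Z is block-diagonal) and per target ROI."""
    pre = _as_precomp(stack)
    spec = pre.spec
    xi = state.xi.copy()
    for s in range(pre.S):
        g = pre.group_of[s]
        for r in range(spec.R):
            idxq = pre.idx_r[r]
            A = state.tau[r] * pre.G_s[s] + np.diag(state.d[g][idxq])
            rhs = state.tau[r] * (pre.b_s[s][:, r]
                                  - pre.G_s[s] @ state.phi[pre.idx_gr[g, r]])
            xi[s][idxq] = _sample_mvn_precision(rng, A, rhs)
    return xi


def sample_alpha(rng: np.random.Generator, state: ModelState, stack,
                 hyper: HyperParams) -> np.ndarray:
    """Draw the elastic-net latents alpha_j from their inverse-Gaussian full
    conditionals: mean sqrt(gamma / (tau_h(j) phi_j^2)), shape gamma."""
    pre = _as_precomp(stack)
    phi2 = np.maximum(state.phi ** 2, PHI_SQ_FLOOR)
    mean = np.sqrt(state.gamma / (pre.tau_h(state.tau) * phi2))
    return rng.wald(mean, state.gamma)


def _residual_ssq(state: ModelState, pre: StudyPrecomp) -> np.ndarray:
    """Per-ROI residual sum of squares of y - X phi - Z xi."""
    spec = pre.spec
    ssq = np.zeros(spec.R)
    for s in range(pre.S):
        g = pre.group_of[s]
        for r in range(spec.R):
            coef = state.phi[pre.idx_gr[g, r]] + state.xi[s][pre.idx_r[r]]
            e = pre.Yt[s][:, r] - pre.L[s] @ coef
            ssq[r] += e @ e
    return ssq


def tau_conditional_params(state: ModelState, stack, hyper: HyperParams
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(shape, rate) of every tau_r full conditional.

    shape_r = (n_resid_r + m_r + 2 r_tau_r) / 2 where n_resid_r counts the
    residual entries with variance 1/tau_r (equal to (T-K)S for
    single-session subjects) and m_r = G*C*K*R counts the coefficients tied
    to tau_r through V_tau; rate_r = w_(r)'w_(r)/2 + zeta_(r)'zeta_(r)/2 +
    h_tau_r with zeta_j = sqrt(alpha_j + lambda2) * phi_j.
    """
    pre = _as_precomp(stack)
    r_tau, h_tau = hyper.tau_prior(pre.spec.R)
    if np.any(pre.m_r == 0):
        raise RuntimeError("empty coefficient selection set for some ROI "
                           "(V_tau indexing bug)")
    ssq = _residual_ssq(state, pre)
    quad = (state.alpha + state.lambda2) * state.phi ** 2
    zeta = np.array([quad[pre.tau_of == r].sum() for r in range(pre.spec.R)])
    shape = (pre.n_resid + pre.m_r + 2.0 * r_tau) / 2.0
    rate = 0.5 * ssq + 0.5 * zeta + h_tau
    return shape, rate


def sample_tau(rng: np.random.Generator, state: ModelState, stack,
               hyper: HyperParams) -> np.ndarray:
    shape, rate = tau_conditional_params(state, stack, hyper)
    return rng.gamma(shape, 1.0 / rate)


def lambda2_conditional_params(state: ModelState, stack, hyper: HyperParams,
                               variant: str = "joint") -> tuple[float, float]:
    """(shape, rate) of the lambda2 full conditional.

    ``"joint"``: shape r_lambda — the lambda2 factors in the phi-prior
    normalizer and the alpha-prior correction cancel.  ``"printed"``: shape
    r_lambda + n_coef/2.  Rate is the same in both: sum_j tau_h(j) phi_j^2 / 2
    + h_lambda.
    """
    pre = _as_precomp(stack)
    rate = 0.5 * float(pre.tau_h(state.tau) @ state.phi ** 2) + hyper.h_lambda
    if variant == "joint":
        shape = hyper.r_lambda
    elif variant == "printed":
        shape = hyper.r_lambda + pre.n_coef / 2.0
    else:
        raise ConfigurationError(f"unknown conditional variant {variant!r}")
    return shape, rate


def sample_lambda2(rng: np.random.Generator, state: ModelState, stack,
                   hyper: HyperParams, variant: str = "joint") -> float:
    shape, rate = lambda2_conditional_params(state, stack, hyper, variant)
    return float(rng.gamma(shape, 1.0 / rate))


def gamma_conditional_params(state: ModelState, stack, hyper: HyperParams
                             ) -> tuple[float, float]:
    """(shape, rate) of the gamma full conditional:
    Gamma(r_gamma + n_coef, sum_j 1/alpha_j / 2 + h_gamma)."""
    pre = _as_precomp(stack)
    return (hyper.r_gamma + pre.n_coef,
            0.5 * float(np.sum(1.0 / state.alpha)) + hyper.h_gamma)


def sample_gamma_hyper(rng: np.random.Generator, state: ModelState, stack,
                       hyper: HyperParams) -> float:
    shape, rate = gamma_conditional_params(state, stack, hyper)
    return float(rng.gamma(shape, 1.0 / rate))


def d_conditional_params(state: ModelState, stack, hyper: HyperParams,
                         variant: str = "joint"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-group (shape, rate) arrays (G, q) of the d_j full conditionals.

    Subjects contribute only to their own group's d.  ``"joint"``:
    Gamma(r_d + S_g/2, sum_s xi_j^2 / 2 + h_d).  ``"printed"``:
    Gamma(S_g (r_d - 1/2) + 1, sum_s xi_j^2 / 2 + S_g h_d).
    """
    pre = _as_precomp(stack)
    spec = pre.spec
    shape = np.empty((spec.G, spec.q))
    rate = np.empty((spec.G, spec.q))
    for g in range(spec.G):
        subj = pre.subjects_in_group[g]
        Sg = len(subj)
        ssq = (np.sum([state.xi[s] ** 2 for s in subj], axis=0)
               if subj else np.zeros(spec.q))
        if variant == "joint":
            shape[g] = hyper.r_d + Sg / 2.0
            rate[g] = 0.5 * ssq + hyper.h_d
        elif variant == "printed":
            shape[g] = Sg * (hyper.r_d - 0.5) + 1.0
            rate[g] = 0.5 * ssq + Sg * hyper.h_d
        else:
            raise ConfigurationError(f"unknown conditional variant {variant!r}")
    return shape, rate


def sample_d(rng: np.random.Generator, state: ModelState, stack,
             hyper: HyperParams, variant: str = "joint") -> np.ndarray:
    shape, rate = d_conditional_params(state, stack, hyper, variant)
    return rng.gamma(shape, 1.0 / rate)


def gibbs_sweep(rng: np.random.Generator, state: ModelState, pre: StudyPrecomp,
                hyper: HyperParams, variant: str = "joint") -> None:
    """One full Gibbs cycle in the fixed order
    (phi, xi, alpha, tau, lambda2, gamma, d); mutates ``state``."""
    state.phi = sample_phi(rng, state, pre, hyper)
    state.xi = sample_xi(rng, state, pre, hyper)
    state.alpha = sample_alpha(rng, state, pre, hyper)
    state.tau = sample_tau(rng, state, pre, hyper)
    state.lambda2 = sample_lambda2(rng, state, pre, hyper, variant)
    state.gamma = sample_gamma_hyper(rng, state, pre, hyper)
    state.d = sample_d(rng, state, pre, hyper, variant)


# ---------------------------------------------------------------------------
# posterior container and driver
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in chains for every unknown.

    phi draws are addressable by (group, condition, lag, target ROI, source
    ROI) through :meth:`phi_draws` / :meth:`lag_joint`.
    """

    spec: ModelSpec
    subject_ids: list[str]
    subject_groups: list[str]
    config: SamplerConfig
    hyper: HyperParams
    phi: np.ndarray       # (N, G*q)
    xi: np.ndarray        # (N, S, q)
    tau: np.ndarray       # (N, R)
    d: np.ndarray         # (N, G, q)
    alpha: np.ndarray     # (N, G*q)
    lambda2: np.ndarray   # (N,)
    gamma: np.ndarray     # (N,)
    provenance: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.phi.shape[0]

    def phi_draws(self, group: str, condition: str, lag: int, target: int,
                  source: int) -> np.ndarray:
        return self.phi[:, self.spec.coef_index(group, condition, lag, target, source)]

    def lag_joint(self, group: str, condition: str, target: int,
                  source: int) -> np.ndarray:
        """N x K matrix of lag-joint group-coefficient draws for one edge."""
        cols = [self.spec.coef_index(group, condition, k, target, source)
                for k in range(1, self.spec.K + 1)]
        return self.phi[:, cols]

    def subject_lag_joint(self, subject_id: str, condition: str, target: int,
                          source: int) -> np.ndarray:
        """N x K draws of phi + xi^(s) for one edge of one subject."""
        s = self.subject_ids.index(subject_id)
        group = self.subject_groups[s]
        cols = [self.spec.coef_index(group, condition, k, target, source)
                for k in range(1, self.spec.K + 1)]
        qcols = [c % self.spec.q for c in cols]
        return self.phi[:, cols] + self.xi[:, s, qcols]

    def geweke_summary(self) -> dict[str, float]:
        """Max |Geweke z| per parameter family (nan-safe)."""
        out = {}
        for name, arr in (("phi", self.phi), ("tau", self.tau),
                          ("lambda2", self.lambda2[:, None]),
                          ("gamma", self.gamma[:, None])):
            if self.n_draws < 100:  # diagnostic undefined on very short chains
                out[name] = float("nan")
                continue
            z = geweke_diagnostic(arr)
            out[name] = float(np.nanmax(np.abs(z))) if z.size else float("nan")
        return out


def run_gibbs(stack: DesignStack, hyper: HyperParams | None = None,
              config: SamplerConfig | None = None, variant: str = "joint",
              provenance: dict | None = None) -> PosteriorSamples:
    """Run the Gibbs sampler and retain every ``thin``-th post-burn-in draw.

    Reproducible under a fixed ``config.seed``; numerical failure mid-chain
    raises with the sweep index at which it occurred.
    """
    hyper = hyper or HyperParams()
    config = config or SamplerConfig()
    pre = _as_precomp(stack)
    spec = pre.spec
    rng = np.random.default_rng(config.seed)
    state = ModelState.initial(spec, pre.S)
    N = config.n_retained
    out = PosteriorSamples(
        spec=spec, subject_ids=list(pre.stack.subject_ids),
        subject_groups=list(pre.stack.subject_groups), config=config,
        hyper=hyper,
        phi=np.empty((N, spec.G * spec.q)), xi=np.empty((N, pre.S, spec.q)),
        tau=np.empty((N, spec.R)), d=np.empty((N, spec.G, spec.q)),
        alpha=np.empty((N, spec.G * spec.q)), lambda2=np.empty(N),
        gamma=np.empty(N), provenance=provenance or {})
    kept = 0
    log_every = max(1, config.iterations // 10)
    for it in range(1, config.iterations + 1):
        try:
            gibbs_sweep(rng, state, pre, hyper, variant)
        except (RuntimeError, FloatingPointError) as exc:
            raise RuntimeError(f"Gibbs sampler failed at sweep {it}: {exc}") from exc
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < N:
            out.phi[kept] = state.phi
            out.xi[kept] = state.xi
            out.tau[kept] = state.tau
            out.d[kept] = state.d
            out.alpha[kept] = state.alpha
            out.lambda2[kept] = state.lambda2
            out.gamma[kept] = state.gamma
            kept += 1
        if it % log_every == 0:
            logger.info("gibbs sweep %d/%d (retained %d)", it, config.iterations, kept)
    return out


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Bartlett-windowed
    autocovariance sum (bandwidth ~ 2 n^{1/3})."""
    n = x.size
    x = x - x.mean()
    v = float(x @ x) / n
    if v == 0.0:
        return 0.0
    L = min(n - 1, max(1, int(round(2.0 * n ** (1.0 / 3.0)))))
    s = v
    for lag in range(1, L + 1):
        c = float(x[:-lag] @ x[lag:]) / n
        s += 2.0 * (1.0 - lag / (L + 1.0)) * c
    return max(s, 0.0)


def geweke_diagnostic(chain: np.ndarray, first: float = 0.1,
                      last: float = 0.5) -> np.ndarray:
    """Convergence z-scores comparing the means of the first ``first`` and
    last ``last`` fractions of each chain, with spectral-density variance
    estimates.  Constant segments yield nan (flagged, not an error)."""
    chain = np.asarray(chain, dtype=float)
    squeeze = chain.ndim == 1
    if squeeze:
        chain = chain[:, None]
    n = chain.shape[0]
    if n < 100:
        raise ConfigurationError("chain must have length >= 100")
    na, nb = int(first * n), int(last * n)
    z = np.empty(chain.shape[1])
    for j in range(chain.shape[1]):
        a, b = chain[:na, j], chain[n - nb:, j]
        var = _spectral_density_zero(a) / na + _spectral_density_zero(b) / nb
        z[j] = (a.mean() - b.mean()) / math.sqrt(var) if var > 0 else np.nan
    return z[0] if squeeze and z.size == 1 else z
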