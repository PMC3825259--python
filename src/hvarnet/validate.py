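"""Sampler-validation tooling: joint-distribution (getting-it-right) testing
and the elastic-net correspondence of the phi conditional.

The getting-it-right check compares two ways of sampling the joint
distribution of (parameters, data):

* the *marginal-conditional* simulator draws parameters from the prior and
  then data from the likelihood (independent draws);
* the *successive-conditional* simulator alternates one full Gibbs cycle of
  parameters given data with a fresh data draw given parameters (a Markov
  chain whose stationary distribution is the same joint iff every full
  conditional is correct).

If every full conditional is consistent with the joint, the two simulators
agree in distribution; first and second moments of a panel of test
functions are compared via z-scores (iid standard errors on the marginal
side, batch means on the successive side).

Prior simulation note: the (lambda2, gamma, alpha) block of the prior is
sampled *exactly* by joint rejection — propose lambda2 and gamma from their
Gamma priors and alpha_j ~ InvGamma(1, gamma/2), then accept the whole
block with probability prod_j sqrt(alpha_j / (alpha_j + lambda2)) <= 1,
which is precisely the correction factor the hierarchy places on the alpha
prior.  This keeps the simulated joint identical to the one the Gibbs
conditionals are derived from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (BlockDesign, ConfigurationError, ModelSpec, SubjectSeries,
                     build_study, make_block_indicators)
from .gibbs import (HyperParams, ModelState, StudyPrecomp, _as_precomp,
                    gibbs_sweep)


# ---------------------------------------------------------------------------
# exact prior simulation
# ---------------------------------------------------------------------------


def draw_shrinkage_block(rng: np.random.Generator, hyper: HyperParams,
                         n_coef: int, max_batches: int = 100000,
                         batch: int = 256) -> tuple[float, float, np.ndarray]:
    """Exact draw of (lambda2, gamma, alpha) from the prior by joint
    rejection sampling."""
    for _ in range(max_batches):
        lam = rng.gamma(hyper.r_lambda, 1.0 / hyper.h_lambda, size=batch)
        gam = rng.gamma(hyper.r_gamma, 1.0 / hyper.h_gamma, size=batch)
        # alpha_j ~ InvGamma(1, gamma/2) == 1 / Gamma(1, rate=gamma/2)
        alpha = gam[:, None] / (2.0 * rng.gamma(1.0, 1.0, size=(batch, n_coef)))
        logacc = 0.5 * np.sum(np.log(alpha) - np.log(alpha + lam[:, None]), axis=1)
        acc = np.log(rng.random(batch)) < logacc
        hits = np.nonzero(acc)[0]
        if hits.size:
            i = hits[0]
            return float(lam[i]), float(gam[i]), alpha[i]
    raise RuntimeError("prior rejection sampler failed to accept")


def draw_prior_state(rng: np.random.Generator, spec: ModelSpec, S: int,
                     subject_groups: list[int], hyper: HyperParams) -> ModelState:
    """One exact draw of all unknowns from the prior."""
    lam, gam, alpha = draw_shrinkage_block(rng, hyper, spec.G * spec.q)
    r_tau, h_tau = hyper.tau_prior(spec.R)
    tau = rng.gamma(r_tau, 1.0 / h_tau)
    d = rng.gamma(hyper.r_d, 1.0 / hyper.h_d, size=(spec.G, spec.q))
    tau_of = np.array([spec.target_of_coef(j) for j in range(spec.G * spec.q)])
    phi_var = 1.0 / (tau[tau_of] * (alpha + lam))
    phi = rng.normal(0.0, np.sqrt(phi_var))
    xi = np.stack([rng.normal(0.0, 1.0 / np.sqrt(d[g])) for g in subject_groups])
    return ModelState(phi=phi, xi=xi, tau=tau, d=d, alpha=alpha,
                      lambda2=lam, gamma=gam)


# ---------------------------------------------------------------------------
# joint model simulator
# ---------------------------------------------------------------------------


@dataclass
class JointModelSimulator:
    """Couples the prior, the conditional VAR likelihood (given fixed
    initial values of zero for the first K scans of every session) and the
    Gibbs transition, for getting-it-right runs."""

    spec: ModelSpec
    design: BlockDesign
    subject_groups: list[str]
    hyper: HyperParams

    def __post_init__(self):
        self.W = make_block_indicators(self.design, self.spec.conditions)
        self.cond_at = np.argmax(self.W, axis=1)
        self.group_idx = [self.spec.groups.index(g) for g in self.subject_groups]
        self.subject_ids = [f"sub{i + 1}" for i in range(len(self.subject_groups))]

    @property
    def S(self) -> int:
        return len(self.subject_groups)

    def draw_prior(self, rng: np.random.Generator) -> ModelState:
        return draw_prior_state(rng, self.spec, self.S, self.group_idx, self.hyper)

    def simulate_series(self, rng: np.random.Generator,
                        state: ModelState) -> list[SubjectSeries]:
        """Data draw given parameters: iterate the condition-switching VAR
        per session from zero initial values, diagonal noise 1/tau."""
        spec, design = self.spec, self.design
        R, K = spec.R, spec.K
        noise_sd = 1.0 / np.sqrt(state.tau)
        out = []
        for s in range(self.S):
            g = self.group_idx[s]
            coef = state.phi[g * spec.q:(g + 1) * spec.q] + state.xi[s]
            # per-condition lag matrices from the flat within-group vector
            phis = [[coef[((c * K + k) * R + np.arange(R)[None, :]) * R
                          + np.arange(R)[:, None]]
                     for k in range(K)] for c in range(spec.C)]
            Y = np.zeros((design.T, R))
            for start in design.session_starts:
                for t in range(start + K, start + design.scans_per_session):
                    ph = phis[self.cond_at[t]]
                    y = ph[0] @ Y[t - 1]
                    for k in range(1, K):
                        y += ph[k] @ Y[t - k - 1]
                    Y[t] = y + noise_sd * rng.standard_normal(R)
            out.append(SubjectSeries(subject_id=self.subject_ids[s],
                                     group=self.subject_groups[s], Y=Y, W=self.W,
                                     session_starts=design.session_starts))
        return out

    def precomp(self, series: list[SubjectSeries]) -> StudyPrecomp:
        return _as_precomp(build_study(series, self.spec))


# ---------------------------------------------------------------------------
# getting-it-right comparison
# ---------------------------------------------------------------------------


def _test_functions(state: ModelState, series: list[SubjectSeries]) -> np.ndarray:
    y_last = series[0].Y[-1, 0]
    return np.array([
        state.phi[0],
        float(np.mean(state.phi ** 2)),
        state.xi[0, 0],
        float(np.mean(state.xi ** 2)),
        state.tau[0],
        1.0 / state.tau[-1],
        state.lambda2,
        np.log(state.lambda2),
        np.log(state.gamma),
        float(np.mean(1.0 / state.alpha)),
        state.d[0, 0],
        float(np.mean(1.0 / state.d)),
        np.tanh(y_last),
        float(np.mean(np.tanh(series[-1].Y))),
    ])


TEST_FUNCTION_LABELS = [
    "phi[0]", "mean(phi^2)", "xi[0,0]", "mean(xi^2)", "tau[0]", "1/tau[-1]",
    "lambda2", "log(lambda2)", "log(gamma)", "mean(1/alpha)", "d[0,0]",
    "mean(1/d)", "tanh(y_last)", "mean(tanh(Y))",
]


def _batch_se(x: np.ndarray, n_batches: int = 50) -> np.ndarray:
    """Batch-means standard error of the mean for autocorrelated draws."""
    n = x.shape[0] // n_batches
    b = x[:n * n_batches].reshape(n_batches, n, -1).mean(axis=1)
    return b.std(axis=0, ddof=1) / np.sqrt(n_batches)


def getting_it_right(spec: ModelSpec, design: BlockDesign,
                     subject_groups: list[str], hyper: HyperParams,
                     n_sweeps: int = 50000, n_marginal: int | None = None,
                     seed: int = 0, variant: str = "joint",
                     ) -> dict[str, np.ndarray]:
    """Run both simulators and return z-scores for the first two moments of
    the test-function panel.

    Returns a dict with ``z`` (2 x n_functions), ``labels``, and the two
    moment estimates.  |z| < 4 everywhere is the expected outcome for a
    correct sampler.
    """
    sim = JointModelSimulator(spec, design, list(subject_groups), hyper)
    n_marginal = n_sweeps if n_marginal is None else n_marginal
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    f_mc = np.empty((n_marginal, len(TEST_FUNCTION_LABELS)))
    for i in range(n_marginal):
        state = sim.draw_prior(rng)
        series = sim.simulate_series(rng, state)
        f_mc[i] = _test_functions(state, series)

    state = sim.draw_prior(rng)
    series = sim.simulate_series(rng, state)
    f_sc = np.empty_like(f_mc, shape=(n_sweeps, len(TEST_FUNCTION_LABELS)))
    for i in range(n_sweeps):
        pre = sim.precomp(series)
        gibbs_sweep(rng, state, pre, sim.hyper, variant)
        series = sim.simulate_series(rng, state)
        f_sc[i] = _test_functions(state, series)

    z = np.empty((2, len(TEST_FUNCTION_LABELS)))
    moments = {}
    for m, power in enumerate((1, 2)):
        a, b = f_mc ** power, f_sc ** power
        se_a = a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])
        se_b = _batch_se(b)
        z[m] = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(se_a ** 2 + se_b ** 2)
        moments[f"moment{power}_marginal"] = a.mean(axis=0)
        moments[f"moment{power}_successive"] = b.mean(axis=0)
    return {"z": z, "labels": list(TEST_FUNCTION_LABELS), **moments}


# ---------------------------------------------------------------------------
# elastic-net correspondence
# ---------------------------------------------------------------------------


def elastic_net_weights(stack, tau: np.ndarray, lambda2: float, gamma: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient (L1, L2) weights of the phi conditional with the
    inverse-Gaussian latents marginalized out:

        -log p(phi | tau, lambda2, gamma, xi, y)
          = 1/2 sum_rows tau_row * resid^2
            + sum_j [ l1_j |phi_j| + 1/2 l2_j phi_j^2 ] + const,

    with l1_j = sqrt(gamma * tau_h(j)) and l2_j = lambda2 * tau_h(j).
    """
    pre = _as_precomp(stack)
    tau_h = pre.tau_h(np.asarray(tau, dtype=float))
    return np.sqrt(gamma * tau_h), lambda2 * tau_h


def elastic_net_objective(phi: np.ndarray, stack, tau: np.ndarray,
                          lambda2: float, gamma: float,
                          xi: np.ndarray | None = None) -> float:
    """Negative log conditional density of phi (alpha marginalized), up to
    an additive constant — the elastic-net penalized least-squares
    criterion.  ``xi`` defaults to zero (the correspondence setting)."""
    pre = _as_precomp(stack)
    spec = pre.spec
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (pre.n_coef,):
        raise ConfigurationError(f"phi must have length {pre.n_coef}")
    tau = np.asarray(tau, dtype=float)
    sse = 0.0
    for s in range(pre.S):
        g = pre.group_of[s]
        for r in range(spec.R):
            coef = phi[pre.idx_gr[g, r]]
            if xi is not None:
                coef = coef + xi[s][pre.idx_r[r]]
            e = pre.Yt[s][:, r] - pre.L[s] @ coef
            sse += tau[r] * (e @ e)
    l1, l2 = elastic_net_weights(pre, tau, lambda2, gamma)
    return 0.5 * sse + float(l1 @ np.abs(phi)) + 0.5 * float(l2 @ phi ** 2)
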