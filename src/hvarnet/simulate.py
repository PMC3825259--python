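"""Forward simulation of multi-subject condition-switching VAR studies.

Generates studies with known ground truth by running the hierarchical model
forward: group coefficient sets, per-subject deviations drawn with diagonal
between-subject covariance, condition-switching VAR iteration per session
with diagonal Gaussian observation noise.  Every draw is reproducible from
the seed in the :class:`TruthSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import (BlockDesign, CoefficientSet, ConfigurationError, ModelSpec,
                     NonstationaryError, SubjectSeries, companion_spectral_radius,
                     make_block_indicators)

#: discarded warm-up steps per session before recording, long enough that
#: initial-condition bias is negligible at spectral radius <= 0.9
WARMUP_STEPS = 200

#: attempts to redraw a subject's deviations before giving up on stationarity
STATIONARITY_RETRY_CAP = 50


@dataclass
class TruthSpec:
    """Complete generative description of a synthetic study.

    ``deviation_sd`` holds the between-subject standard deviations
    sqrt(1/d_j) per within-group coefficient (length q, shared across
    groups); ``noise_var`` holds the observation noise variances 1/tau_r.
    """

    spec: ModelSpec
    design: BlockDesign
    coefficients: CoefficientSet
    deviation_sd: np.ndarray
    noise_var: np.ndarray
    subjects_per_group: int = 6
    seed: int = 0

    def __post_init__(self):
        self.deviation_sd = np.broadcast_to(
            np.asarray(self.deviation_sd, dtype=float), (self.spec.q,)).copy()
        self.noise_var = np.broadcast_to(
            np.asarray(self.noise_var, dtype=float), (self.spec.R,)).copy()
        if np.any(self.deviation_sd < 0):
            raise ConfigurationError("deviation SDs must be >= 0")
        if np.any(self.noise_var <= 0):
            raise ConfigurationError("noise variances must be positive")
        if self.subjects_per_group < 1:
            raise ConfigurationError("subjects_per_group must be >= 1")


def make_default_truth(R: int = 3, K: int = 1, n_edges: int = 2,
                       effect_size: float = 0.4, seed: int = 0,
                       conditions: tuple[str, ...] = ("rest", "active"),
                       groups: tuple[str, ...] = ("group1",),
                       design: BlockDesign | None = None,
                       deviation_sd: float = 0.1, noise_var: float = 1.0,
                       subjects_per_group: int = 6,
                       self_lag: float = 0.3) -> TruthSpec:
    """Sparse ground truth: self-lags at ``self_lag`` on the first lag,
    ``n_edges`` randomly placed cross-edges at +/-``effect_size`` per group,
    everything else zero; rescaled per condition if the spectral radius
    exceeds 0.9.

    The default study shape mirrors a typical motor-task block experiment:
    two conditions alternating in 12-scan blocks within 48-scan sessions.
    """
    spec = ModelSpec(R=R, K=K, conditions=conditions, groups=groups)
    if design is None:
        design = BlockDesign(sessions=2, scans_per_session=48, block_length=12,
                             condition_order=tuple(conditions)[:2] if len(conditions) > 1
                             else tuple(conditions))
    slots_per_group = spec.C * spec.K * R * (R - 1)
    if n_edges > slots_per_group:
        raise ConfigurationError(
            f"n_edges={n_edges} exceeds available cross-coefficient slots "
            f"({slots_per_group})")
    rng = np.random.default_rng(seed)
    mats: dict[tuple[str, str, int], np.ndarray] = {}
    for g in spec.groups:
        for c in spec.conditions:
            for k in range(1, K + 1):
                M = np.zeros((R, R))
                if k == 1:
                    np.fill_diagonal(M, self_lag)
                mats[(g, c, k)] = M
        # place cross-edges uniformly over (condition, lag, ordered pair) slots
        offdiag = [(tgt, src) for tgt in range(R) for src in range(R) if tgt != src]
        slots = [(c, k, tgt, src) for c in spec.conditions
                 for k in range(1, K + 1) for tgt, src in offdiag]
        chosen = rng.choice(len(slots), size=n_edges, replace=False)
        for i in chosen:
            c, k, tgt, src = slots[i]
            mats[(g, c, k)][tgt, src] = effect_size * rng.choice([-1.0, 1.0])
        for c in spec.conditions:
            phis = [mats[(g, c, k)] for k in range(1, K + 1)]
            rho = companion_spectral_radius(phis)
            if rho > 0.9:
                # scaling lag-k matrices by s^k scales the companion
                # eigenvalues by exactly s
                scale = 0.9 / rho
                for k in range(1, K + 1):
                    mats[(g, c, k)] *= scale ** k
                if companion_spectral_radius(
                        [mats[(g, c, k)] for k in range(1, K + 1)]) > 0.9 + 1e-6:
                    raise NonstationaryError(
                        f"could not rescale truth for group {g}, condition {c} "
                        "to spectral radius <= 0.9")
    coeffs = CoefficientSet(spec, mats)
    return TruthSpec(spec=spec, design=design, coefficients=coeffs,
                     deviation_sd=np.full(spec.q, deviation_sd),
                     noise_var=np.full(R, noise_var),
                     subjects_per_group=subjects_per_group, seed=seed)


@dataclass
class StudyTruth:
    """Simulated study plus the ground truth needed for recovery scoring."""

    truth: TruthSpec
    series: list[SubjectSeries]
    xi: dict[str, np.ndarray] = field(default_factory=dict)  # realized deviations (q,)


def _draw_subject_coeffs(rng: np.random.Generator, truth: TruthSpec,
                         group: str, subject_id: str
                         ) -> tuple[CoefficientSet, np.ndarray]:
    """Group truth plus a stationarity-respecting deviation draw."""
    spec = truth.spec
    single = ModelSpec(R=spec.R, K=spec.K, conditions=spec.conditions, groups=(group,))
    group_vec = np.concatenate([
        truth.coefficients.matrices[(group, c, k)][:, src]
        for c in spec.conditions for k in range(1, spec.K + 1)
        for src in range(spec.R)])
    for _ in range(STATIONARITY_RETRY_CAP):
        xi = rng.normal(0.0, truth.deviation_sd)
        subj = CoefficientSet.from_vector(group_vec + xi, single)
        if all(companion_spectral_radius(subj.lag_matrices(group, c)) < 1.0
               for c in spec.conditions):
            return subj, xi
    raise NonstationaryError(
        f"subject {subject_id}: no stationary deviation draw in "
        f"{STATIONARITY_RETRY_CAP} attempts")


def simulate_subject(rng: np.random.Generator, truth: TruthSpec, group: str,
                     subject_id: str) -> tuple[SubjectSeries, np.ndarray]:
    """Simulate one subject: draw deviations, iterate the VAR per session
    from a ``WARMUP_STEPS``-step warm-up under the session's opening
    condition, add diagonal Gaussian noise."""
    spec, design = truth.spec, truth.design
    subj, xi = _draw_subject_coeffs(rng, truth, group, subject_id)
    W = make_block_indicators(design, spec.conditions)
    noise_sd = np.sqrt(truth.noise_var)
    R, K = spec.R, spec.K
    phis_by_cond = {c: subj.lag_matrices(group, ci)
                    for c, ci in enumerate(spec.conditions)}
    Y = np.zeros((design.T, R))
    for sl_start in design.session_starts:
        sl = slice(sl_start, sl_start + design.scans_per_session)
        Wses = W[sl]
        opening = int(np.argmax(Wses[0]))
        # warm-up under the opening condition, discarded
        hist = np.zeros((K, R))
        phis = phis_by_cond[opening]
        for _ in range(WARMUP_STEPS):
            y = sum(phis[k] @ hist[-1 - k] for k in range(K))
            y = y + rng.normal(0.0, noise_sd)
            hist = np.vstack([hist[1:], y]) if K > 1 else y[None, :]
        out = np.empty((design.scans_per_session, R))
        for t in range(design.scans_per_session):
            phis = phis_by_cond[int(np.argmax(Wses[t]))]
            y = sum(phis[k] @ hist[-1 - k] for k in range(K))
            y = y + rng.normal(0.0, noise_sd)
            out[t] = y
            hist = np.vstack([hist[1:], y]) if K > 1 else y[None, :]
        Y[sl] = out
    series = SubjectSeries(subject_id=subject_id, group=group, Y=Y, W=W,
                           session_starts=design.session_starts)
    return series, xi


def simulate_study(truth: TruthSpec) -> StudyTruth:
    """Simulate all subjects of a study; deterministic under ``truth.seed``."""
    root = np.random.SeedSequence(truth.seed)
    out = StudyTruth(truth=truth, series=[])
    children = root.spawn(len(truth.spec.groups) * truth.subjects_per_group)
    i = 0
    for group in truth.spec.groups:
        for j in range(truth.subjects_per_group):
            sid = f"{group}_sub{j + 1:02d}"
            rng = np.random.default_rng(children[i])
            series, xi = simulate_subject(rng, truth, group, sid)
            out.series.append(series)
            out.xi[sid] = xi
            i += 1
    return out
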