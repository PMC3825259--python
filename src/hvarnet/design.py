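"""Condition-switching VAR model objects and deterministic regression structures.

A study consists of ``S`` subjects, each observed as an ``R``-variate time
series of ROI means under a block design that switches between ``C``
experimental conditions.  Within each condition the series follows a VAR(K)
whose coefficient matrices are condition specific:

    Y(t) = sum_k sum_c W_c(t) * Phi_{c,k} Y(t-k) + e(t),

with ``W_c(t)`` the binary condition indicator and diagonal noise covariance
``Sigma_tau = diag(1/tau_r)``.  This module builds the classical-linear-model
form of that equation: per usable time point a block ``x(t) = I_R kron w(t)``
where ``w(t)`` holds the condition-gated lagged observations, stacked into
per-subject fixed-effects (group-expanded) and random-effects design
matrices.

Coefficient vector ordering (fixed once, used everywhere): groups are
concatenated; within a group the flat index of coefficient
``Phi_{c,k}(target, source)`` is ``((c*K + (k-1))*R + source)*R + target``,
i.e. condition-major, then lag, then the column-major unrolling of each
R x R matrix (target fastest).  ``Phi(target, source)`` multiplies the past
value of *source* to predict the current value of *target*; network edges
therefore point source -> target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


class ConfigurationError(ValueError):
    """Invalid model / design configuration."""


class NonstationaryError(RuntimeError):
    """A coefficient set with companion spectral radius >= 1 was supplied
    where stationarity is required."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Dimensions and labels of the hierarchical VAR.

    Parameters
    ----------
    R : number of ROIs.
    K : VAR order (maximal lag).
    conditions : ordered condition labels (length C >= 1).
    groups : ordered group labels (length G >= 1).
    """

    R: int
    K: int
    conditions: tuple[str, ...] = ("rest", "active")
    groups: tuple[str, ...] = ("group1",)

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.R < 1 or self.K < 1:
            raise ConfigurationError("R and K must be >= 1")
        if len(self.conditions) < 1 or len(self.groups) < 1:
            raise ConfigurationError("need at least one condition and one group")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("group labels must be unique")

    @property
    def C(self) -> int:
        return len(self.conditions)

    @property
    def G(self) -> int:
        return len(self.groups)

    @property
    def q(self) -> int:
        """Mean parameters per group: R^2 * K * C."""
        return self.R * self.R * self.K * self.C

    @property
    def p(self) -> int:
        """Regressors per target ROI: C * K * R (q = p * R)."""
        return self.C * self.K * self.R

    # -- flat-index bookkeeping ------------------------------------------

    def coef_index(self, group: str, condition: str, lag: int, target: int,
                   source: int) -> int:
        """Flat index of Phi_{condition,lag}(target, source) in the length
        G*q coefficient vector."""
        g = self.groups.index(group)
        c = self.conditions.index(condition)
        if not 1 <= lag <= self.K:
            raise ConfigurationError(f"lag must be in 1..{self.K}")
        if not (0 <= target < self.R and 0 <= source < self.R):
            raise ConfigurationError("ROI index out of range")
        return g * self.q + ((c * self.K + (lag - 1)) * self.R + source) * self.R + target

    def coef_label(self, j: int) -> tuple[str, str, int, int, int]:
        """Inverse of :meth:`coef_index`: (group, condition, lag, target, source)."""
        g, jq = divmod(j, self.q)
        flat3, target = divmod(jq, self.R)
        ck, source = divmod(flat3, self.R)
        c, k = divmod(ck, self.K)
        return self.groups[g], self.conditions[c], k + 1, target, source

    def target_of_coef(self, j: int) -> int:
        """ROI whose noise precision tau_r is tied to coefficient j via V_tau."""
        return (j % self.q) % self.R

    def block_indices(self, group_index: int, target: int) -> np.ndarray:
        """Flat indices (into the G*q vector) of all coefficients in one
        group's regression for one target ROI, ordered (condition, lag,
        source) — the same ordering as the per-target regressor rows."""
        return group_index * self.q + np.arange(self.p) * self.R + target


@dataclass(frozen=True)
class BlockDesign:
    """Block experimental design: sessions of equal length, alternating
    fixed-length condition blocks (e.g. 12-scan rest/active alternation)."""

    sessions: int
    scans_per_session: int
    block_length: int
    condition_order: tuple[str, ...] = ("rest", "active")
    TR: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "condition_order", tuple(self.condition_order))
        if self.sessions < 1 or self.scans_per_session < 1 or self.block_length < 1:
            raise ConfigurationError("sessions, scans_per_session, block_length must be >= 1")
        if self.scans_per_session % self.block_length != 0:
            raise ConfigurationError(
                f"scans_per_session ({self.scans_per_session}) must be a "
                f"multiple of block_length ({self.block_length})")
        if self.TR <= 0:
            raise ConfigurationError("TR must be positive")

    @property
    def T(self) -> int:
        """Total raw time points across sessions."""
        return self.sessions * self.scans_per_session

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.condition_order:
            seen.setdefault(c)
        return tuple(seen)

    @property
    def session_starts(self) -> list[int]:
        return [i * self.scans_per_session for i in range(self.sessions)]


def make_block_indicators(design: BlockDesign,
                          conditions: tuple[str, ...] | None = None) -> np.ndarray:
    """Binary T x C condition-indicator matrix for a block design.

    Each session cycles through ``design.condition_order`` in blocks of
    ``block_length`` scans; an indicator stays 1 from its block onset until
    the next block onset, so every row has exactly one 1.
    """
    conditions = design.conditions if conditions is None else tuple(conditions)
    missing = set(design.condition_order) - set(conditions)
    if missing:
        raise ConfigurationError(f"conditions {sorted(missing)} not in {conditions}")
    col = {c: i for i, c in enumerate(conditions)}
    W = np.zeros((design.T, len(conditions)), dtype=float)
    n_blocks = design.scans_per_session // design.block_length
    order = design.condition_order
    t = 0
    for _ in range(design.sessions):
        for b in range(n_blocks):
            c = order[b % len(order)]
            W[t:t + design.block_length, col[c]] = 1.0
            t += design.block_length
    return W


@dataclass
class SubjectSeries:
    """One subject's multi-ROI time series with condition indicators.

    ``Y`` is T x R (rows = scans, columns = ROIs); ``W`` is T x C with
    exactly one 1 per row; ``session_starts`` are the 0-based indices at
    which sessions begin (lagged predictors never cross these boundaries).
    """

    subject_id: str
    group: str
    Y: np.ndarray
    W: np.ndarray
    session_starts: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.Y.ndim != 2 or self.W.ndim != 2:
            raise ConfigurationError("Y and W must be 2-D")
        if self.Y.shape[0] != self.W.shape[0]:
            raise ConfigurationError("Y and W must have equal row counts")
        if not np.all(np.isfinite(self.Y)):
            raise ConfigurationError(f"subject {self.subject_id}: Y has non-finite entries")
        if not np.allclose(self.W.sum(axis=1), 1.0):
            raise ConfigurationError("every row of W must sum to 1 (conditions partition time)")
        self.session_starts = sorted(int(s) for s in self.session_starts)
        if not self.session_starts or self.session_starts[0] != 0:
            raise ConfigurationError("session_starts must begin at index 0")

    @property
    def T(self) -> int:
        return self.Y.shape[0]

    @property
    def R(self) -> int:
        return self.Y.shape[1]

    def session_slices(self) -> list[slice]:
        bounds = list(self.session_starts) + [self.T]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# coefficient sets
# ---------------------------------------------------------------------------


@dataclass
class CoefficientSet:
    """Mapping (group, condition, lag) -> R x R coefficient matrix, with a
    bijective flattening to the length-(G*q) vector phi.

    ``matrices[(group, condition, lag)][target, source]`` is the coefficient
    of past *source* activity predicting current *target* activity.
    """

    spec: ModelSpec
    matrices: dict[tuple[str, str, int], np.ndarray]

    def __post_init__(self):
        for g in self.spec.groups:
            for c in self.spec.conditions:
                for k in range(1, self.spec.K + 1):
                    key = (g, c, k)
                    M = np.asarray(self.matrices.get(key, np.zeros((self.spec.R,) * 2)),
                                   dtype=float)
                    if M.shape != (self.spec.R, self.spec.R):
                        raise ConfigurationError(f"matrix for {key} has shape {M.shape}")
                    self.matrices[key] = M

    @classmethod
    def zeros(cls, spec: ModelSpec) -> "CoefficientSet":
        return cls(spec, {})

    def flatten(self) -> np.ndarray:
        """Length G*q vector in the canonical ordering."""
        spec = self.spec
        phi = np.empty(spec.G * spec.q)
        for g in spec.groups:
            for c in spec.conditions:
                for k in range(1, spec.K + 1):
                    M = self.matrices[(g, c, k)]
                    for src in range(spec.R):
                        for tgt in range(spec.R):
                            phi[spec.coef_index(g, c, k, tgt, src)] = M[tgt, src]
        return phi

    @classmethod
    def from_vector(cls, phi: np.ndarray, spec: ModelSpec) -> "CoefficientSet":
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (spec.G * spec.q,):
            raise ConfigurationError(
                f"phi must have length G*q = {spec.G * spec.q}, got {phi.shape}")
        mats: dict[tuple[str, str, int], np.ndarray] = {}
        for g in spec.groups:
            for c in spec.conditions:
                for k in range(1, spec.K + 1):
                    M = np.empty((spec.R, spec.R))
                    for src in range(spec.R):
                        for tgt in range(spec.R):
                            M[tgt, src] = phi[spec.coef_index(g, c, k, tgt, src)]
                    mats[(g, c, k)] = M
        return cls(spec, mats)

    def lag_matrices(self, group: str, condition: str) -> list[np.ndarray]:
        return [self.matrices[(group, condition, k)] for k in range(1, self.spec.K + 1)]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _lag_rows(series: SubjectSeries, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Compact per-target regressor matrix.

    Returns ``(L, Yt)`` where ``L`` is n_s x p with row for usable time t
    holding ``W_c(t) * Y_src(t-k)`` in (condition, lag, source) order, and
    ``Yt`` is n_s x R holding the predicted observations.  The first K scans
    of every session are dropped so lags never cross session boundaries.
    """
    R, K, C, p = spec.R, spec.K, spec.C, spec.p
    if series.R != R:
        raise ConfigurationError(f"series has {series.R} ROIs, spec expects {R}")
    if series.W.shape[1] != C:
        raise ConfigurationError(f"W has {series.W.shape[1]} columns, spec expects {C}")
    L_parts, Y_parts = [], []
    for sl in series.session_slices():
        Ys, Ws = series.Y[sl], series.W[sl]
        n = Ys.shape[0] - K
        if n < 1:
            raise ConfigurationError(
                f"subject {series.subject_id}: session of length {Ys.shape[0]} "
                f"is too short for VAR order {K}")
        L = np.zeros((n, p))
        for c in range(C):
            w = Ws[K:, c][:, None]
            for k in range(1, K + 1):
                cols = slice((c * K + k - 1) * R, (c * K + k) * R)
                L[:, cols] = w * Ys[K - k:Ys.shape[0] - k, :]
        L_parts.append(L)
        Y_parts.append(Ys[K:])
    return np.vstack(L_parts), np.vstack(Y_parts)


def build_subject_design(series: SubjectSeries, spec: ModelSpec
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject regression structures (X_s, Z_s, y_s).

    ``Z_s`` (n_s*R x q) stacks the blocks ``x(t) = I_R kron w(t)``; ``X_s``
    (n_s*R x G*q) is the group-expanded version ``Z_s A^(s)`` with the
    identity in the subject's group slot; ``y_s`` stacks ``Y(t)`` time-major.
    For G = 1, ``X_s`` equals ``Z_s`` entrywise.
    """
    if series.group not in spec.groups:
        raise ConfigurationError(
            f"subject {series.subject_id}: unknown group {series.group!r}")
    L, Yt = _lag_rows(series, spec)
    Z_s = np.kron(L, np.eye(spec.R))
    y_s = Yt.reshape(-1)
    g = spec.groups.index(series.group)
    X_s = np.zeros((Z_s.shape[0], spec.G * spec.q))
    X_s[:, g * spec.q:(g + 1) * spec.q] = Z_s
    return X_s, Z_s, y_s


@dataclass
class DesignStack:
    """Stacked study-level regression structures.

    Holds the per-subject fixed-effects (group-expanded) designs ``X_s``,
    random-effects designs ``Z_s`` and responses ``y_s``, plus pooled
    row-stacked ``X``/``y`` and block-diagonal ``Z``.
    """

    spec: ModelSpec
    subject_ids: list[str]
    subject_groups: list[str]
    X_list: list[np.ndarray]
    Z_list: list[np.ndarray]
    y_list: list[np.ndarray]

    def __post_init__(self):
        for g, sid in zip(self.subject_groups, self.subject_ids):
            if g not in self.spec.groups:
                raise ConfigurationError(f"subject {sid}: unknown group {g!r}")

    @property
    def S(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rows(self) -> list[int]:
        """Usable time points per subject (rows of the compact design)."""
        return [Z.shape[0] // self.spec.R for Z in self.Z_list]

    @property
    def X(self) -> np.ndarray:
        return np.vstack(self.X_list)

    @property
    def y(self) -> np.ndarray:
        return np.concatenate(self.y_list)

    @property
    def Z(self) -> np.ndarray:
        return scipy.linalg.block_diag(*self.Z_list)

    def group_index(self, s: int) -> int:
        return self.spec.groups.index(self.subject_groups[s])

    def subjects_in_group(self, g: int) -> list[int]:
        label = self.spec.groups[g]
        return [s for s, grp in enumerate(self.subject_groups) if grp == label]

    # compact per-target structures used by the Gibbs sampler ------------

    def lag_matrix(self, s: int) -> np.ndarray:
        """Recover the n_s x p compact regressor matrix from Z_s."""
        R = self.spec.R
        return self.Z_list[s][::R, ::R]

    def target_response(self, s: int, r: int) -> np.ndarray:
        return self.y_list[s][r::self.spec.R]


def stack_study(designs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                groups: list[str], spec: ModelSpec,
                subject_ids: list[str] | None = None) -> DesignStack:
    """Stack per-subject (X_s, Z_s, y_s) tuples into a :class:`DesignStack`."""
    if subject_ids is None:
        subject_ids = [f"sub{i + 1:02d}" for i in range(len(designs))]
    return DesignStack(spec, list(subject_ids), list(groups),
                       [d[0] for d in designs], [d[1] for d in designs],
                       [d[2] for d in designs])


def build_study(series_list: list[SubjectSeries], spec: ModelSpec) -> DesignStack:
    """Build and stack designs for a whole study."""
    designs = [build_subject_design(s, spec) for s in series_list]
    return stack_study(designs, [s.group for s in series_list], spec,
                       [s.subject_id for s in series_list])


# ---------------------------------------------------------------------------
# stationarity utilities
# ---------------------------------------------------------------------------


def companion_matrix(phis: list[np.ndarray]) -> np.ndarray:
    """RK x RK companion embedding of VAR(K) coefficient matrices."""
    phis = [np.asarray(P, dtype=float) for P in phis]
    R = phis[0].shape[0]
    for P in phis:
        if P.shape != (R, R):
            raise ConfigurationError("all coefficient matrices must be R x R with equal R")
    K = len(phis)
    M = np.zeros((R * K, R * K))
    M[:R] = np.hstack(phis)
    if K > 1:
        M[R:, :R * (K - 1)] = np.eye(R * (K - 1))
    return M


def companion_spectral_radius(phis: list[np.ndarray]) -> float:
    """Spectral radius of the companion matrix; < 1 means stationary."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(phis)))))


def stationary_covariance(phis: list[np.ndarray], sigma_tau: np.ndarray,
                          tol: float = 1e-10, max_terms: int = 10000) -> np.ndarray:
    """Stationary covariance of a stable condition-constant VAR(K).

    Evaluates ``sum_i M^i Sigma (M^i)'`` on the companion embedding,
    truncating once the largest absolute entry of a term drops below
    ``tol``; the top-left R x R block is Cov(Y(t)).  Agrees with the exact
    discrete-Lyapunov solution.
    """
    M = companion_matrix(phis)
    R = phis[0].shape[0]
    sigma_tau = np.atleast_1d(np.asarray(sigma_tau, dtype=float))
    if sigma_tau.ndim == 1:
        if sigma_tau.shape != (R,):
            raise ConfigurationError("sigma_tau must have one variance per ROI")
        if np.any(sigma_tau <= 0):
            raise ConfigurationError("noise variances must be positive")
        Sigma = np.diag(sigma_tau)
    else:
        Sigma = sigma_tau
    rho = float(np.max(np.abs(np.linalg.eigvals(M))))
    if rho >= 1.0:
        raise NonstationaryError(f"companion spectral radius {rho:.4f} >= 1")
    big = np.zeros_like(M)
    big[:R, :R] = Sigma
    V = big.copy()
    term = big
    for _ in range(max_terms):
        term = M @ term @ M.T
        V += term
        if np.max(np.abs(term)) < tol:
            break
    return V[:R, :R]
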