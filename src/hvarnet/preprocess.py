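"""Nuisance regression for ROI-mean BOLD time series.

Before VAR fitting, the expected condition responses (condition indicators
convolved with a canonical double-gamma hemodynamic response function),
slow polynomial drifts and seasonal sine/cosine components are removed per
subject and per ROI by ordinary least squares; the hierarchical VAR
consumes the residuals.  Detrending is performed per session independently
(sessions differ in baseline) and sessions are re-concatenated with their
boundaries preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import ConfigurationError, SubjectSeries

logger = logging.getLogger("hvarnet")


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF shape parameters (seconds).

    The response is the difference of two gamma densities: a positive
    response peaking near ``peak_delay - dispersion`` and an undershoot
    scaled by ``undershoot_ratio``; peak-normalized to maximum 1.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0
    onset: float = 0.0


def canonical_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma hemodynamic response on a nonnegative time grid,
    peak-normalized to 1; zero at t = 0 and beyond ``params.length``."""
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ConfigurationError("time grid must be nonempty")
    if np.any(t < 0):
        raise ConfigurationError("time grid must be nonnegative")
    ts = t - params.onset
    d = params.dispersion
    h = (stats.gamma.pdf(ts, params.peak_delay / d, scale=d)
         - params.undershoot_ratio
         * stats.gamma.pdf(ts, params.undershoot_delay / d, scale=d))
    h[(ts < 0) | (ts > params.length)] = 0.0
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


@dataclass
class NuisanceDesign:
    """Columns: one HRF-convolved response per condition, orthogonalized
    polynomial drift up to ``poly_order`` (the order-0 column is the
    intercept), and a sine/cosine pair per retained frequency."""

    matrix: np.ndarray
    column_names: list[str]
    TR: float
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ConfigurationError("nuisance design has non-finite entries")
        norms = np.linalg.norm(self.matrix, axis=0)
        zero = [n for n, v in zip(self.column_names, norms) if v == 0]
        if zero:
            raise ConfigurationError(f"identically zero nuisance columns: {zero}")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_nuisance_design(W: np.ndarray, TR: float, poly_order: int = 3,
                          frequencies: tuple[float, ...] = (0.01,),
                          hrf: HRFParams = HRFParams(),
                          condition_names: list[str] | None = None
                          ) -> NuisanceDesign:
    """Assemble the nuisance design for one session.

    Condition columns are the discrete convolution of each indicator with
    the canonical HRF sampled at TR, truncated to the session length.
    Polynomial drift columns are Legendre polynomials on a time grid
    rescaled to [-1, 1] (orthogonal for conditioning; the fitted span is the
    ordinary polynomial span).  Each frequency contributes a
    sin/cos(2 pi f t TR) pair; frequencies at or above the Nyquist limit
    1/(2 TR) are dropped with a warning.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    T, C = W.shape
    names = condition_names or [f"cond{c + 1}" for c in range(C)]
    kernel = canonical_hrf(np.arange(0.0, hrf.length + TR / 2, TR), hrf)
    cols, colnames = [], []
    for c in range(C):
        cols.append(np.convolve(W[:, c], kernel)[:T])
        colnames.append(f"hrf:{names[c]}")
    grid = np.linspace(-1.0, 1.0, T)
    P = np.polynomial.legendre.legvander(grid, poly_order)
    for o in range(poly_order + 1):
        cols.append(P[:, o])
        colnames.append(f"poly{o}")
    t = np.arange(T) * TR
    nyquist = 1.0 / (2.0 * TR)
    dropped = []
    for f in frequencies:
        if f <= 0 or f >= nyquist:
            dropped.append(f"f={f:g}Hz")
            logger.warning("dropping seasonal frequency %g Hz (Nyquist %g Hz)",
                           f, nyquist)
            continue
        cols.append(np.sin(2 * np.pi * f * t))
        colnames.append(f"sin:{f:g}Hz")
        cols.append(np.cos(2 * np.pi * f * t))
        colnames.append(f"cos:{f:g}Hz")
    M = np.column_stack(cols)
    if T < M.shape[1] + 1:
        raise ConfigurationError(
            f"session length {T} too short for {M.shape[1]} nuisance columns")
    return NuisanceDesign(matrix=M, column_names=colnames, TR=TR, dropped=dropped)


def detrend_subject(Y: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Per-ROI OLS residuals of ``Y`` (T x R) on the nuisance design.

    Residuals are numerically orthogonal to every design column; a
    rank-deficient design raises with the collinear columns listed.
    """
    Y = np.asarray(Y, dtype=float)
    M = design.matrix
    if Y.shape[0] != M.shape[0]:
        raise ConfigurationError("Y and nuisance design have different lengths")
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name columns whose removal restores full rank
        bad = [design.column_names[j] for j in range(M.shape[1])
               if np.linalg.matrix_rank(np.delete(M, j, axis=1)) == rank]
        raise ConfigurationError(f"nuisance design is rank deficient; "
                                 f"collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
    return Y - M @ beta


@dataclass
class PreprocessReport:
    """Per-session dropped columns and per-ROI nuisance-fit R^2."""

    dropped: list[str]
    r_squared: np.ndarray  # (sessions, R)

    def to_text(self, roi_labels: list[str] | None = None) -> str:
        lines = ["nuisance regression report"]
        lines.append("dropped columns: " + (", ".join(self.dropped) or "none"))
        R = self.r_squared.shape[1]
        labels = roi_labels or [f"ROI{i + 1}" for i in range(R)]
        for si, row in enumerate(self.r_squared):
            vals = ", ".join(f"{l}={v:.3f}" for l, v in zip(labels, row))
            lines.append(f"session {si + 1} R^2: {vals}")
        return "\n".join(lines)


def preprocess_subject(series: SubjectSeries, TR: float, poly_order: int = 3,
                       frequencies: tuple[float, ...] = (0.01,),
                       hrf: HRFParams = HRFParams(),
                       condition_names: list[str] | None = None
                       ) -> tuple[SubjectSeries, PreprocessReport]:
    """Detrend each session of a subject independently and re-concatenate.

    Returns the residual series (same condition indicators and session
    boundaries) and a report of dropped columns and per-ROI R^2.
    """
    resid = np.empty_like(series.Y)
    dropped: list[str] = []
    r2 = np.empty((len(series.session_slices()), series.R))
    for si, sl in enumerate(series.session_slices()):
        design = build_nuisance_design(series.W[sl], TR, poly_order,
                                       frequencies, hrf, condition_names)
        dropped = design.dropped
        e = detrend_subject(series.Y[sl], design)
        resid[sl] = e
        tot = ((series.Y[sl] - series.Y[sl].mean(axis=0)) ** 2).sum(axis=0)
        res = (e ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[si] = np.where(tot > 0, 1.0 - res / tot, 0.0)
    out = SubjectSeries(subject_id=series.subject_id, group=series.group,
                        Y=resid, W=series.W.copy(),
                        session_starts=list(series.session_starts))
    return out, PreprocessReport(dropped=dropped, r_squared=r2)
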