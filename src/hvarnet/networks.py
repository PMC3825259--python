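"""Granger-causality network construction from posterior samples.

An ordered ROI pair (source, target) carries a directed edge when the
lag-joint posterior distribution of its K coefficients excludes the origin
at the requested credibility level.  The primary decision rule is the
highest-density region (HDR) of a K-dimensional empirical histogram: the
smallest density threshold whose super-level set covers at least ``level``
of the draws; the edge is significant when the origin's bin falls outside
that set.  In the symmetric one-dimensional case this reduces to the usual
central credible-interval rule.  A literal fixed-height contour rule
(origin bin below 0.025 of the peak height) is available for comparison,
and for K > 3 — where histograms are unreliable — a Gaussian-approximation
Mahalanobis test at the same level is used and flagged in the diagnostics.

No multiple-comparison correction is applied across the R^2 edge tests by
default (an optional Bonferroni-style level adjustment is provided);
self-edges (r -> r) are tested and reported like any other edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ConfigurationError
from .gibbs import PosteriorSamples

#: per-dimension histogram bin count: ceil(N^(1/(K+2))) clipped to this range
BIN_RANGE = (10, 50)
#: fractional padding of the histogram range beyond the sample extremes
RANGE_PAD = 0.05


def _bin_edges(samples: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Per-dimension edges, padded and forced to include the origin."""
    edges = []
    for j in range(samples.shape[1]):
        lo, hi = samples[:, j].min(), samples[:, j].max()
        pad = RANGE_PAD * (hi - lo)
        lo = min(lo - pad, 0.0) - 1e-12
        hi = max(hi + pad, 0.0) + 1e-12
        edges.append(np.linspace(lo, hi, n_bins + 1))
    return edges


def hdr_contains_origin(samples: np.ndarray, level: float = 0.95,
                        rule: str = "hdr") -> tuple[bool, dict]:
    """Decide whether the origin lies outside the credible region of the
    lag-joint draws.

    Returns ``(significant, diagnostics)`` where ``significant`` is True
    when the origin is *excluded*.  ``rule`` is ``"hdr"`` (default) or
    ``"contour"`` (fixed-height 0.025-of-peak contour).  Zero-variance
    dimensions are decided analytically: a constant coordinate excludes the
    origin iff its value is nonzero.
    """
    if not 0.0 < level < 1.0:
        raise ConfigurationError("level must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if samples.ndim != 2 or samples.shape[0] < 1:
        raise ConfigurationError("samples must be a nonempty N x K matrix")
    N, K = samples.shape

    sd = samples.std(axis=0)
    const = sd == 0.0
    if const.any():
        vals = samples[0, const]
        if np.any(vals != 0.0):
            return True, {"method": "degenerate", "constant_value": vals}
        if const.all():
            return False, {"method": "degenerate", "constant_value": vals}
        samples = samples[:, ~const]
        K = samples.shape[1]

    if K > 3:
        mean = samples.mean(axis=0)
        cov = np.cov(samples, rowvar=False, ddof=1)
        d2 = float(mean @ np.linalg.solve(cov, mean))
        thresh = float(stats.chi2.ppf(level, K))
        return d2 > thresh, {"method": "mahalanobis", "d2": d2,
                             "threshold": thresh, "flag": "K>3 fallback"}

    n_bins = int(np.clip(np.ceil(N ** (1.0 / (K + 2))), *BIN_RANGE))
    edges = _bin_edges(samples, n_bins)
    counts, _ = np.histogramdd(samples, bins=edges)
    origin_bin = tuple(
        int(np.clip(np.searchsorted(edges[j], 0.0, side="right") - 1,
                    0, n_bins - 1))
        for j in range(K))
    origin_count = counts[origin_bin]
    peak = counts.max()
    if rule == "hdr":
        flat = np.sort(counts.ravel())[::-1]
        cum = np.cumsum(flat)
        ix = int(np.searchsorted(cum, level * N))
        threshold = flat[min(ix, flat.size - 1)]
    elif rule == "contour":
        threshold = 0.025 * peak
    else:
        raise ConfigurationError(f"unknown decision rule {rule!r}")
    inside = origin_count >= threshold
    return (not inside), {"method": rule, "n_bins": n_bins,
                          "threshold": float(threshold),
                          "origin_count": float(origin_count),
                          "peak_count": float(peak)}


# ---------------------------------------------------------------------------
# edge tests and network results
# ---------------------------------------------------------------------------


@dataclass
class EdgeTest:
    """Decision record for one ordered ROI pair."""

    source: int
    target: int
    condition: str
    group: str                      # group label, subject id, or contrast tag
    lag_means: np.ndarray           # posterior mean coefficient per lag
    significant: bool
    level: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_self_edge(self) -> bool:
        return self.source == self.target


@dataclass
class NetworkResult:
    """All edge tests of one network plus metadata."""

    kind: str                       # "group", "contrast", or "subject"
    label: str
    condition: str
    level: float
    K: int
    edges: list[EdgeTest]

    def significant_edges(self) -> list[EdgeTest]:
        return [e for e in self.edges if e.significant]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.source, e.target) for e in self.significant_edges()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            row = {"source": e.source, "target": e.target,
                   "condition": e.condition, "group": e.group}
            for k in range(self.K):
                row[f"mean_lag{k + 1}"] = e.lag_means[k]
            row["significant"] = e.significant
            row["level"] = self.level
            row["self_edge"] = e.is_self_edge
            rows.append(row)
        return pd.DataFrame(rows)

    def to_graph(self, roi_labels: list[str] | None = None):
        """Directed graph of significant edges (networkx), self-edges marked."""
        import networkx as nx

        g = nx.DiGraph(kind=self.kind, label=self.label,
                       condition=self.condition, level=self.level)
        n_rois = max((max(e.source, e.target) for e in self.edges), default=-1) + 1
        labels = roi_labels or [f"ROI{i + 1}" for i in range(n_rois)]
        g.add_nodes_from(labels)
        for e in self.significant_edges():
            g.add_edge(labels[e.source], labels[e.target],
                       self_edge=e.is_self_edge,
                       **{f"mean_lag{k + 1}": float(e.lag_means[k])
                          for k in range(self.K)})
        return g


def _edges_from_sampler(sample_fn, R: int, condition: str, tag: str,
                        level: float, rule: str,
                        bonferroni: bool) -> list[EdgeTest]:
    eff_level = 1.0 - (1.0 - level) / (R * R) if bonferroni else level
    edges = []
    for src in range(R):
        for tgt in range(R):
            draws = sample_fn(tgt, src)
            sig, diag = hdr_contains_origin(draws, eff_level, rule)
            edges.append(EdgeTest(source=src, target=tgt, condition=condition,
                                  group=tag, lag_means=draws.mean(axis=0),
                                  significant=sig, level=eff_level,
                                  diagnostics=diag))
    return edges


def group_network(posterior: PosteriorSamples, condition: str, group: str,
                  level: float = 0.95, rule: str = "hdr",
                  bonferroni: bool = False) -> NetworkResult:
    """Group-level Granger network: every ordered ROI pair (self-edges
    included) is tested on the lag-joint group-coefficient draws."""
    spec = posterior.spec
    if condition not in spec.conditions:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if group not in spec.groups:
        raise ConfigurationError(f"unknown group {group!r}")
    edges = _edges_from_sampler(
        lambda tgt, src: posterior.lag_joint(group, condition, tgt, src),
        spec.R, condition, group, level, rule, bonferroni)
    return NetworkResult("group", group, condition, level, spec.K, edges)


def contrast_network(posterior: PosteriorSamples, level: float = 0.95,
                     conditions: tuple[str, str] | None = None,
                     groups: tuple[str, str] | None = None,
                     condition: str | None = None, group: str | None = None,
                     rule: str = "hdr", bonferroni: bool = False) -> NetworkResult:
    """Condition- or group-difference network from per-draw, per-lag
    coefficient differences.

    Pass either ``conditions=(a, b)`` with ``group=...`` (condition contrast
    within a group) or ``groups=(a, b)`` with ``condition=...`` (group
    contrast within a condition).
    """
    spec = posterior.spec
    if (conditions is None) == (groups is None):
        raise ConfigurationError("specify exactly one of conditions= or groups=")
    if conditions is not None:
        if group is None:
            raise ConfigurationError("condition contrast requires group=")
        a, b = conditions
        fn = lambda tgt, src: (posterior.lag_joint(group, a, tgt, src)
                               - posterior.lag_joint(group, b, tgt, src))
        tag, cond_label = group, f"{a}-{b}"
    else:
        if condition is None:
            raise ConfigurationError("group contrast requires condition=")
        ga, gb = groups
        fn = lambda tgt, src: (posterior.lag_joint(ga, condition, tgt, src)
                               - posterior.lag_joint(gb, condition, tgt, src))
        tag, cond_label = f"{ga}-{gb}", condition
    edges = _edges_from_sampler(fn, spec.R, cond_label, tag, level, rule,
                                bonferroni)
    return NetworkResult("contrast", tag, cond_label, level, spec.K, edges)


def subject_network(posterior: PosteriorSamples, subject: str, condition: str,
                    level: float = 0.95, rule: str = "hdr",
                    bonferroni: bool = False) -> NetworkResult:
    """Subject-level network from per-draw phi + xi^(s) coefficients."""
    if subject not in posterior.subject_ids:
        raise ConfigurationError(f"unknown subject {subject!r}")
    spec = posterior.spec
    if condition not in spec.conditions:
        raise ConfigurationError(f"unknown condition {condition!r}")
    edges = _edges_from_sampler(
        lambda tgt, src: posterior.subject_lag_joint(subject, condition, tgt, src),
        spec.R, condition, subject, level, rule, bonferroni)
    return NetworkResult("subject", subject, condition, level, spec.K, edges)


# ---------------------------------------------------------------------------
# between-subject variability summaries
# ---------------------------------------------------------------------------


@dataclass
class VarianceSummary:
    edge_table: pd.DataFrame    # posterior-mean between-subject variance per edge
    top_edges: pd.DataFrame     # top-k most variable edges per group
    noise_table: pd.DataFrame   # ROI noise-variance quantiles Q.025/Q.50/Q.975


def variance_summaries(posterior: PosteriorSamples, top_k: int = 3,
                       roi_labels: list[str] | None = None) -> VarianceSummary:
    """Between-subject variance ranking (posterior mean of 1/d_j mapped back
    to condition/lag/source/target) and the ROI noise-variance quantile
    table at 0.025, 0.50, 0.975."""
    spec = posterior.spec
    labels = roi_labels or [f"ROI{i + 1}" for i in range(spec.R)]
    rows = []
    var_mean = (1.0 / posterior.d).mean(axis=0)  # (G, q)
    for gi, gname in enumerate(spec.groups):
        for jq in range(spec.q):
            _, cond, lag, tgt, src = spec.coef_label(jq)
            rows.append({"group": gname, "condition": cond, "lag": lag,
                         "source": labels[src], "target": labels[tgt],
                         "between_subject_variance": var_mean[gi, jq]})
    edge_table = pd.DataFrame(rows).sort_values(
        ["group", "between_subject_variance"], ascending=[True, False],
        ignore_index=True)
    top = (edge_table.groupby("group", sort=False, group_keys=False)
           .head(top_k).reset_index(drop=True))

    noise = 1.0 / posterior.tau  # (N, R) variances
    qs = np.quantile(noise, [0.025, 0.50, 0.975], axis=0)
    noise_table = pd.DataFrame(
        {"Q.025": qs[0], "Q.50": qs[1], "Q.975": qs[2]}, index=labels)
    noise_table.index.name = "ROI"
    return VarianceSummary(edge_table=edge_table, top_edges=top,
                           noise_table=noise_table)
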