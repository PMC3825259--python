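"""Tabular-text readers/writers and run configuration.

Everything on disk is inspectable text: wide CSV time series (one row per
scan, one column per ROI, one file per subject per session), CSV posterior
tables (draw index x labeled parameter columns), TSV edge lists, JSON
manifests and YAML configuration.  Writers and readers round-trip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (BlockDesign, ConfigurationError, ModelSpec, SubjectSeries,
                     make_block_indicators)
from .gibbs import HyperParams, PosteriorSamples, SamplerConfig
from .simulate import StudyTruth

_PHI_FAMILIES = ("phi", "alpha")       # columns labeled group.cond.lag.tgt.src


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _check_keys(block: dict, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {context}: {sorted(unknown)}; allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    """Validated study configuration (YAML)."""

    spec: ModelSpec
    design: BlockDesign
    hyper: HyperParams
    sampler: SamplerConfig
    level: float = 0.95
    preprocess: bool = False
    poly_order: int = 3
    frequencies: tuple[float, ...] = (0.01,)
    roi_labels: tuple[str, ...] | None = None

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        _check_keys(cfg, {"model", "design", "hyperparameters", "sampler",
                          "network", "preprocess"}, "config")
        model = dict(cfg.get("model", {}))
        _check_keys(model, {"rois", "order", "conditions", "groups"}, "model")
        rois = model.get("rois", 2)
        if isinstance(rois, int):
            roi_labels = tuple(f"ROI{i + 1}" for i in range(rois))
        else:
            roi_labels = tuple(str(r) for r in rois)
        spec = ModelSpec(R=len(roi_labels), K=int(model.get("order", 1)),
                         conditions=tuple(model.get("conditions", ("rest", "active"))),
                         groups=tuple(model.get("groups", ("group1",))))
        des = dict(cfg.get("design", {}))
        _check_keys(des, {"sessions", "scans_per_session", "block_length",
                          "condition_order", "TR"}, "design")
        design = BlockDesign(
            sessions=int(des.get("sessions", 2)),
            scans_per_session=int(des.get("scans_per_session", 48)),
            block_length=int(des.get("block_length", 12)),
            condition_order=tuple(des.get("condition_order", spec.conditions)),
            TR=float(des.get("TR", 2.0)))
        hp = dict(cfg.get("hyperparameters", {}))
        _check_keys(hp, {"r_tau", "h_tau", "r_lambda", "h_lambda", "r_gamma",
                         "h_gamma", "r_d", "h_d"}, "hyperparameters")
        hyper = HyperParams(**hp)
        sc = dict(cfg.get("sampler", {}))
        _check_keys(sc, {"iterations", "burn_in", "thin", "seed"}, "sampler")
        sampler = SamplerConfig(**{k: int(v) for k, v in sc.items()})
        net = dict(cfg.get("network", {}))
        _check_keys(net, {"level"}, "network")
        pp = dict(cfg.get("preprocess", {}))
        _check_keys(pp, {"enabled", "poly_order", "frequencies"}, "preprocess")
        return cls(spec=spec, design=design, hyper=hyper, sampler=sampler,
                   level=float(net.get("level", 0.95)),
                   preprocess=bool(pp.get("enabled", False)),
                   poly_order=int(pp.get("poly_order", 3)),
                   frequencies=tuple(pp.get("frequencies", (0.01,))),
                   roi_labels=roi_labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if not isinstance(cfg, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(cfg)


# ---------------------------------------------------------------------------
# time-series files
# ---------------------------------------------------------------------------


def write_subject_series(series: SubjectSeries, out_dir: str | Path,
                         roi_labels: list[str] | None = None) -> list[Path]:
    """One wide CSV per session: rows = scans, columns = ROI labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = roi_labels or [f"ROI{i + 1}" for i in range(series.R)]
    paths = []
    for si, sl in enumerate(series.session_slices()):
        df = pd.DataFrame(series.Y[sl], columns=labels)
        p = out_dir / f"session{si + 1:02d}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    return paths


def read_session_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    try:
        Y = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ConfigurationError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(Y)):
        bad = np.argwhere(~np.isfinite(Y))[0]
        raise ConfigurationError(
            f"{path}: non-finite value at row {bad[0] + 2}, column "
            f"{df.columns[bad[1]]!r}")
    return Y, list(df.columns)


def write_study(study: StudyTruth, out_dir: str | Path, force: bool = False,
                roi_labels: list[str] | None = None) -> Path:
    """Write a simulated study: per-subject session CSVs, a study manifest
    (subject -> group and file list) and a ground-truth manifest (JSON) for
    recovery scoring."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = study.truth.spec
    labels = roi_labels or [f"ROI{i + 1}" for i in range(spec.R)]
    subjects = []
    for series in study.series:
        paths = write_subject_series(series, out_dir / series.subject_id, labels)
        subjects.append({"id": series.subject_id, "group": series.group,
                         "files": [str(p.relative_to(out_dir)) for p in paths]})
    manifest = {
        "model": {"rois": labels, "order": spec.K,
                  "conditions": list(spec.conditions),
                  "groups": list(spec.groups)},
        "design": {"sessions": study.truth.design.sessions,
                   "scans_per_session": study.truth.design.scans_per_session,
                   "block_length": study.truth.design.block_length,
                   "condition_order": list(study.truth.design.condition_order),
                   "TR": study.truth.design.TR},
        "subjects": subjects,
    }
    (out_dir / "study.json").write_text(json.dumps(manifest, indent=2))
    truth = {
        "seed": study.truth.seed,
        "noise_var": study.truth.noise_var.tolist(),
        "deviation_sd": study.truth.deviation_sd.tolist(),
        "coefficients": {
            f"{g}.{c}.{k}": study.truth.coefficients.matrices[(g, c, k)].tolist()
            for g in spec.groups for c in spec.conditions
            for k in range(1, spec.K + 1)},
        "xi": {sid: x.tolist() for sid, x in study.xi.items()},
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return out_dir


def read_study(data_dir: str | Path) -> tuple[list[SubjectSeries], ModelSpec,
                                              BlockDesign, list[str]]:
    """Read a study directory written by :func:`write_study` (or hand-built
    in the same layout)."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "study.json"
    if not manifest_path.exists():
        raise ConfigurationError(f"missing study manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    model, des = manifest["model"], manifest["design"]
    roi_labels = [str(r) for r in model["rois"]]
    spec = ModelSpec(R=len(roi_labels), K=int(model["order"]),
                     conditions=tuple(model["conditions"]),
                     groups=tuple(model["groups"]))
    design = BlockDesign(sessions=int(des["sessions"]),
                         scans_per_session=int(des["scans_per_session"]),
                         block_length=int(des["block_length"]),
                         condition_order=tuple(des["condition_order"]),
                         TR=float(des["TR"]))
    W = make_block_indicators(design, spec.conditions)
    series = []
    for sub in manifest["subjects"]:
        parts = []
        for f in sub["files"]:
            Y, labels = read_session_csv(data_dir / f)
            if labels != roi_labels:
                raise ConfigurationError(
                    f"{f}: ROI columns {labels} do not match manifest {roi_labels}")
            parts.append(Y)
        Y = np.vstack(parts)
        if Y.shape[0] != design.T:
            raise ConfigurationError(
                f"subject {sub['id']}: {Y.shape[0]} scans, design expects {design.T}")
        series.append(SubjectSeries(subject_id=sub["id"], group=sub["group"],
                                    Y=Y, W=W,
                                    session_starts=design.session_starts))
    return series, spec, design, roi_labels


def data_digest(series_list: list[SubjectSeries]) -> str:
    h = hashlib.sha256()
    for s in series_list:
        h.update(s.subject_id.encode())
        h.update(s.group.encode())
        h.update(np.ascontiguousarray(s.Y).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# posterior tables
# ---------------------------------------------------------------------------


def _phi_columns(spec: ModelSpec) -> list[str]:
    return [".".join(map(str, spec.coef_label(j)))
            for j in range(spec.G * spec.q)]


def write_posterior(post: PosteriorSamples, out_dir: str | Path,
                    manifest_extra: dict | None = None) -> Path:
    """One CSV per parameter family plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = post.spec
    phi_cols = _phi_columns(spec)
    fmt = "%.10g"
    pd.DataFrame(post.phi, columns=phi_cols).to_csv(
        out_dir / "phi.csv", index=False, float_format=fmt)
    pd.DataFrame(post.alpha, columns=phi_cols).to_csv(
        out_dir / "alpha.csv", index=False, float_format=fmt)
    qlabels = [".".join(map(str, spec.coef_label(j)[1:])) for j in range(spec.q)]
    xi_cols = [f"{sid}.{lab}" for sid in post.subject_ids for lab in qlabels]
    pd.DataFrame(post.xi.reshape(post.n_draws, -1), columns=xi_cols).to_csv(
        out_dir / "xi.csv", index=False, float_format=fmt)
    d_cols = [f"{g}.{lab}" for g in spec.groups for lab in qlabels]
    pd.DataFrame(post.d.reshape(post.n_draws, -1), columns=d_cols).to_csv(
        out_dir / "d.csv", index=False, float_format=fmt)
    pd.DataFrame(post.tau, columns=[f"tau.{r}" for r in range(spec.R)]).to_csv(
        out_dir / "tau.csv", index=False, float_format=fmt)
    pd.DataFrame({"lambda2": post.lambda2, "gamma": post.gamma}).to_csv(
        out_dir / "scalars.csv", index=False, float_format=fmt)
    manifest = {
        "model": {"R": spec.R, "K": spec.K, "conditions": list(spec.conditions),
                  "groups": list(spec.groups)},
        "subjects": [{"id": i, "group": g}
                     for i, g in zip(post.subject_ids, post.subject_groups)],
        "sampler": asdict(post.config),
        "hyperparameters": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in asdict(post.hyper).items()},
        "n_draws": post.n_draws,
        "geweke_max_abs_z": post.geweke_summary(),
        **(post.provenance or {}),
        **(manifest_extra or {}),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_posterior(in_dir: str | Path) -> PosteriorSamples:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigurationError(f"missing posterior manifest {manifest_path}")
    m = json.loads(manifest_path.read_text())
    spec = ModelSpec(R=int(m["model"]["R"]), K=int(m["model"]["K"]),
                     conditions=tuple(m["model"]["conditions"]),
                     groups=tuple(m["model"]["groups"]))
    ids = [s["id"] for s in m["subjects"]]
    groups = [s["group"] for s in m["subjects"]]
    arrays = {}
    for fam in ("phi", "alpha", "xi", "d", "tau", "scalars"):
        p = in_dir / f"{fam}.csv"
        if not p.exists():
            raise ConfigurationError(f"missing posterior family file {p}")
        arrays[fam] = pd.read_csv(p).to_numpy(dtype=float)
    N = arrays["phi"].shape[0]
    return PosteriorSamples(
        spec=spec, subject_ids=ids, subject_groups=groups,
        config=SamplerConfig(**m["sampler"]),
        hyper=HyperParams(**m["hyperparameters"]),
        phi=arrays["phi"], alpha=arrays["alpha"],
        xi=arrays["xi"].reshape(N, len(ids), spec.q),
        d=arrays["d"].reshape(N, spec.G, spec.q),
        tau=arrays["tau"], lambda2=arrays["scalars"][:, 0],
        gamma=arrays["scalars"][:, 1],
        provenance={k: m[k] for k in ("data_digest",) if k in m})


# ---------------------------------------------------------------------------
# network and summary outputs
# ---------------------------------------------------------------------------


def write_network(result, out_path: str | Path,
                  roi_labels: list[str] | None = None) -> Path:
    """TSV edge list; a sibling ``.graphml`` is written alongside."""
    import networkx as nx

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df = result.to_dataframe()
    if roi_labels is not None:
        df["source"] = [roi_labels[s] for s in df["source"]]
        df["target"] = [roi_labels[t] for t in df["target"]]
    df.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    nx.write_graphml(result.to_graph(roi_labels), out_path.with_suffix(".graphml"))
    return out_path


def read_network_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
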