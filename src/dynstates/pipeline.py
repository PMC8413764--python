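"""End-to-end orchestration: simulate, prep, dFC, states, metrics, stats.

``analyze_cohort`` is the library entry point working on in-memory
subjects; ``run_pipeline`` is the file-based driver behind the command
line, reading a YAML study configuration and writing TSV/JSON outputs plus
a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, dfc, io, stats
from .metrics import temporal_properties
from .prep import PrepConfig, preprocess_subject
from .synthetic import CohortConfig, CovariateModel, NuisanceConfig, ScoreModel, generate_cohort


@dataclass
class AnalysisResult:
    state_model: clustering.StateModel
    elbow: clustering.ElbowCurve | None
    labels_by_subject: list[np.ndarray]
    metrics: pd.DataFrame  # one row per subject
    subject_centroids: np.ndarray  # n_subjects x k x P (NaN = absent state)
    group_centroids: dict
    temporal_stats: pd.DataFrame
    fc_strength: pd.DataFrame | None
    partial_correlations: pd.DataFrame
    occupancy_pct: np.ndarray  # percent of all windows per state
    n_windows: int


def metrics_dataframe(labels_by_subject, subjects, k: int) -> pd.DataFrame:
    rows = []
    for labels, sub in zip(labels_by_subject, subjects):
        props = temporal_properties(labels, k)
        row = {
            "subject_id": sub.subject_id,
            "group": sub.group,
            "age": sub.age,
            "sex": sub.sex,
            "education": sub.education,
            "sdmt": sub.sdmt,
            "tmt_a": sub.tmt_a,
            "n_transitions": props.n_transitions,
        }
        for s in range(1, k + 1):
            row[f"frac_state_{s}"] = props.fractional_windows[s - 1]
            row[f"dwell_state_{s}"] = props.mean_dwell_time[s - 1]
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    subjects,
    prep_config: PrepConfig | None = None,
    width: int = 30,
    sigma: float = 3.0,
    step: int = 1,
    lasso_penalty: float = 0.1,
    residualize: bool = True,
    k: int | str = 4,
    n_replicates: int = 500,
    k_range=range(2, 11),
    seed: int = 0,
    run_fc_strength: bool = True,
) -> AnalysisResult:
    """Run prep, windowed connectivity, clustering, metrics, and stats.

    ``k`` may be an integer or ``"auto"`` to select the state count by the
    elbow criterion over ``k_range``.
    """
    prep_cfg = prep_config or PrepConfig()
    series = []
    for sub in subjects:
        clean = preprocess_subject(sub.data, sub.tr_seconds, sub.motion, prep_cfg)
        series.append(
            dfc.subject_windowed_fc(
                clean, sub.subject_id, width=width, sigma=sigma, step=step,
                lasso_penalty=lasso_penalty,
            )
        )
    n_windows = series[0].z_matrices.shape[0]
    z_stack = np.stack([s.z_vectors for s in series])  # n_subj x n_win x P
    if residualize:
        z_stack = dfc.residualize_connectivity(
            z_stack, [s.age for s in subjects], [s.sex for s in subjects]
        )
    pooled = z_stack.reshape(-1, z_stack.shape[-1])
    elbow = None
    if k == "auto":
        elbow = clustering.elbow_select_k(pooled, k_range, n_replicates=n_replicates, seed=seed)
        k = elbow.selected_k
    model = clustering.cluster_states(pooled, int(k), n_replicates=n_replicates, seed=seed)
    labels_by_subject = model.split_by_subject([n_windows] * len(subjects))
    metrics = metrics_dataframe(labels_by_subject, subjects, model.k)
    subj_centroids = clustering.subject_state_centroids(z_stack, labels_by_subject, model.k)
    groups = np.array([s.group for s in subjects])
    group_centroids = {
        g: clustering.group_state_centroids(subj_centroids, groups == g)
        for g in dict.fromkeys(groups)
    }
    temporal_stats = stats.temporal_group_comparison(metrics)
    fc_strength = None
    if run_fc_strength and (groups == "patient").any() and (groups == "control").any():
        try:
            fc_strength = stats.fc_strength_ttest(subj_centroids, groups == "patient")
        except ValueError as exc:
            warnings.warn(f"FC-strength t-tests skipped: {exc}")
    pc_rows = []
    patients = metrics[metrics["group"] == "patient"]
    if len(patients) > 6:
        covs = patients[["age", "sex", "education"]].to_numpy()
        for xcol, ycol in (("n_transitions", "sdmt"), ("dwell_state_1", "tmt_a")):
            res = stats.partial_correlation(
                patients[xcol].to_numpy(), patients[ycol].to_numpy(), covs,
                names=("age", "sex", "education"),
            )
            pc_rows.append({"x": xcol, "y": ycol, "r": res.r, "p": res.p, "n": res.n})
    occupancy = np.array(
        [100.0 * (model.labels == s).mean() for s in range(1, model.k + 1)]
    )
    return AnalysisResult(
        state_model=model,
        elbow=elbow,
        labels_by_subject=labels_by_subject,
        metrics=metrics,
        subject_centroids=subj_centroids,
        group_centroids=group_centroids,
        temporal_stats=temporal_stats,
        fc_strength=fc_strength,
        partial_correlations=pd.DataFrame(pc_rows, columns=["x", "y", "r", "p", "n"]),
        occupancy_pct=occupancy,
        n_windows=n_windows,
    )


# ---------------------------------------------------------------------------
# file-based driver


_ALLOWED_TOP_KEYS = {"seed", "cohort", "prep", "dfc", "states"}
_ALLOWED_DFC_KEYS = {"width", "sigma", "step", "lasso_penalty", "residualize"}
_ALLOWED_STATES_KEYS = {"k", "replicates", "kmin", "kmax"}


def _dataclass_from_dict(cls, values: dict, label: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - fields
    if unknown:
        raise ValueError(f"unknown {label} config keys: {sorted(unknown)}")
    return cls(**values)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _ALLOWED_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in (("dfc", _ALLOWED_DFC_KEYS), ("states", _ALLOWED_STATES_KEYS)):
        extra = set(cfg.get(section, {})) - allowed
        if extra:
            raise ValueError(f"unknown {section} config keys: {sorted(extra)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _build_cohort_config(cfg: dict, seed: int) -> CohortConfig:
    values = dict(cfg.get("cohort", {}))
    nested = {
        "covariates": CovariateModel,
        "score_model": ScoreModel,
        "nuisance": NuisanceConfig,
    }
    for key, cls in nested.items():
        if key in values:
            values[key] = _dataclass_from_dict(cls, values[key], key)
    values.setdefault("seed", seed)
    return _dataclass_from_dict(CohortConfig, values, "cohort")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    started: str
    finished: str = ""
    n_subjects: int = 0
    n_volumes: int = 0
    tr_seconds: float = 0.0
    scan_duration_seconds: float = 0.0
    n_analyzed_volumes: int = 0
    n_windows: int = 0
    selected_k: int = 0
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Run the full study pipeline from a YAML config; write all outputs."""
    cfg = load_config(config_path)
    master_seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(cfg),
        seed=master_seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cohort_cfg = _build_cohort_config(cfg, master_seed)
        subjects, truth = generate_cohort(cohort_cfg)
        io.write_cohort(subjects, truth, out / "cohort")
        manifest.n_subjects = len(subjects)
        manifest.n_volumes = cohort_cfg.n_timepoints
        manifest.tr_seconds = cohort_cfg.tr_seconds
        manifest.scan_duration_seconds = cohort_cfg.n_timepoints * cohort_cfg.tr_seconds
        prep_cfg = _dataclass_from_dict(PrepConfig, dict(cfg.get("prep", {})), "prep")
        manifest.n_analyzed_volumes = cohort_cfg.n_timepoints - prep_cfg.n_discard
        dfc_cfg = dict(cfg.get("dfc", {}))
        states_cfg = dict(cfg.get("states", {}))
        result = analyze_cohort(
            subjects,
            prep_config=prep_cfg,
            width=int(dfc_cfg.get("width", 30)),
            sigma=float(dfc_cfg.get("sigma", 3.0)),
            step=int(dfc_cfg.get("step", 1)),
            lasso_penalty=float(dfc_cfg.get("lasso_penalty", 0.1)),
            residualize=bool(dfc_cfg.get("residualize", True)),
            k=states_cfg.get("k", 4),
            n_replicates=int(states_cfg.get("replicates", 500)),
            k_range=range(
                int(states_cfg.get("kmin", 2)), int(states_cfg.get("kmax", 10)) + 1
            ),
            seed=master_seed,
        )
        manifest.n_windows = result.n_windows
        manifest.selected_k = result.state_model.k
        _write_results(result, out)
        manifest.outputs = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    manifest.warnings = [str(w.message) for w in caught]
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest


def _write_results(result: AnalysisResult, out: Path) -> None:
    rows = []
    for labels, sid in zip(result.labels_by_subject, result.metrics["subject_id"]):
        for w, s in enumerate(labels):
            rows.append({"subject_id": sid, "window": w, "state": int(s)})
    pd.DataFrame(rows).to_csv(out / "state_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(result.state_model.centroids).to_csv(
        out / "state_centroids.tsv", sep="\t", index=False
    )
    result.metrics.to_csv(out / "temporal_metrics.tsv", sep="\t", index=False)
    result.temporal_stats.to_csv(out / "temporal_stats.tsv", sep="\t", index=False)
    if result.fc_strength is not None:
        result.fc_strength.to_csv(out / "fc_strength_ttests.tsv", sep="\t", index=False)
    result.partial_correlations.to_csv(
        out / "partial_correlations.tsv", sep="\t", index=False
    )
    if result.elbow is not None:
        pd.DataFrame(
            {"k": result.elbow.k_values, "cvi": result.elbow.cvi}
        ).to_csv(out / "elbow_curve.tsv", sep="\t", index=False)
    report = build_report(result)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(out / "report.md", "w") as fh:
        fh.write(render_report(report))


def build_report(result: AnalysisResult) -> dict:
    """Machine-readable summary: occupancy, the 9-row table, correlations."""
    sig = result.temporal_stats[result.temporal_stats["p_fdr"] < 0.05]
    return {
        "k": int(result.state_model.k),
        "n_windows": int(result.n_windows),
        "occupancy_pct": [round(float(v), 2) for v in result.occupancy_pct],
        "temporal_stats": result.temporal_stats.drop(
            columns=[c for c in result.temporal_stats.columns if c.startswith("iqr_")]
        ).to_dict(orient="records"),
        "significant_tests": [
            f"{r.metric} state {r.state}" for r in sig.itertuples()
        ],
        "partial_correlations": result.partial_correlations.to_dict(orient="records"),
    }


def render_report(report: dict) -> str:
    lines = ["# Dynamic connectivity state analysis", ""]
    lines.append(f"States: k = {report['k']}; windows per subject: {report['n_windows']}")
    occ = ", ".join(
        f"state {i + 1}: {v}%" for i, v in enumerate(report["occupancy_pct"])
    )
    lines.append(f"Occupancy across all windows — {occ}")
    lines.append("")
    lines.append("## Temporal properties (Mann-Whitney U, BH-FDR)")
    lines.append("")
    lines.append("| metric | state | z | p (raw) | p (FDR) |")
    lines.append("|---|---|---|---|---|")
    for row in report["temporal_stats"]:
        lines.append(
            f"| {row['metric']} | {row['state']} | {row['z']:.3f} "
            f"| {row['p_raw']:.4g} | {row['p_fdr']:.4g} |"
        )
    lines.append("")
    if report["significant_tests"]:
        lines.append("Significant after FDR: " + "; ".join(report["significant_tests"]))
    else:
        lines.append("None significant after FDR.")
    lines.append("")
    lines.append("## Partial correlations (patients; age/sex/education controlled)")
    lines.append("")
    if report["partial_correlations"]:
        for row in report["partial_correlations"]:
            lines.append(
                f"- {row['x']} vs {row['y']}: r = {row['r']:.3f}, "
                f"p = {row['p']:.4g} (n = {row['n']})"
            )
    else:
        lines.append("- not computed (too few patients)")
    lines.append("")
    return "\n".join(lines)
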