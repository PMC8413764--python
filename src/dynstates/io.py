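"""Plain-text file formats for cohorts and results.

Per-subject time courses are TSV files with one leading ``#`` metadata
line (subject id, group, TR) and the five component columns. Motion
parameters use the six-column whitespace-delimited realignment-parameter
dialect (rp_*.txt). The cohort manifest is a CSV indexing subjects,
covariates, scores, and file paths; the planted truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import COMPONENT_NAMES, SubjectTimeCourses, SyntheticTruth

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "sdmt",
    "tmt_a",
    "timecourse_path",
    "motion_path",
]


def write_timecourse_tsv(subject: SubjectTimeCourses, path: Path) -> None:
    path = Path(path)
    names = COMPONENT_NAMES[: subject.data.shape[1]]
    with open(path, "w") as fh:
        fh.write(
            f"# subject={subject.subject_id} group={subject.group} "
            f"tr={subject.tr_seconds}\n"
        )
        fh.write("\t".join(names) + "\n")
        for row in subject.data:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_timecourse_tsv(path) -> tuple[np.ndarray, dict]:
    """Returns (T x C matrix, metadata dict from the '#' line)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    meta = {}
    if header.startswith("#"):
        for tok in header[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
        skip = 1
    else:
        skip = 0
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df.to_numpy(dtype=float), meta


def write_motion_txt(motion: np.ndarray, path: Path) -> None:
    np.savetxt(path, motion, fmt="%.6f")


def read_motion_txt(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"{path}: expected a T x 6 motion matrix")
    return m


def write_cohort(subjects, truth: SyntheticTruth, out_dir) -> Path:
    """Write per-subject TSVs, motion files, manifest CSV, and truth JSON.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        tc_path = out / f"{sub.subject_id}_timecourses.tsv"
        write_timecourse_tsv(sub, tc_path)
        mo_path = ""
        if sub.motion is not None:
            mo_path = out / f"rp_{sub.subject_id}.txt"
            write_motion_txt(sub.motion, mo_path)
        rows.append(
            {
                "subject_id": sub.subject_id,
                "group": sub.group,
                "age": sub.age,
                "sex": sub.sex,
                "education": sub.education,
                "sdmt": sub.sdmt,
                "tmt_a": sub.tmt_a,
                "timecourse_path": tc_path.name,
                "motion_path": Path(mo_path).name if mo_path else "",
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    payload = {
        "seed": truth.seed,
        "groups": truth.groups,
        "state_covariances": [np.asarray(c).tolist() for c in truth.state_covariances],
        "sequences": [np.asarray(s).tolist() for s in truth.sequences],
        "fractional_windows": truth.fractional_windows.tolist(),
        "mean_dwell_time": truth.mean_dwell_time.tolist(),
        "n_transitions": truth.n_transitions.tolist(),
        "transition_matrices": {
            g: np.asarray(M).tolist() for g, M in truth.transition_matrices.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh)
    return manifest


def load_cohort(manifest_path) -> list[SubjectTimeCourses]:
    """Load subjects back from a manifest CSV (paths relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    subjects = []
    for _, row in df.iterrows():
        tc = base / row["timecourse_path"]
        if not tc.exists():
            raise FileNotFoundError(f"subject {row['subject_id']}: missing {tc}")
        data, meta = read_timecourse_tsv(tc)
        motion = None
        if isinstance(row.get("motion_path"), str) and row["motion_path"]:
            motion = read_motion_txt(base / row["motion_path"])
        subjects.append(
            SubjectTimeCourses(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                data=data,
                tr_seconds=float(meta.get("tr", 2.0)),
                motion=motion,
                age=float(row["age"]),
                sex=int(row["sex"]),
                education=float(row["education"]),
                sdmt=float(row["sdmt"]),
                tmt_a=float(row["tmt_a"]),
            )
        )
    return subjects


def load_truth(truth_path) -> SyntheticTruth:
    with open(truth_path) as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        state_covariances=[np.asarray(c) for c in payload["state_covariances"]],
        sequences=[np.asarray(s, dtype=int) for s in payload["sequences"]],
        fractional_windows=np.asarray(payload["fractional_windows"]),
        mean_dwell_time=np.asarray(payload["mean_dwell_time"]),
        n_transitions=np.asarray(payload["n_transitions"]),
        groups=payload["groups"],
        transition_matrices={
            g: np.asarray(M) for g, M in payload["transition_matrices"].items()
        },
        seed=payload["seed"],
    )
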