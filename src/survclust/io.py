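"""Reading and writing cohorts, assignments and curves.

Tabular cohorts travel as CSV with mandatory ``time`` and ``event`` columns
(UTF-8, header row); every remaining column is a feature, with empty cells
preserved as missing for downstream train-only imputation.  Image cohorts
travel as a compressed array archive plus a CSV manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SurvivalCohort

__all__ = [
    "CohortSchemaError",
    "load_cohort_csv",
    "save_cohort_csv",
    "load_image_cohort",
    "save_image_cohort",
    "save_assignments_csv",
    "write_json",
]


class CohortSchemaError(ValueError):
    """Malformed cohort file: missing columns or invalid values."""


def load_cohort_csv(path):
    """Read ``(features_df, cohort)`` from a cohort CSV.

    Validates positive times and 0/1 events, reporting the first offending
    row (1-based, excluding the header).  A ``label`` column, if present,
    is kept inside the returned feature frame; callers decide whether it is
    ground truth or a feature.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time", "event"):
        if col not in df.columns:
            raise CohortSchemaError(f"{path.name}: missing mandatory column {col!r}")
    times = pd.to_numeric(df["time"], errors="coerce")
    events = pd.to_numeric(df["event"], errors="coerce")
    bad_t = times.isna() | (times <= 0)
    if bad_t.any():
        row = int(np.argmax(bad_t.to_numpy())) + 1
        raise CohortSchemaError(
            f"{path.name}: row {row} has nonpositive or non-numeric time"
        )
    bad_e = ~events.isin((0, 1))
    if bad_e.any():
        row = int(np.argmax(bad_e.to_numpy())) + 1
        raise CohortSchemaError(f"{path.name}: row {row} has non-binary event")
    cohort = SurvivalCohort(times.to_numpy(float), events.to_numpy(int))
    features = df.drop(columns=["time", "event"])
    return features, cohort


def save_cohort_csv(path, cohort: SurvivalCohort, features=None, labels=None) -> None:
    """Write a cohort CSV (``time,event[,label][,f0..f{d-1}]``)."""
    data = {"time": cohort.times, "event": cohort.events}
    if labels is not None:
        data["label"] = np.asarray(labels, dtype=int)
    df = pd.DataFrame(data)
    if features is not None:
        feats = np.asarray(features, dtype=float)
        for j in range(feats.shape[1]):
            df[f"f{j}"] = feats[:, j]
    df.to_csv(path, index=False)


def save_image_cohort(out_dir, images, cohort, labels=None) -> tuple[Path, Path]:
    """Write image stack (npz archive) + manifest CSV; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr_path = out_dir / "images.npz"
    np.savez_compressed(arr_path, images=np.asarray(images))
    manifest = pd.DataFrame(
        {
            "subject_id": np.arange(cohort.n),
            "time": cohort.times,
            "event": cohort.events,
            "index": np.arange(cohort.n),
        }
    )
    if labels is not None:
        manifest["label"] = np.asarray(labels, dtype=int)
    man_path = out_dir / "manifest.csv"
    manifest.to_csv(man_path, index=False)
    return arr_path, man_path


def load_image_cohort(manifest_path):
    """Read ``(images, cohort, labels_or_None)`` written by save_image_cohort."""
    man_path = Path(manifest_path)
    df = pd.read_csv(man_path)
    images = np.load(man_path.parent / "images.npz")["images"]
    if len(images) != len(df):
        raise CohortSchemaError("manifest and image archive disagree on n")
    cohort = SurvivalCohort(df["time"].to_numpy(float), df["event"].to_numpy(int))
    labels = df["label"].to_numpy(int) if "label" in df.columns else None
    return images, cohort, labels


def save_assignments_csv(path, probs: np.ndarray) -> None:
    """Write held-out soft assignments (`subject_id,p_0..p_{k-1},cluster`)."""
    probs = np.asarray(probs, dtype=float)
    df = pd.DataFrame(probs, columns=[f"p_{g}" for g in range(probs.shape[1])])
    df.insert(0, "subject_id", np.arange(len(probs)))
    df["cluster"] = probs.argmax(axis=1)
    df.to_csv(path, index=False)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
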