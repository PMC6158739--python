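"""Readers and writers: NIfTI volumes, CSV tables, YAML configs, JSON manifests.

Voxel coordinates are 0-based internally; world coordinates come from the
NIfTI affine.  Volumes are written as float32 (masks as uint8); tables
round-trip bit-exactly through CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "read_subject_table",
    "write_subject_table",
    "read_measure_table",
    "write_manifest",
    "read_yaml",
    "write_yaml",
    "read_streamlines_json",
    "write_streamlines_json",
]

SUBJECT_COLUMNS = ("subject_id", "mutation_carrier", "eyo", "sex", "education", "cdr_positive")


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine if affine is not None else np.eye(4))
    img.to_filename(str(path))


def load_volume(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask).astype(np.uint8), affine if affine is not None else np.eye(4)
    )
    img.to_filename(str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def read_subject_table(path) -> pd.DataFrame:
    """Read and validate a subject CSV.

    Required columns: subject_id, mutation_carrier, eyo, sex, education,
    cdr_positive.  Duplicate ids and unparseable EYO values raise with the
    offending id / row number; unknown columns are preserved.
    """
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {dup.iloc[0]!r}")
    eyo = pd.to_numeric(df["eyo"], errors="coerce")
    bad = np.flatnonzero(eyo.isna().to_numpy() | ~np.isfinite(eyo.to_numpy(dtype=float, na_value=np.nan)))
    if bad.size:
        raise ValueError(f"unparseable EYO value in row {bad[0] + 2} (1-based incl. header)")
    df["eyo"] = eyo
    for col in ("mutation_carrier", "cdr_positive"):
        df[col] = df[col].astype(bool)
    for col in ("sex", "education"):
        df[col] = pd.to_numeric(df[col])
    if (df["education"] < 0).any():
        raise ValueError("negative education years")
    return df


def write_subject_table(path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, index=False)


def read_measure_table(path) -> pd.DataFrame:
    """Read a tidy long measure table (subject_id, measure, value)."""
    df = pd.read_csv(path)
    missing = {"subject_id", "measure", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"measure table missing columns: {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"])
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_manifest(path, manifest: dict) -> None:
    """Write a deterministic (sorted-keys) JSON manifest."""
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(obj), fh, sort_keys=True)


def write_streamlines_json(path, streamlines: dict) -> None:
    """Streamline bundles as JSON: tract -> list of point lists."""
    payload = {
        tract: [s.points.tolist() for s in bundle] for tract, bundle in streamlines.items()
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_streamlines_json(path) -> dict:
    from .projection import Streamline

    payload = json.loads(Path(path).read_text())
    return {
        tract: [Streamline(points=np.asarray(pts, dtype=float)) for pts in bundle]
        for tract, bundle in payload.items()
    }
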