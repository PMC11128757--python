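"""File formats and run configuration.

Volumes and parcellations travel as NIfTI-1 (``.nii``/``.nii.gz``, identity
affine for synthetic data); cohort manifests and grades as CSV; metrics,
histories and prior sidecars as JSON; run configuration as TOML with a
frozen schema version. Every artifact written by the pipeline embeds the
hash of the configuration that produced it, so a results directory is
traceable to its exact run conditions.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import Parcellation, VolumeSample, stain_grade_table

__all__ = [
    "read_volume", "write_volume", "config_hash", "load_config", "dump_toml",
    "write_cohort", "load_cohort", "write_json", "read_json", "SCHEMA_VERSION",
    "DEFAULT_CONFIG",
]

SCHEMA_VERSION = 1

#: A complete, runnable default configuration (tiny desk-scale cohort).
DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 1,
    "synth": {
        "n_per_class": [12, 10, 8],
        "shape": [16, 16, 16],
        "n_regions": 8,
        "disease_regions": [2, 5],
        "effect_size": 0.2,
        "noise_sd": 0.01,
    },
    "model": {
        "n_classes": 3,
        "encoder_channels": [4, 8],
        "downsample_factor": 4,
    },
    "train": {
        "lam": 5e-5,
        "epochs": 20,
        "micro_batch": 2,
        "accumulation_steps": 4,
        "learning_rate": 3e-3,
    },
    "attribution": {
        "n_background": 4,
        "n_draws": 4,
    },
    "evaluate": {
        "k": 5,
    },
}


# -- NIfTI -------------------------------------------------------------

def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D (or 4D multi-channel) NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # corrupt header, wrong format
        raise ValueError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    return data, np.asarray(img.affine)


def write_volume(grid: np.ndarray, affine: np.ndarray | None, path, descrip: str = "") -> None:
    """Write a 3D/4D grid as NIfTI-1 (float32 on disk, identity affine default)."""
    grid = np.asarray(grid)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(grid.astype(np.float32), affine)
    if descrip:
        img.header["descrip"] = descrip[:79].encode()
    nib.save(img, str(path))


# -- config ------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    """Read and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path, "rb") as fh:
        try:
            cfg = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ValueError(f"invalid TOML in {path}: {exc}") from exc
    if cfg.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"config key 'schema_version' must be {SCHEMA_VERSION}, "
            f"got {cfg.get('schema_version')!r}"
        )
    for section in ("synth", "model", "train"):
        if section not in cfg:
            raise ValueError(f"config is missing the [{section}] section")
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(config: dict, path) -> None:
    """Write a flat-sectioned configuration mapping as TOML."""
    lines = []
    scalars = {k: v for k, v in config.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in config.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for name, table in tables.items():
        lines.append("")
        lines.append(f"[{name}]")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- JSON --------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


# -- cohort directories ------------------------------------------------

def write_cohort(directory, samples: list[VolumeSample], parcellation: Parcellation,
                 effect_map: np.ndarray, cfg_hash: str, grades_seed: int = 0) -> None:
    """Materialize a synthetic cohort on disk.

    Layout: ``volumes/<subject>.nii.gz``, ``parcellation.nii.gz``,
    ``effect_map.nii.gz``, ``manifest.csv`` (subject_id, label, cohort,
    path), ``grades.csv`` (subject_id, region_id, stain, grade) and a
    ``cohort.json`` sidecar carrying the config hash.
    """
    directory = Path(directory)
    (directory / "volumes").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        rel = f"volumes/{s.subject_id}.nii.gz"
        write_volume(s.volume, None, directory / rel, descrip=cfg_hash)
        rows.append({"subject_id": s.subject_id, "label": s.label,
                     "cohort": s.cohort, "path": rel})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    write_volume(parcellation.labels.astype(np.int16), None,
                 directory / "parcellation.nii.gz", descrip=cfg_hash)
    write_volume(effect_map.astype(np.int16), None,
                 directory / "effect_map.nii.gz", descrip=cfg_hash)
    stain_grade_table(samples, seed=grades_seed).to_csv(directory / "grades.csv", index=False)
    write_json({"config_hash": cfg_hash,
                "region_names": {str(k): v for k, v in parcellation.region_names.items()},
                "n_samples": len(samples)},
               directory / "cohort.json")


def load_cohort(directory) -> tuple[np.ndarray, np.ndarray, list[str], Parcellation, pd.DataFrame]:
    """Load a cohort directory back: (X, y, subject_ids, parcellation, grades)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    volumes, labels, sids = [], [], []
    for _, row in manifest.iterrows():
        grid, _ = read_volume(directory / row["path"])
        volumes.append(grid)
        labels.append(int(row["label"]))
        sids.append(str(row["subject_id"]))
    labels_grid, _ = read_volume(directory / "parcellation.nii.gz")
    meta = read_json(directory / "cohort.json")
    names = {int(k): v for k, v in meta["region_names"].items()}
    parc = Parcellation(labels_grid.astype(np.int32), names)
    grades = pd.read_csv(directory / "grades.csv")
    return np.stack(volumes), np.array(labels), sids, parc, grades
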