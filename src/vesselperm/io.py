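"""File I/O: NIfTI-1 volumes, CSV tables, YAML configuration.

Volumes are written as NIfTI-1 with the affine preserved (RAS); 4D
arrays use the last axis for time or flip angle. Malformed files raise
errors that name the offending file.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_table",
    "load_table",
    "load_yaml",
    "save_yaml",
]


def save_nifti(array: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file named
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    return data, img.affine


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CSV file not found: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not read CSV file {path}: {exc}") from exc


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"YAML file not found: {path}")
    try:
        with open(path) as fh:
            out = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise IOError(f"could not parse YAML file {path}: {exc}") from exc
    return out or {}


def save_yaml(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
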