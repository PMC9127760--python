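"""File I/O for the standard formats used by the pipeline.

NIfTI-1 volumes (via nibabel; .nii and .nii.gz), comma-separated subject /
metric / cluster tables (via pandas), 6-column whitespace-delimited motion
parameter files, YAML ``key: value`` configuration files, and plain-text run
manifests with input checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import BoldSeries, ReHoMap, SubjectRecord

__all__ = [
    "read_bold",
    "write_bold",
    "read_reho_map",
    "write_reho_map",
    "read_mask",
    "write_mask",
    "read_motion",
    "write_motion",
    "read_records",
    "write_records",
    "read_config_file",
    "write_config_file",
    "write_manifest",
]

_RECORD_COLUMNS = [
    "subject_id",
    "group",
    "hdrs17",
    "hars14",
    "mmse",
    "trs_ab",
    "trs_c",
    "tetras",
    "age",
    "education",
    "sex",
    "fd_power",
]


def read_bold(path: str | Path, tr_seconds: float | None = None, subject_id: str | None = None) -> BoldSeries:
    """Load a 4D NIfTI volume; TR falls back to the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return BoldSeries(data=data, tr_seconds=tr_seconds, affine=np.asarray(img.affine), subject_id=subject_id)


def write_bold(series: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_zooms(tuple(series.voxel_sizes_mm) + (series.tr_seconds,))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_reho_map(reho: ReHoMap, path: str | Path) -> None:
    """Write a 3D map; the processing stage is recorded in the header descrip."""
    img = nib.Nifti1Image(reho.values, reho.affine)
    img.header["descrip"] = f"reho stage={reho.stage}".encode()
    nib.save(img, str(path))


def read_reho_map(path: str | Path, mask: np.ndarray, subject_id: str | None = None) -> ReHoMap:
    img = nib.load(str(path))
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    stage = "raw"
    for token in descrip.split():
        if token.startswith("stage="):
            stage = token.split("=", 1)[1]
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return ReHoMap(
        values=np.asarray(img.get_fdata(), dtype=np.float64),
        mask=mask,
        stage=stage,
        subject_id=subject_id,
        affine=np.asarray(img.affine),
    )


def read_motion(path: str | Path) -> np.ndarray:
    """6-column whitespace-delimited motion parameters, one row per volume."""
    arr = np.loadtxt(str(path))
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    return arr


def write_motion(motion6: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(motion6), fmt="%.8f")


def write_records(records: list[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records])
    df.to_csv(path, index=False)


def read_records(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        SubjectRecord(**{c: row[c] for c in _RECORD_COLUMNS})
        for _, row in df.iterrows()
    ]


def read_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a key: value mapping")
    return cfg


def write_config_file(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    parameters: dict,
    input_paths: list[str | Path] | None = None,
) -> Path:
    """Record parameters, package version and input checksums for a run."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package": "rehomvpa",
        "version": __version__,
        "parameters": parameters,
        "inputs": {
            str(p): _sha256(Path(p)) for p in (input_paths or []) if Path(p).is_file()
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
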