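"""Shared format readers/writers: NIfTI volumes, CSV tables, YAML configs.

Volumes are plain numpy arrays in on-disk index order (0-based voxel
coordinates, no reorientation); the affine is ``diag(voxel_size)``.  Voxel
volume is always taken from the header zooms so anisotropic acquisitions
(e.g. 1 x 1 x 4 mm FLAIR) are handled correctly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("endowm")


class SchemaError(ValueError):
    """A table or config is missing a required field."""


def voxel_volume_mm3(voxel_size: Sequence[float]) -> float:
    """Volume of one voxel in mm^3 from the (dx, dy, dz) zooms."""
    vs = np.asarray(voxel_size, dtype=float)
    if vs.size != 3 or np.any(vs <= 0):
        raise ValueError(f"voxel_size must be 3 positive reals, got {voxel_size!r}")
    return float(np.prod(vs))


def write_volume(path: str | Path, data: np.ndarray, voxel_size: Sequence[float]) -> Path:
    """Write a 3D array as NIfTI with affine = diag(voxel_size).

    Boolean masks are stored as uint8 so the round trip is bit exact.
    """
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(map(float, voxel_size)) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    path = Path(path)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, voxel zooms in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for provenance stamping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
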