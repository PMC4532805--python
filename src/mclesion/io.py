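"""NIfTI and delimited-table I/O."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from mclesion.reference import ContrastMap, TissueAtlas


def save_volume(path: str | Path, data: np.ndarray, voxel_volume: float = 1.0) -> None:
    """Write a 3D volume as NIfTI with isotropic spacing voxel_volume^(1/3)."""
    spacing = float(voxel_volume) ** (1.0 / 3.0)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (data, voxel volume in mm^3)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), float(np.prod(zooms))


def load_atlas(path: str | Path, label_table: Mapping[int, tuple[str, str]]) -> TissueAtlas:
    data, voxel_volume = load_volume(path)
    return TissueAtlas(labels=np.rint(data).astype(np.int32),
                       label_table=dict(label_table), voxel_volume=voxel_volume)


def load_contrast_map(path: str | Path, contrast: str,
                      subject_id: str = "", cohort: str = "HC") -> ContrastMap:
    data, _ = load_volume(path)
    return ContrastMap(data=np.asarray(data, dtype=float), contrast=contrast,
                       subject_id=subject_id, cohort=cohort)


def config_hash(config: object) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_table(path: str | Path, frame: pd.DataFrame, cfg_hash: str | None = None,
                index: bool = False) -> None:
    """Tab-separated table with an optional provenance comment header."""
    path = Path(path)
    with path.open("w") as fh:
        if cfg_hash is not None:
            fh.write(f"# config_hash: {cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
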