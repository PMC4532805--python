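"""Lesion extraction, localization, volume normalization and z-scoring.

Lesions are connected components of the union of the per-contrast binary
masks. Each surviving lesion (strictly more than ``min_voxels`` voxels) is
assigned a lobe and a tissue type, a TIV-normalized volume, and one z-score
per contrast: the mean over lesion voxels of the voxel intensity
standardized by the reference mean/SD of that voxel's compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from mclesion.core import (
    CONTRASTS,
    LOBES,
    LESION_CORTICAL_I,
    LESION_CORTICAL_II,
    LESION_WM,
    OrphanLesionError,
)
from mclesion.reference import ContrastMap, ReferenceStats, TissueAtlas

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class ZScoreVector:
    """Per-contrast lesion z-scores (dimensionless)."""

    T1: float
    T2: float
    T2star: float
    MTR: float

    def __getitem__(self, contrast: str) -> float:
        return getattr(self, contrast)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CONTRASTS}

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(list(self.as_dict().values()))))


@dataclass
class Lesion:
    """A connected lesion: geometry, location/type, volumes, z-scores.

    ``voxels`` are 0-based grid indices, shape (N, 3).
    """

    id: int
    voxels: np.ndarray
    lobe: str | None = None
    tissue_type: str | None = None
    background_fraction: float = 0.0
    raw_volume: float | None = None
    normalized_volume: float | None = None
    zscores: ZScoreVector | None = None
    compartments: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


def merge_lesion_masks(
    masks: Sequence[np.ndarray], connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Voxelwise union of binary masks, then connected-component labeling.

    Returns the labeled volume and the number of components.
    """
    if not masks:
        raise ValueError("no masks given")
    shapes = {np.asarray(m).shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shape mismatch: {sorted(shapes)}")
    union = np.zeros(next(iter(shapes)), dtype=bool)
    for m in masks:
        union |= np.asarray(m).astype(bool)
    labeled, n = ndimage.label(union, structure=_structure(connectivity))
    return labeled, int(n)


def filter_lesions(labeled: np.ndarray, min_voxels: int = 10) -> list[Lesion]:
    """Keep components with strictly more than ``min_voxels`` voxels."""
    labeled = np.asarray(labeled)
    lesions: list[Lesion] = []
    n = int(labeled.max())
    if n == 0:
        return lesions
    counts = np.bincount(labeled.ravel(), minlength=n + 1)
    new_id = 0
    for lab in range(1, n + 1):
        if counts[lab] > min_voxels:
            new_id += 1
            lesions.append(Lesion(id=new_id, voxels=np.argwhere(labeled == lab)))
    return lesions


def localize_and_type(lesion: Lesion, atlas: TissueAtlas) -> Lesion:
    """Assign the majority lobe and the tissue type in place.

    Tissue type: cortical-II if all non-background voxels are GM, WM if all
    are WM, cortical-I if mixed. Lobe ties break by the fixed lobe order.
    Background voxels are recorded (``background_fraction``) and never
    contribute to typing.
    """
    labs = atlas.labels[tuple(lesion.voxels.T)]
    fg = labs != 0
    if not fg.any():
        raise OrphanLesionError(f"lesion {lesion.id} lies entirely on background")
    lesion.background_fraction = float(np.mean(~fg))
    pairs = [atlas.label_table[int(lab)] for lab in labs[fg]]
    tissues = {t for _, t in pairs}
    if tissues == {"GM"}:
        lesion.tissue_type = LESION_CORTICAL_II
    elif tissues == {"WM"}:
        lesion.tissue_type = LESION_WM
    else:
        lesion.tissue_type = LESION_CORTICAL_I
    lobe_counts: dict[str, int] = {}
    for lobe, _ in pairs:
        lobe_counts[lobe] = lobe_counts.get(lobe, 0) + 1
    # tie-break: highest count, then fixed LOBES ordering
    lesion.lobe = min(lobe_counts, key=lambda lo: (-lobe_counts[lo], LOBES.index(lo)))
    lesion.compartments = sorted(set(pairs))
    return lesion


def normalize_volume(n_voxels: int, voxel_volume: float, tiv: float) -> float:
    """Lesion volume as a fraction of total intracranial volume."""
    if tiv <= 0:
        raise ValueError("tiv must be positive")
    if voxel_volume <= 0:
        raise ValueError("voxel_volume must be positive")
    return n_voxels * voxel_volume / tiv


def lesion_zscore(
    cmap: ContrastMap | np.ndarray,
    lesion: Lesion,
    ref: ReferenceStats,
    atlas: TissueAtlas,
    contrast: str | None = None,
    compartment_mode: str = "voxel",
) -> float:
    """Mean standardized deviation of the lesion from its reference tissue.

    z = (1/N) * sum over lesion voxels of (I(v) - mu_c(v)) / sigma_c(v),
    where c(v) is the voxel's (lobe, tissue) compartment. With
    ``compartment_mode='majority'`` a single compartment (majority vote,
    ties by fixed lobe/tissue order) standardizes every voxel, which is
    identical for homogeneous lesions. Background voxels are excluded.
    """
    if isinstance(cmap, ContrastMap):
        data, contrast = cmap.data, cmap.contrast
    else:
        data = np.asarray(cmap, dtype=float)
        if contrast is None:
            raise ValueError("contrast id required for a bare array")
    if compartment_mode not in ("voxel", "majority"):
        raise ValueError(f"unknown compartment_mode {compartment_mode!r}")

    labs = atlas.labels[tuple(lesion.voxels.T)]
    fg = labs != 0
    if not fg.any():
        raise OrphanLesionError(f"lesion {lesion.id} lies entirely on background")
    values = data[tuple(lesion.voxels.T)][fg]
    labs = labs[fg]

    if compartment_mode == "majority":
        uniq, counts = np.unique(labs, return_counts=True)

        def _rank(i: int) -> tuple[int, int, str]:
            lobe, tissue = atlas.label_table[int(uniq[i])]
            return (-int(counts[i]), LOBES.index(lobe), tissue)

        major = uniq[min(range(len(uniq)), key=_rank)]
        labs = np.full_like(labs, major)

    z_terms = np.empty(values.shape, dtype=float)
    for lab in np.unique(labs):
        lobe, tissue = atlas.label_table[int(lab)]
        stats = ref.get(lobe, tissue, contrast)
        sel = labs == lab
        z_terms[sel] = (values[sel] - stats.mu) / stats.sigma
    return float(z_terms.mean())


def compute_zscores(
    maps: Mapping[str, ContrastMap | np.ndarray],
    lesion: Lesion,
    ref: ReferenceStats,
    atlas: TissueAtlas,
    compartment_mode: str = "voxel",
) -> ZScoreVector:
    z = {
        c: lesion_zscore(maps[c], lesion, ref, atlas, contrast=c, compartment_mode=compartment_mode)
        for c in CONTRASTS
    }
    return ZScoreVector(**z)


def extract_lesions(
    masks: Sequence[np.ndarray],
    atlas: TissueAtlas,
    maps: Mapping[str, ContrastMap | np.ndarray] | None = None,
    ref: ReferenceStats | None = None,
    min_voxels: int = 10,
    connectivity: int = 26,
    tiv: float | None = None,
    max_background_fraction: float = 0.5,
    compartment_mode: str = "voxel",
) -> list[Lesion]:
    """Full per-subject lesion pipeline: merge, filter, localize, z-score.

    Lesions with more than ``max_background_fraction`` of their voxels on
    background are dropped (no reference compartment defines them).
    """
    labeled, _ = merge_lesion_masks(masks, connectivity=connectivity)
    lesions = filter_lesions(labeled, min_voxels=min_voxels)
    if tiv is None:
        tiv = atlas.tiv()
    kept: list[Lesion] = []
    for lesion in lesions:
        localize_and_type(lesion, atlas)
        if lesion.background_fraction > max_background_fraction:
            continue
        lesion.raw_volume = lesion.n_voxels * atlas.voxel_volume
        lesion.normalized_volume = normalize_volume(lesion.n_voxels, atlas.voxel_volume, tiv)
        if maps is not None and ref is not None:
            lesion.zscores = compute_zscores(
                maps, lesion, ref, atlas, compartment_mode=compartment_mode
            )
        kept.append(lesion)
    for new_id, lesion in enumerate(kept, start=1):
        lesion.id = new_id
    return kept


def lesion_table(lesions: Iterable[Lesion], subject_id: str = "") -> pd.DataFrame:
    """Per-lesion summary table (one row per lesion)."""
    rows = []
    for les in lesions:
        row = {
            "subject": subject_id,
            "lesion_id": les.id,
            "lobe": les.lobe,
            "type": les.tissue_type,
            "n_voxels": les.n_voxels,
            "raw_volume_mm3": les.raw_volume,
            "normalized_volume": les.normalized_volume,
        }
        for c in CONTRASTS:
            row[f"z_{c}"] = les.zscores[c] if les.zscores is not None else np.nan
        rows.append(row)
    cols = ["subject", "lesion_id", "lobe", "type", "n_voxels",
            "raw_volume_mm3", "normalized_volume"] + [f"z_{c}" for c in CONTRASTS]
    return pd.DataFrame(rows, columns=cols)
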