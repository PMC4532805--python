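"""Healthy-control reference statistics per (lobe, tissue, contrast).

The reference supplies, for every contrast, the compartmental mean and
standard deviation used to standardize lesion intensities downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from mclesion.core import (
    CONTRASTS,
    DegenerateReferenceError,
    MissingCompartmentError,
)


@dataclass
class TissueAtlas:
    """Lobar tissue parcellation on a 3D integer grid.

    Parameters
    ----------
    labels
        3D integer volume; 0 is background, every other value must appear
        in ``label_table``.
    label_table
        Maps label id -> (lobe, tissue). (lobe, tissue) pairs are unique.
    voxel_volume
        Volume of one voxel in mm^3.
    """

    labels: np.ndarray
    label_table: Mapping[int, tuple[str, str]]
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        pairs = list(self.label_table.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (lobe, tissue) pair in label table")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_table)
        if unknown:
            raise ValueError(f"labels without table entry: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def compartments(self) -> list[tuple[str, str]]:
        """(lobe, tissue) pairs actually present in the label volume."""
        present = set(np.unique(self.labels)) - {0}
        return [self.label_table[lab] for lab in sorted(present)]

    def compartment_mask(self, lobe: str, tissue: str) -> np.ndarray:
        for lab, (lo, ti) in self.label_table.items():
            if (lo, ti) == (lobe, tissue):
                return self.labels == lab
        raise MissingCompartmentError((lobe, tissue))

    def label_for(self, lobe: str, tissue: str) -> int:
        for lab, (lo, ti) in self.label_table.items():
            if (lo, ti) == (lobe, tissue):
                return lab
        raise MissingCompartmentError((lobe, tissue))

    def tiv(self) -> float:
        """Total intracranial volume: all non-background voxels, in mm^3."""
        return float(np.count_nonzero(self.labels)) * self.voxel_volume


@dataclass
class ContrastMap:
    """One subject's 3D quantitative map for one contrast."""

    data: np.ndarray
    contrast: str
    subject_id: str = ""
    cohort: str = "HC"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("contrast map must be 3D")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class CompartmentStats:
    mu: float
    sigma: float
    n_voxels: int


@dataclass
class ReferenceStats:
    """Per-(lobe, tissue, contrast) mean/SD from a healthy-control cohort."""

    table: dict[tuple[str, str, str], CompartmentStats] = field(default_factory=dict)

    def get(self, lobe: str, tissue: str, contrast: str) -> CompartmentStats:
        try:
            return self.table[(lobe, tissue, contrast)]
        except KeyError as exc:
            raise MissingCompartmentError((lobe, tissue, contrast)) from exc

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lobe": k[0], "tissue": k[1], "contrast": k[2],
             "mu": v.mu, "sigma": v.sigma, "n_voxels": v.n_voxels}
            for k, v in sorted(self.table.items())
        ]
        return pd.DataFrame(rows, columns=["lobe", "tissue", "contrast", "mu", "sigma", "n_voxels"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceStats":
        table = {
            (r.lobe, r.tissue, r.contrast): CompartmentStats(float(r.mu), float(r.sigma), int(r.n_voxels))
            for r in frame.itertuples()
        }
        return cls(table)


def compute_reference_stats(
    hc_cohort: Iterable[Mapping[str, ContrastMap]],
    atlas: TissueAtlas,
    contrasts: Iterable[str] = CONTRASTS,
    pooling: str = "voxels",
) -> ReferenceStats:
    """Estimate compartmental reference statistics from HC maps.

    ``pooling='voxels'`` (default) pools all compartment voxels of all HC
    subjects into one sample; ``pooling='subjects'`` first averages within
    each subject, then takes mean/SD over the per-subject means. SDs use the
    n-1 denominator in both cases.

    Raises
    ------
    MissingCompartmentError
        If a tabulated compartment has no voxels in the atlas.
    DegenerateReferenceError
        If a pooled compartment sample has zero variance.
    """
    cohort = list(hc_cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 healthy-control subjects")
    if pooling not in ("voxels", "subjects"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    contrasts = list(contrasts)
    for subject in cohort:
        missing = [c for c in contrasts if c not in subject]
        if missing:
            raise ValueError(f"subject missing contrast maps: {missing}")
        for c in contrasts:
            if subject[c].data.shape != atlas.shape:
                raise ValueError("contrast map shape does not match atlas grid")

    out = ReferenceStats()
    for lobe, tissue in sorted(set(atlas.label_table.values())):
        mask = atlas.labels == atlas.label_for(lobe, tissue)
        if not mask.any():
            raise MissingCompartmentError((lobe, tissue))
        for contrast in contrasts:
            samples = [subject[contrast].data[mask] for subject in cohort]
            if pooling == "voxels":
                pooled = np.concatenate(samples)
                mu = float(np.mean(pooled))
                sigma = float(np.std(pooled, ddof=1))
                n = pooled.size
            else:
                means = np.array([s.mean() for s in samples])
                mu = float(means.mean())
                sigma = float(means.std(ddof=1))
                n = means.size
            if sigma == 0.0:
                raise DegenerateReferenceError(
                    f"zero variance in compartment ({lobe}, {tissue}) for {contrast}"
                )
            out.table[(lobe, tissue, contrast)] = CompartmentStats(mu, sigma, n)
    return out
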