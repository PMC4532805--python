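"""Synthetic multicontrast phantoms with known ground truth.

Generates a block-layout lobar atlas, healthy-control maps with Gaussian
per-compartment contrast distributions, patients carrying connected
lesions whose per-contrast means are shifted by configured effect sizes
(in units of the compartment SD), per-pseudo-contrast lesion masks, and
clinical scores from a known linear model on per-combination mean lesion
volume. Everything is reproducible from a single seed: per-subject random
streams are spawned as ``default_rng([seed, stream, index])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from mclesion.core import (
    CONTRASTS,
    LOBES,
    TISSUES,
    ConfigurationError,
    PlacementError,
)
from mclesion.reference import ContrastMap, TissueAtlas

#: Canonical effect-direction patterns per pathology group, in units of the
#: compartment SD. Group 1: no change; Group 2: isolated T2/T2* increase;
#: Group 3: T1 increase (with inflammation) and normal MTR; Group 4: T1
#: increase with MTR decrease. Magnitude 4 is a free choice large enough to
#: clear the |z| > 2 cut with margin.
DEFAULT_GROUP_EFFECTS: dict[int, dict[str, float]] = {
    1: {"T1": 0.0, "T2": 0.0, "T2star": 0.0, "MTR": 0.0},
    2: {"T1": 0.0, "T2": 4.0, "T2star": 4.0, "MTR": 0.0},
    3: {"T1": 4.0, "T2": 4.0, "T2star": 4.0, "MTR": 0.0},
    4: {"T1": 4.0, "T2": 4.0, "T2star": 4.0, "MTR": -4.0},
}

#: Plausible tissue-level (mean, SD) per contrast; relaxation times in ms,
#: MTR dimensionless. Applied uniformly across lobes by default.
_TISSUE_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("WM", "T1"): (850.0, 50.0),
    ("GM", "T1"): (1400.0, 80.0),
    ("WM", "T2"): (75.0, 5.0),
    ("GM", "T2"): (90.0, 8.0),
    ("WM", "T2star"): (50.0, 5.0),
    ("GM", "T2star"): (60.0, 6.0),
    ("WM", "MTR"): (0.45, 0.03),
    ("GM", "MTR"): (0.35, 0.03),
}

_NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def default_contrast_params() -> dict[tuple[str, str, str], tuple[float, float]]:
    """(lobe, tissue, contrast) -> (mean, SD), identical across lobes."""
    return {
        (lobe, tissue, contrast): _TISSUE_PARAMS[(tissue, contrast)]
        for lobe in LOBES
        for tissue in TISSUES
        for contrast in CONTRASTS
    }


@dataclass
class LesionSpec:
    """Lesions of one pathology group to insert per patient."""

    group: int
    count_per_patient: int
    voxel_range: tuple[int, int] = (15, 30)
    effects: dict[str, float] | None = None  # contrast -> shift in SD units
    tissue: str = "WM"

    def resolved_effects(self) -> dict[str, float]:
        if self.effects is not None:
            return dict(self.effects)
        return dict(DEFAULT_GROUP_EFFECTS[self.group])


@dataclass
class ScoreModel:
    """Linear generator for one clinical score."""

    intercept: float
    coefficients: dict[str, float]  # predictor (signature code or covariate) -> beta
    noise_sd: float = 0.0


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_volume: float = 1.0
    n_hc: int = 8
    n_patients: int = 4
    contrast_params: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=default_contrast_params
    )
    lesion_specs: list[LesionSpec] = field(
        default_factory=lambda: [LesionSpec(group=g, count_per_patient=2) for g in (1, 2, 3, 4)]
    )
    mask_fraction: float = 1.0  # per-pseudo-contrast connected subset fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if self.voxel_volume <= 0:
            raise ConfigurationError("voxel_volume must be positive")
        if self.n_hc < 0 or self.n_patients < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        for key, (_, sd) in self.contrast_params.items():
            if sd < 0:
                raise ConfigurationError(f"negative SD for {key}")
        for spec in self.lesion_specs:
            if spec.group not in (1, 2, 3, 4):
                raise ConfigurationError(f"lesion group must be 1-4, got {spec.group}")
            if spec.voxel_range[0] < 1 or spec.voxel_range[1] < spec.voxel_range[0]:
                raise ConfigurationError("invalid voxel_range")
            if spec.tissue not in TISSUES:
                raise ConfigurationError(f"unknown lesion tissue {spec.tissue!r}")
        if not 0.0 < self.mask_fraction <= 1.0:
            raise ConfigurationError("mask_fraction must be in (0, 1]")


@dataclass
class LesionTruth:
    """Ground truth for one generated lesion."""

    patient: str
    lesion_id: int
    group: int
    effects: dict[str, float]
    expected_code: str
    n_voxels: int
    seed_voxel: tuple[int, int, int]
    lobe: str
    tissue: str
    voxels: np.ndarray  # (N, 3) grid indices


def expected_signature_code(effects: Mapping[str, float]) -> str:
    """Signature implied by the configured effect directions."""
    code = ""
    for c in CONTRASTS:
        e = effects.get(c, 0.0)
        code += "H" if e > 0 else ("L" if e < 0 else "N")
    return code


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def generate_atlas(config: PhantomConfig) -> TissueAtlas:
    """Block-layout atlas: one x-slab per lobe, split into WM/GM along y.

    A one-voxel background border surrounds the labelled interior. Realism
    is not the goal; full (lobe, tissue) coverage is.
    """
    nx, ny, nz = config.grid_shape
    inner_x, inner_y, inner_z = nx - 2, ny - 2, nz - 2
    if inner_x < len(LOBES) or inner_y < len(TISSUES) or inner_z < 1:
        raise ConfigurationError(
            f"grid {config.grid_shape} too small to host {len(LOBES)}x{len(TISSUES)} labels"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    label_table: dict[int, tuple[str, str]] = {}
    x_edges = np.linspace(1, nx - 1, len(LOBES) + 1).astype(int)
    y_edges = np.linspace(1, ny - 1, len(TISSUES) + 1).astype(int)
    lab = 0
    for i, lobe in enumerate(LOBES):
        for j, tissue in enumerate(TISSUES):
            lab += 1
            label_table[lab] = (lobe, tissue)
            labels[x_edges[i]:x_edges[i + 1], y_edges[j]:y_edges[j + 1], 1:nz - 1] = lab
    atlas = TissueAtlas(labels=labels, label_table=label_table, voxel_volume=config.voxel_volume)
    for lab, pair in label_table.items():
        if not np.any(labels == lab):
            raise ConfigurationError(f"grid too small: compartment {pair} received no voxels")
    return atlas


# ---------------------------------------------------------------------------
# Healthy-control maps
# ---------------------------------------------------------------------------

def _check_params(config: PhantomConfig, atlas: TissueAtlas) -> None:
    for pair in set(atlas.label_table.values()):
        for contrast in CONTRASTS:
            if (pair[0], pair[1], contrast) not in config.contrast_params:
                raise ConfigurationError(f"missing contrast_params for {(*pair, contrast)}")


def _mean_sd_maps(
    config: PhantomConfig, atlas: TissueAtlas, contrast: str
) -> tuple[np.ndarray, np.ndarray]:
    mu = np.zeros(atlas.shape, dtype=float)
    sd = np.zeros(atlas.shape, dtype=float)
    for lab, (lobe, tissue) in atlas.label_table.items():
        m, s = config.contrast_params[(lobe, tissue, contrast)]
        sel = atlas.labels == lab
        mu[sel] = m
        sd[sel] = s
    return mu, sd


def _draw_maps(
    config: PhantomConfig,
    atlas: TissueAtlas,
    rng: np.random.Generator,
    subject_id: str,
    cohort: str,
) -> dict[str, ContrastMap]:
    maps = {}
    for contrast in CONTRASTS:
        mu, sd = _mean_sd_maps(config, atlas, contrast)
        data = rng.normal(mu, sd)
        data[atlas.labels == 0] = 0.0
        maps[contrast] = ContrastMap(data=data, contrast=contrast,
                                     subject_id=subject_id, cohort=cohort)
    return maps


def generate_hc_maps(config: PhantomConfig, atlas: TissueAtlas) -> list[dict[str, ContrastMap]]:
    """Per-subject contrast maps; voxel values ~ N(mean, SD) of their label."""
    _check_params(config, atlas)
    cohort = []
    for i in range(config.n_hc):
        rng = np.random.default_rng([config.seed, 0, i])
        cohort.append(_draw_maps(config, atlas, rng, subject_id=f"HC{i:03d}", cohort="HC"))
    return cohort


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------

def _grow_region(
    seed_voxel: tuple[int, int, int],
    allowed: np.ndarray,
    n_target: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]] | None:
    """Random 26-connected region growth inside ``allowed``; None if stuck."""
    shape = allowed.shape
    chosen = {seed_voxel}
    frontier: list[tuple[int, int, int]] = []

    def push_neighbors(v: tuple[int, int, int]) -> None:
        for d in _NEIGHBORS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]
                    and allowed[w] and w not in chosen and w not in frontier):
                frontier.append(w)

    push_neighbors(seed_voxel)
    while len(chosen) < n_target and frontier:
        idx = int(rng.integers(len(frontier)))
        v = frontier.pop(idx)
        chosen.add(v)
        push_neighbors(v)
    if len(chosen) < n_target:
        return None
    return sorted(chosen)


def _place_lesions(
    config: PhantomConfig,
    atlas: TissueAtlas,
    rng: np.random.Generator,
    patient_id: str,
    max_retries: int = 100,
) -> list[LesionTruth]:
    """Place all configured lesions without overlap (one-voxel separation)."""
    blocked = np.zeros(atlas.shape, dtype=bool)
    dilate_struct = np.ones((3, 3, 3), dtype=bool)
    truths: list[LesionTruth] = []
    lesion_id = 0
    for spec in config.lesion_specs:
        labels_of_tissue = [
            lab for lab, (_, tissue) in atlas.label_table.items() if tissue == spec.tissue
        ]
        for _ in range(spec.count_per_patient):
            lesion_id += 1
            n_target = int(rng.integers(spec.voxel_range[0], spec.voxel_range[1] + 1))
            placed = None
            for _attempt in range(max_retries):
                lab = labels_of_tissue[int(rng.integers(len(labels_of_tissue)))]
                allowed = (atlas.labels == lab) & ~blocked
                candidates = np.argwhere(allowed)
                if candidates.size == 0:
                    continue
                seed_voxel = tuple(candidates[int(rng.integers(len(candidates)))])
                voxels = _grow_region(seed_voxel, allowed, n_target, rng)
                if voxels is not None:
                    placed = (lab, seed_voxel, voxels)
                    break
            if placed is None:
                raise PlacementError(
                    f"could not place lesion {lesion_id} ({n_target} voxels) "
                    f"after {max_retries} attempts"
                )
            lab, seed_voxel, voxels = placed
            mask = np.zeros(atlas.shape, dtype=bool)
            mask[tuple(np.array(voxels).T)] = True
            blocked |= ndimage.binary_dilation(mask, structure=dilate_struct)
            effects = spec.resolved_effects()
            truths.append(
                LesionTruth(
                    patient=patient_id,
                    lesion_id=lesion_id,
                    group=spec.group,
                    effects=effects,
                    expected_code=expected_signature_code(effects),
                    n_voxels=n_target,
                    seed_voxel=tuple(int(x) for x in seed_voxel),
                    lobe=atlas.label_table[lab][0],
                    tissue=atlas.label_table[lab][1],
                    voxels=np.array(voxels, dtype=int),
                )
            )
    return truths


def _lesion_subset(
    truth: LesionTruth, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Full lesion, or a random connected subset of >= ``fraction`` of it."""
    if fraction >= 1.0:
        return truth.voxels
    n_sub = max(1, math.ceil(fraction * truth.n_voxels))
    inside = np.zeros(tuple(truth.voxels.max(axis=0) + 2), dtype=bool)
    inside[tuple(truth.voxels.T)] = True
    start = tuple(truth.voxels[int(rng.integers(len(truth.voxels)))])
    voxels = _grow_region(start, inside, n_sub, rng)
    assert voxels is not None  # subset of a connected set is always reachable
    return np.array(voxels, dtype=int)


def generate_patient(
    config: PhantomConfig,
    atlas: TissueAtlas,
    patient_index: int = 0,
    n_masks: int = 3,
) -> tuple[dict[str, ContrastMap], list[np.ndarray], list[LesionTruth]]:
    """One patient: maps with inserted lesions, pseudo-contrast masks, truth.

    Within each lesion, contrast c is drawn from
    N(mean + effect_c * SD, SD) of the host compartment. ``n_masks``
    binary masks are emitted; with ``mask_fraction < 1`` each mask covers a
    random connected subset of each lesion (clamped to >= 60%), exercising
    downstream union-merging.
    """
    _check_params(config, atlas)
    patient_id = f"P{patient_index:03d}"
    rng = np.random.default_rng([config.seed, 1, patient_index])
    maps = _draw_maps(config, atlas, rng, subject_id=patient_id, cohort="patient")
    truths = _place_lesions(config, atlas, rng, patient_id)

    for truth in truths:
        idx = tuple(truth.voxels.T)
        for contrast in CONTRASTS:
            mean, sd = config.contrast_params[(truth.lobe, truth.tissue, contrast)]
            shift = truth.effects.get(contrast, 0.0) * sd
            maps[contrast].data[idx] = rng.normal(mean + shift, sd, size=truth.n_voxels)

    fraction = max(0.6, config.mask_fraction) if config.mask_fraction < 1.0 else 1.0
    masks = []
    for _k in range(n_masks):
        mask = np.zeros(atlas.shape, dtype=np.uint8)
        for truth in truths:
            sub = _lesion_subset(truth, fraction, rng)
            mask[tuple(sub.T)] = 1
        masks.append(mask)
    return maps, masks, truths


def generate_patients(
    config: PhantomConfig, atlas: TissueAtlas
) -> list[tuple[dict[str, ContrastMap], list[np.ndarray], list[LesionTruth]]]:
    return [generate_patient(config, atlas, i) for i in range(config.n_patients)]


def truth_records(
    truth_sets: Sequence[Sequence[LesionTruth]], atlas: TissueAtlas
) -> pd.DataFrame:
    """Ground-truth lesion records in the downstream classification layout.

    One row per generated lesion with its expected signature code, group,
    compartment column, and TIV-normalized volume — the generative side of
    the per-subject predictor matrix.
    """
    from mclesion.classify import compartment_column
    from mclesion.core import LESION_CORTICAL_II, LESION_WM

    tiv = atlas.tiv()
    rows = []
    for truths in truth_sets:
        for t in truths:
            tissue_type = LESION_WM if t.tissue == "WM" else LESION_CORTICAL_II
            rows.append({
                "subject": t.patient,
                "lesion_id": t.lesion_id,
                "code": t.expected_code,
                "group": t.group,
                "column": compartment_column(t.lobe, tissue_type),
                "normalized_volume": t.n_voxels * atlas.voxel_volume / tiv,
            })
    return pd.DataFrame(
        rows, columns=["subject", "lesion_id", "code", "group", "column", "normalized_volume"]
    )


# ---------------------------------------------------------------------------
# Clinical scores
# ---------------------------------------------------------------------------

def generate_covariates(subjects: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Plausible demographic/psychological covariates per subject."""
    rng = np.random.default_rng([seed, 2])
    n = len(subjects)
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(35.0, 9.0, n), 1),
            "gender": rng.integers(0, 2, n).astype(float),
            "education": np.round(np.clip(rng.normal(15.0, 3.0, n), 6, 25), 0),
            "had_anxiety": np.round(np.clip(rng.normal(6.0, 3.0, n), 0, 21), 0),
            "had_depression": np.round(np.clip(rng.normal(4.0, 3.0, n), 0, 21), 0),
        },
        index=pd.Index(list(subjects), name="subject"),
    )


def generate_clinical_scores(
    mlv_table: pd.DataFrame,
    covariates: pd.DataFrame,
    score_model: Mapping[str, ScoreModel],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ScoreModel]]:
    """Scores = intercept + sum(beta * predictor) + Gaussian noise.

    ``mlv_table`` holds per-subject MLV per signature combination;
    coefficients may reference its columns or covariate columns. Returns
    the score table and the generating models (the recorded ground truth).
    """
    design = mlv_table.join(covariates, how="inner")
    if len(design) != len(mlv_table):
        raise ConfigurationError("covariates missing for some subjects")
    rng = np.random.default_rng([seed, 3])
    scores = pd.DataFrame(index=design.index)
    for name, model in score_model.items():
        missing = [p for p in model.coefficients if p not in design.columns]
        if missing:
            raise ConfigurationError(f"score model {name!r} references unknown predictors {missing}")
        if model.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        linear = np.full(len(design), float(model.intercept))
        for pred, beta in model.coefficients.items():
            linear = linear + beta * design[pred].to_numpy(dtype=float)
        scores[name] = linear + rng.normal(0.0, model.noise_sd, len(design))
    return scores, dict(score_model)


def default_score_model() -> dict[str, ScoreModel]:
    """Seven clinical scores driven by the canonical group-effect signatures.

    Predictor codes are the expected signatures of groups 1-4 under the
    default effect patterns. Coefficients are sized for normalized-volume
    predictors of order 1e-3.
    """
    g1 = expected_signature_code(DEFAULT_GROUP_EFFECTS[1])  # NNNN
    g3 = expected_signature_code(DEFAULT_GROUP_EFFECTS[3])  # HHHN
    g4 = expected_signature_code(DEFAULT_GROUP_EFFECTS[4])  # HHHL
    return {
        "MSFC": ScoreModel(2.0, {g4: -300.0, g3: -150.0, "age": -0.005}, noise_sd=0.2),
        "FV": ScoreModel(25.0, {g3: -2000.0, "gender": 1.0}, noise_sd=2.0),
        "SRT": ScoreModel(50.0, {g1: -3000.0, g4: -4000.0}, noise_sd=4.0),
        "SDMT": ScoreModel(55.0, {g1: -2500.0, g3: -1500.0, "age": -0.1}, noise_sd=4.0),
        "Tot10_36": ScoreModel(28.0, {g4: -1500.0}, noise_sd=3.0),
        "FSMC_cog": ScoreModel(20.0, {g4: 2000.0, "had_depression": 0.5}, noise_sd=3.0),
        "FSMC_mot": ScoreModel(22.0, {g4: 2500.0, "age": 0.1}, noise_sd=3.0),
    }
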