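"""End-to-end orchestration: simulate -> reference -> quantify -> classify
-> regress, with provenance.

Each stage writes delimited tables stamped with the configuration hash;
rerunning with the same configuration (including seed) reproduces every
deterministic output bit-for-bit. Inputs are either simulated (``simulate``
config block) or loaded from files (``atlas_path`` + ``manifest_path`` +
``subject_table_path``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from mclesion import __version__, io
from mclesion.core import CONTRASTS, ConfigurationError
from mclesion.classify import enumerate_combinations, lesion_records, subject_predictor_matrix
from mclesion.lesions import extract_lesions, lesion_table
from mclesion.reference import compute_reference_stats
from mclesion.regression import format_report, regress_all
from mclesion import synthetic

log = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "gender", "education", "had_anxiety", "had_depression")


@dataclass
class PipelineConfig:
    """Settings shared by every stage; defaults match the reference method
    (threshold 2, lesions must exceed 10 voxels, 7-way Bonferroni)."""

    out_dir: str = "runs/latest"
    seed: int = 0
    threshold: float = 2.0
    min_voxels: int = 10
    connectivity: int = 26
    compartment_mode: str = "voxel"
    reference_pooling: str = "voxels"
    stepwise_criterion: str = "aic"
    stepwise_alpha: float = 0.05
    bonferroni_m: int = 7
    boxcox_responses: list[str] = field(
        default_factory=lambda: ["FV", "SRT", "SDMT", "Tot10_36", "FSMC_cog", "FSMC_mot"]
    )
    simulate: dict | None = None  # PhantomConfig overrides; None -> load files
    atlas_path: str | None = None
    label_table_path: str | None = None
    manifest_path: str | None = None  # TSV: subject, cohort, kind, contrast, path
    subject_table_path: str | None = None  # TSV: subject, covariates, scores

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def phantom_config_from_dict(raw: dict | None, seed: int) -> synthetic.PhantomConfig:
    raw = dict(raw or {})
    specs = raw.pop("lesion_specs", None)
    if specs is not None:
        raw["lesion_specs"] = [
            synthetic.LesionSpec(**{**s, "voxel_range": tuple(s.get("voxel_range", (15, 30)))})
            for s in specs
        ]
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    raw.setdefault("seed", seed)
    return synthetic.PhantomConfig(**raw)


def _load_label_table(path: str | Path) -> dict[int, tuple[str, str]]:
    frame = io.read_table(path)
    return {int(r.label): (r.lobe, r.tissue) for r in frame.itertuples()}


def _load_cohorts(config: PipelineConfig):
    """Load atlas, HC maps, and patient maps/masks from the file manifest."""
    for fld in ("atlas_path", "label_table_path", "manifest_path"):
        if getattr(config, fld) is None:
            raise ConfigurationError(
                f"missing required configuration field '{fld}' (no simulate block given)"
            )
    atlas = io.load_atlas(config.atlas_path, _load_label_table(config.label_table_path))
    manifest = io.read_table(config.manifest_path)
    hc, patients = [], []
    for subject, sub in manifest.groupby("subject", sort=True):
        cohort = sub["cohort"].iloc[0]
        maps = {}
        masks = []
        for r in sub.itertuples():
            if r.kind == "map":
                maps[r.contrast] = io.load_contrast_map(
                    r.path, r.contrast, subject_id=str(subject), cohort=cohort
                )
            elif r.kind == "mask":
                masks.append(io.load_volume(r.path)[0].astype(bool))
            else:
                raise ConfigurationError(f"unknown manifest kind {r.kind!r}")
        missing = [c for c in CONTRASTS if c not in maps]
        if missing:
            raise ConfigurationError(f"subject {subject}: missing maps for {missing}")
        if cohort == "HC":
            hc.append(maps)
        else:
            if not masks:
                raise ConfigurationError(f"patient {subject}: no lesion masks in manifest")
            patients.append((maps, masks, None))
    return atlas, hc, patients


def _simulate(config: PipelineConfig, out: Path):
    phantom = phantom_config_from_dict(config.simulate, config.seed)
    atlas = synthetic.generate_atlas(phantom)
    io.save_volume(out / "atlas.nii", atlas.labels, atlas.voxel_volume)
    hc = synthetic.generate_hc_maps(phantom, atlas)
    patients = synthetic.generate_patients(phantom, atlas)
    for subject in hc:
        for c in CONTRASTS:
            m = subject[c]
            io.save_volume(out / f"{m.subject_id}_{c}.nii", m.data, atlas.voxel_volume)
    for maps, masks, _truths in patients:
        pid = maps["T1"].subject_id
        for c in CONTRASTS:
            io.save_volume(out / f"{pid}_{c}.nii", maps[c].data, atlas.voxel_volume)
        for k, mask in enumerate(masks):
            io.save_volume(out / f"{pid}_mask{k}.nii", mask, atlas.voxel_volume)
    return atlas, hc, patients


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = io.config_hash(config.to_dict())
    (out / "provenance.json").write_text(
        json.dumps({"config": config.to_dict(), "config_hash": cfg_hash,
                    "version": __version__}, indent=2, default=str)
    )

    if config.simulate is not None:
        log.info("stage: simulate")
        atlas, hc, patients = _simulate(config, out)
    else:
        log.info("stage: load inputs")
        atlas, hc, patients = _load_cohorts(config)

    log.info("stage: reference")
    ref = compute_reference_stats(hc, atlas, pooling=config.reference_pooling)
    io.write_table(out / "reference_stats.tsv", ref.to_frame(), cfg_hash)

    log.info("stage: quantify")
    all_records = []
    tables = []
    for maps, masks, _truths in patients:
        pid = maps["T1"].subject_id
        lesions = extract_lesions(
            masks, atlas, maps=maps, ref=ref,
            min_voxels=config.min_voxels, connectivity=config.connectivity,
            compartment_mode=config.compartment_mode,
        )
        tables.append(lesion_table(lesions, subject_id=pid))
        all_records.append(lesion_records(pid, lesions, threshold=config.threshold))
    lesions_frame = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    io.write_table(out / "lesions.tsv", lesions_frame, cfg_hash)

    log.info("stage: classify")
    records = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame()
    combos = enumerate_combinations(records)
    io.write_table(out / "combinations.tsv", combos, cfg_hash)
    predictors = subject_predictor_matrix(records)
    io.write_table(out / "subject_predictors.tsv", predictors, cfg_hash, index=True)

    log.info("stage: regress")
    if config.simulate is not None:
        # scores come from the generating model applied to ground-truth MLV,
        # so downstream regression is a genuine recovery problem
        truth_recs = synthetic.truth_records([t for _, _, t in patients], atlas)
        truth_predictors = subject_predictor_matrix(truth_recs)
        covariates = synthetic.generate_covariates(list(predictors.index), seed=config.seed)
        model = synthetic.default_score_model()
        model = {k: v for k, v in model.items()
                 if all(p in truth_predictors.columns or p in covariates.columns
                        for p in v.coefficients)}
        scores, _truth = synthetic.generate_clinical_scores(
            truth_predictors, covariates.loc[truth_predictors.index], model, seed=config.seed
        )
        scores = scores.loc[predictors.index]
    else:
        if config.subject_table_path is None:
            log.warning("no subject_table_path given; regression stage skipped")
            return out
        table = io.read_table(config.subject_table_path, index_col="subject")
        covariates = table[[c for c in COVARIATE_COLUMNS if c in table.columns]]
        scores = table.drop(columns=covariates.columns)
        covariates = covariates.loc[predictors.index]
        scores = scores.loc[predictors.index]
    io.write_table(out / "covariates.tsv", covariates, cfg_hash, index=True)
    io.write_table(out / "scores.tsv", scores, cfg_hash, index=True)
    if len(scores) >= 8 and not scores.empty:
        results = regress_all(
            predictors, covariates, scores,
            boxcox_responses=config.boxcox_responses,
            criterion=config.stepwise_criterion,
            alpha=config.stepwise_alpha,
            m=config.bonferroni_m,
        )
        (out / "regression_report.txt").write_text(
            f"# config_hash: {cfg_hash}\n" + format_report(results)
        )
    else:
        log.warning("too few subjects for regression; stage skipped")
    return out
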