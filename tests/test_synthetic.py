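import numpy as np
import pandas as pd
import pytest

from mclesion import synthetic
from mclesion.core import CONTRASTS, ConfigurationError, PlacementError
from mclesion.synthetic import (
    LesionSpec,
    PhantomConfig,
    ScoreModel,
    default_contrast_params,
    expected_signature_code,
    generate_atlas,
    generate_clinical_scores,
    generate_covariates,
    generate_hc_maps,
    generate_patient,
    truth_records,
)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def test_atlas_partitions_non_background(phantom_config, atlas):
    labels = atlas.labels
    present = set(np.unique(labels)) - {0}
    assert present == set(atlas.label_table)  # all 10 compartments present
    assert len(atlas.label_table) == 10
    per_label = {lab: int((labels == lab).sum()) for lab in present}
    assert all(n >= 1 for n in per_label.values())
    assert sum(per_label.values()) + int((labels == 0).sum()) == labels.size


def test_atlas_deterministic(phantom_config):
    a = generate_atlas(phantom_config)
    b = generate_atlas(phantom_config)
    assert np.array_equal(a.labels, b.labels)
    assert a.label_table == b.label_table


def test_atlas_too_small_raises():
    with pytest.raises(ConfigurationError):
        generate_atlas(PhantomConfig(grid_shape=(4, 3, 3)))


# ---------------------------------------------------------------------------
# healthy controls
# ---------------------------------------------------------------------------

def test_hc_zero_sd_gives_exact_mean_map():
    params = {k: (m, 0.0) for k, (m, _) in default_contrast_params().items()}
    cfg = PhantomConfig(grid_shape=(12, 8, 8), n_hc=2, contrast_params=params)
    atlas = generate_atlas(cfg)
    cohort = generate_hc_maps(cfg, atlas)
    for subject in cohort:
        for c in CONTRASTS:
            data = subject[c].data
            for lab, (lobe, tissue) in atlas.label_table.items():
                mean, _ = params[(lobe, tissue, c)]
                assert np.all(data[atlas.labels == lab] == mean)


def test_hc_sample_mean_within_five_se(phantom_config, atlas, hc_cohort):
    cfg = phantom_config
    for lab, (lobe, tissue) in atlas.label_table.items():
        sel = atlas.labels == lab
        n = int(sel.sum()) * len(hc_cohort)
        for c in CONTRASTS:
            mean, sd = cfg.contrast_params[(lobe, tissue, c)]
            pooled = np.concatenate([s[c].data[sel] for s in hc_cohort])
            assert abs(pooled.mean() - mean) < 5 * sd / np.sqrt(n)


def test_hc_cohort_deterministic(phantom_config, atlas):
    a = generate_hc_maps(phantom_config, atlas)
    b = generate_hc_maps(phantom_config, atlas)
    for sa, sb in zip(a, b):
        for c in CONTRASTS:
            assert np.array_equal(sa[c].data, sb[c].data)


def test_hc_missing_params_raises(phantom_config, atlas):
    params = dict(phantom_config.contrast_params)
    params.pop(("frontal", "WM", "T1"))
    cfg = PhantomConfig(grid_shape=phantom_config.grid_shape, n_hc=2, contrast_params=params)
    with pytest.raises(ConfigurationError, match="missing"):
        generate_hc_maps(cfg, atlas)


# ---------------------------------------------------------------------------
# patients
# ---------------------------------------------------------------------------

def test_patient_lesion_bookkeeping(phantom_config, atlas, patient):
    _, masks, truths = patient
    assert len(truths) == sum(s.count_per_patient for s in phantom_config.lesion_specs)
    assert len(masks) == 3
    for truth in truths:
        assert truth.group in (1, 2, 3, 4)
        assert truth.n_voxels == len(truth.voxels)


def test_patient_masks_inside_tissue(atlas, patient):
    # conservation: lesion masks are a subset of non-background atlas voxels
    _, masks, truths = patient
    fg = atlas.labels > 0
    for mask in masks:
        assert np.all(fg[mask.astype(bool)])
    for truth in truths:
        labs = atlas.labels[tuple(truth.voxels.T)]
        assert np.all(labs == atlas.label_for(truth.lobe, truth.tissue))


def test_patient_lesions_disjoint_and_connected(patient, atlas):
    from scipy import ndimage
    _, masks, truths = patient
    seen = set()
    for truth in truths:
        vox = {tuple(v) for v in truth.voxels}
        assert not (vox & seen)
        seen |= vox
        blob = np.zeros(atlas.shape, dtype=bool)
        blob[tuple(truth.voxels.T)] = True
        _, n = ndimage.label(blob, structure=np.ones((3, 3, 3)))
        assert n == 1


def test_patient_deterministic(phantom_config, atlas):
    m1, k1, t1 = generate_patient(phantom_config, atlas, 1)
    m2, k2, t2 = generate_patient(phantom_config, atlas, 1)
    for c in CONTRASTS:
        assert np.array_equal(m1[c].data, m2[c].data)
    for a, b in zip(k1, k2):
        assert np.array_equal(a, b)
    assert [x.voxels.tolist() for x in t1] == [x.voxels.tolist() for x in t2]


def test_group_one_lesions_match_background_distribution(atlas):
    # effect size 0: two-sample location shift estimate within 3 SE of 0
    cfg = PhantomConfig(
        grid_shape=(40, 26, 26), n_hc=0, n_patients=6,
        lesion_specs=[LesionSpec(group=1, count_per_patient=10, voxel_range=(20, 30))],
        seed=23,
    )
    shifts = {c: [] for c in CONTRASTS}
    total = 0
    for i in range(cfg.n_patients):
        maps, _, truths = generate_patient(cfg, atlas, i)
        for truth in truths:
            idx = tuple(truth.voxels.T)
            total += truth.n_voxels
            for c in CONTRASTS:
                mean, sd = cfg.contrast_params[(truth.lobe, truth.tissue, c)]
                shifts[c].append((maps[c].data[idx] - mean).sum() / sd)
    for c in CONTRASTS:
        z = sum(shifts[c]) / total  # standardized mean shift estimate
        assert abs(z) < 3 / np.sqrt(total)


def test_effect_size_fidelity(atlas):
    # empirical mean shift / SD converges to the configured effect size
    effects = {"T1": 3.0, "T2": -1.5, "T2star": 0.0, "MTR": 2.0}
    cfg = PhantomConfig(
        grid_shape=(40, 26, 26), n_patients=4,
        lesion_specs=[LesionSpec(group=3, count_per_patient=8,
                                 voxel_range=(25, 35), effects=effects)],
        seed=5,
    )
    sums = {c: 0.0 for c in CONTRASTS}
    total = 0
    for i in range(cfg.n_patients):
        maps, _, truths = generate_patient(cfg, atlas, i)
        for truth in truths:
            idx = tuple(truth.voxels.T)
            total += truth.n_voxels
            for c in CONTRASTS:
                mean, sd = cfg.contrast_params[(truth.lobe, truth.tissue, c)]
                sums[c] += ((maps[c].data[idx] - mean) / sd).sum()
    for c in CONTRASTS:
        assert sums[c] / total == pytest.approx(effects[c], abs=3 / np.sqrt(total) + 1e-12)


def test_placement_error_when_grid_saturated():
    cfg = PhantomConfig(
        grid_shape=(8, 6, 6),
        lesion_specs=[LesionSpec(group=1, count_per_patient=200, voxel_range=(8, 8))],
    )
    atlas = generate_atlas(cfg)
    with pytest.raises(PlacementError):
        generate_patient(cfg, atlas, 0)


def test_mask_fraction_subsets_are_connected_majorities(atlas):
    from scipy import ndimage
    cfg = PhantomConfig(
        grid_shape=(40, 26, 26), n_patients=1, mask_fraction=0.7,
        lesion_specs=[LesionSpec(group=1, count_per_patient=4, voxel_range=(20, 30))],
        seed=2,
    )
    _, masks, truths = generate_patient(cfg, atlas, 0)
    for truth in truths:
        vox = {tuple(v) for v in truth.voxels}
        for mask in masks:
            covered = {tuple(v) for v in np.argwhere(mask)} & vox
            assert len(covered) >= 0.7 * truth.n_voxels - 1
    # masks never leave the generated lesions
    union = np.zeros(atlas.shape, dtype=bool)
    for truth in truths:
        union[tuple(truth.voxels.T)] = True
    for mask in masks:
        assert np.all(union[mask.astype(bool)])


def test_expected_signature_codes():
    assert expected_signature_code({"T1": 4, "T2": 4, "T2star": 4, "MTR": -4}) == "HHHL"
    assert expected_signature_code({}) == "NNNN"
    assert expected_signature_code({"T2": 4, "T2star": 4}) == "NHHN"


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        PhantomConfig(lesion_specs=[LesionSpec(group=5, count_per_patient=1)])
    with pytest.raises(ConfigurationError):
        PhantomConfig(lesion_specs=[LesionSpec(group=1, count_per_patient=1,
                                               voxel_range=(0, 5))])
    with pytest.raises(ConfigurationError):
        PhantomConfig(mask_fraction=0.0)
    with pytest.raises(ConfigurationError):
        PhantomConfig(grid_shape=(10, 10))


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def _mlv_table(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"P{i:03d}" for i in range(n)], name="subject")
    return pd.DataFrame(
        {"NNNN": np.abs(rng.normal(1e-3, 4e-4, n)),
         "HHHN": np.abs(rng.normal(1e-3, 4e-4, n)),
         "HHHL": np.abs(rng.normal(1e-3, 4e-4, n))},
        index=idx,
    )


def test_noiseless_single_predictor_identity():
    mlv = _mlv_table(10)
    cov = generate_covariates(list(mlv.index), seed=1)
    model = {"S": ScoreModel(intercept=0.0, coefficients={"HHHL": 1.0}, noise_sd=0.0)}
    scores, truth = generate_clinical_scores(mlv, cov, model, seed=1)
    np.testing.assert_allclose(scores["S"].to_numpy(), mlv["HHHL"].to_numpy())
    assert truth["S"].coefficients == {"HHHL": 1.0}


def test_refit_recovers_generating_coefficients():
    import statsmodels.api as sm
    mlv = _mlv_table(200, seed=3)
    cov = generate_covariates(list(mlv.index), seed=3)
    model = {"S": ScoreModel(intercept=5.0,
                             coefficients={"HHHL": -3000.0, "age": 0.2}, noise_sd=1.0)}
    scores, _ = generate_clinical_scores(mlv, cov, model, seed=3)
    X = sm.add_constant(pd.concat([mlv[["HHHL"]], cov[["age"]]], axis=1))
    fit = sm.OLS(scores["S"], X).fit()
    for name, truth in [("const", 5.0), ("HHHL", -3000.0), ("age", 0.2)]:
        assert abs(fit.params[name] - truth) < 3 * fit.bse[name]


def test_unknown_predictor_rejected():
    mlv = _mlv_table(5)
    cov = generate_covariates(list(mlv.index))
    model = {"S": ScoreModel(0.0, {"ZZZZ": 1.0})}
    with pytest.raises(ConfigurationError, match="unknown predictors"):
        generate_clinical_scores(mlv, cov, model)


def test_score_generation_deterministic():
    mlv = _mlv_table(20)
    cov = generate_covariates(list(mlv.index), seed=4)
    model = synthetic.default_score_model()
    model = {k: v for k, v in model.items()
             if all(p in mlv.columns or p in cov.columns for p in v.coefficients)}
    a, _ = generate_clinical_scores(mlv, cov, model, seed=4)
    b, _ = generate_clinical_scores(mlv, cov, model, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_truth_records_layout(atlas, patient, phantom_config):
    _, _, truths = patient
    recs = truth_records([truths], atlas)
    assert len(recs) == len(truths)
    assert set(recs["group"]) == {1, 2, 3, 4}
    assert (recs["normalized_volume"] > 0).all()
    # WM lesions in brain lobes land in the brain WM column
    assert set(recs["column"]) <= {"brain_wm", "cb_wm"}
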