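# mclesion

Multicontrast quantitative-MRI lesion quantification: region-conditional
healthy-control reference statistics, per-lesion z-scores over T1/T2/T2*/MTR,
tri-state combination signatures with pathology-group assignment, mean lesion
volume (MLV) per combination, and a clinical regression stage (Box-Cox,
backward stepwise OLS, Bonferroni correction, leave-one-out cross-validation).
A synthetic phantom generator with full ground truth makes every stage
testable end to end without external data.

## Method overview

1. **Reference** — pool healthy-control voxels per (lobe, tissue, contrast)
   compartment and record mean and SD (n−1 denominator). Lobes: frontal,
   parietal, occipital, temporal, cerebellum; tissues: WM, GM.
2. **Quantify** — union-merge the per-contrast binary lesion masks, label
   26-connected components, keep lesions with **more than 10 voxels**,
   assign the majority lobe and a tissue type (WM / cortical-I mixed /
   cortical-II pure GM), normalize volume by total intracranial volume, and
   compute, per contrast, the mean over lesion voxels of
   `(I(v) − μ) / σ` with each voxel standardized by its own compartment.
3. **Classify** — discretize each z to LOW (z < −2) / NORMAL (−2 ≤ z ≤ 2) /
   HIGH (z > 2); map the 81 signatures onto pathology groups:
   Group 1 (all normal), Group 2 (isolated T2/T2* increase),
   Group 3 (T1 increase, MTR normal), Group 4 (T1 increase with MTR
   decrease), OTHER; tabulate observed combinations with per-compartment
   counts and MLV (total normalized volume / count).
4. **Regress** — per clinical score: optional Box-Cox (ML λ on a grid),
   backward stepwise elimination (AIC default, p-value optional) over the
   per-subject MLV predictors plus covariates (age, gender, education,
   anxiety, depression), Bonferroni over 7 tests, LOO predicted-versus-
   observed adjusted R².

## CLI

```bash
mclesion simulate -c config.yaml -o phantom/      # synthetic cohort + manifest
mclesion reference --atlas ... --label-table ... --manifest ... -o ref.tsv
mclesion quantify  --atlas ... --label-table ... --manifest ... --reference ref.tsv -o lesions.tsv
mclesion classify  --lesions lesions.tsv -o combinations.tsv
mclesion regress   --predictors subject_predictors.tsv --subjects subject_table.tsv
mclesion run -c config.yaml                       # full pipeline from YAML
```

Minimal end-to-end configuration:

```yaml
seed: 0
out_dir: runs/demo
simulate:
  grid_shape: [40, 26, 26]
  n_hc: 6
  n_patients: 10
  lesion_specs:
    - {group: 1, count_per_patient: 2}
    - {group: 3, count_per_patient: 2}
    - {group: 4, count_per_patient: 2}
```

Every output table carries a `# config_hash:` provenance line; reruns with
the same configuration are bit-identical for deterministic stages.

## Layout

- `src/mclesion/synthetic.py` — phantom atlas/maps/lesions/scores with ground truth
- `src/mclesion/reference.py` — compartmental HC statistics
- `src/mclesion/lesions.py` — mask merging, filtering, localization, z-scores
- `src/mclesion/classify.py` — signatures, groups, combination tables, MLV
- `src/mclesion/regression.py` — Box-Cox, stepwise, Bonferroni, LOO CV
- `src/mclesion/pipeline.py`, `cli.py`, `io.py` — orchestration and I/O
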