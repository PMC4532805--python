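import numpy as np
import pytest

from mclesion import synthetic
from mclesion.reference import ContrastMap, TissueAtlas, compute_reference_stats
from mclesion.core import CONTRASTS


@pytest.fixture(scope="session")
def phantom_config():
    return synthetic.PhantomConfig(
        grid_shape=(40, 26, 26),
        n_hc=6,
        n_patients=2,
        lesion_specs=[synthetic.LesionSpec(group=g, count_per_patient=3) for g in (1, 2, 3, 4)],
        seed=11,
    )


@pytest.fixture(scope="session")
def atlas(phantom_config):
    return synthetic.generate_atlas(phantom_config)


@pytest.fixture(scope="session")
def hc_cohort(phantom_config, atlas):
    return synthetic.generate_hc_maps(phantom_config, atlas)


@pytest.fixture(scope="session")
def reference(hc_cohort, atlas):
    return compute_reference_stats(hc_cohort, atlas)


@pytest.fixture(scope="session")
def patient(phantom_config, atlas):
    return synthetic.generate_patient(phantom_config, atlas, 0)


@pytest.fixture
def tiny_atlas():
    """6x6x6 atlas: frontal WM/GM blocks side by side, 1-voxel border."""
    labels = np.zeros((6, 6, 6), dtype=np.int16)
    labels[1:5, 1:3, 1:5] = 1  # frontal WM
    labels[1:5, 3:5, 1:5] = 2  # frontal GM
    return TissueAtlas(
        labels=labels,
        label_table={1: ("frontal", "WM"), 2: ("frontal", "GM")},
        voxel_volume=2.0,
    )


def constant_maps(atlas, value, subject_id="S0", cohort="HC"):
    """All four contrasts set to one constant on non-background voxels."""
    return {
        c: ContrastMap(
            data=np.where(atlas.labels > 0, float(value), 0.0),
            contrast=c, subject_id=subject_id, cohort=cohort,
        )
        for c in CONTRASTS
    }
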