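import numpy as np
import pytest

from mooneyrsa import (
    ROIInfo,
    SimulationConfig,
    compute_rdm,
    generate_behavior,
    generate_patterns,
)


def small_rois():
    return [
        ROIInfo("V1", "Visual", 80, 3),
        ROIInfo("V2", "Visual", 80, 3),
        ROIInfo("FG", "FG", 70, 5),
        ROIInfo("FPN_frontal", "FPN-frontal", 60, 5),
        ROIInfo("FPN_parietal", "FPN-parietal", 60, 5),
        ROIInfo("PCC", "DMN", 60, 4),
    ]


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_subjects=8, rois=small_rois(), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    dataset, truth = generate_patterns(small_config)
    behavior = generate_behavior(small_config, truth)
    return dataset, truth, behavior


@pytest.fixture(scope="session")
def small_rdms(small_cohort):
    dataset, _, _ = small_cohort
    return {
        key: compute_rdm(conds, dataset.image_ids, dataset.categories)
        for key, conds in dataset.patterns.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
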