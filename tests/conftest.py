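import numpy as np
import pytest

from devgeo.cohort import GroundTruthMixture, simulate_patterns
from devgeo.models import categorical_rsms
from devgeo.stimuli import make_stimulus_set, render_stimulus_images


@pytest.fixture(scope="session")
def sset():
    return make_stimulus_set()


@pytest.fixture(scope="session")
def cat_models(sset):
    return categorical_rsms(sset)


@pytest.fixture(scope="session")
def rendered(sset):
    images, masks, truth, specs = render_stimulus_images(sset, seed=11)
    return images, masks, truth, specs


@pytest.fixture(scope="session")
def category_cohort(sset, cat_models):
    """Small cohort with category structure and moderate noise."""
    mixture = GroundTruthMixture(
        weights={"category": (1.0, cat_models["category"].values)},
        sigma_noise=1.0,
    )
    return simulate_patterns(
        sset, mixture, n_subjects=8, runs_per_subject=2, n_voxels=150, seed=42
    )


@pytest.fixture(scope="session")
def noise_cohort(sset):
    """Pure measurement noise: no representational structure at all."""
    mixture = GroundTruthMixture(weights={}, sigma_noise=1.0)
    return simulate_patterns(
        sset, mixture, n_subjects=8, runs_per_subject=1, n_voxels=150, seed=43
    )
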