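import numpy as np
import pytest

from tesdose.phantom import (CohortSpec, build_phantom, sample_morphology,
                             simulate_mri_triplet)
from tesdose.pipeline import RunConfig, run_full_study


@pytest.fixture(scope="session")
def small_spec():
    """Two-subject spec on a 48^3 grid for geometry-level tests."""
    return CohortSpec(n_subjects=2, sex_assignment=("male", "female"),
                      grid_shape=(48, 48, 48), seed=11)


@pytest.fixture(scope="session")
def phantom48(small_spec):
    morph = sample_morphology(small_spec, 0)
    return build_phantom(morph, small_spec, sex="male", subject_id="S000")


@pytest.fixture(scope="session")
def triplet48(phantom48):
    return simulate_mri_triplet(phantom48, noise_sd=0.0)


@pytest.fixture(scope="session")
def study_config(tmp_path_factory):
    """Ten-subject 64^3 end-to-end configuration (shared, run once)."""
    out = tmp_path_factory.mktemp("study")
    return RunConfig(
        cohort=CohortSpec(n_subjects=10, grid_shape=(64, 64, 64), seed=42),
        out_dir=str(out))


@pytest.fixture(scope="session")
def study_bundle(study_config):
    """Full pipeline run used by the acceptance tests (~2 min)."""
    return run_full_study(study_config)
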