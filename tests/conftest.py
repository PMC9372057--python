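import warnings

import pytest

from editscreen.synthetic_cohort import CohortConfig, PlantedEdit, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests: same structure, fewer variants."""
    return CohortConfig(
        seed=7,
        n_germline_per_donor=120,
        reference_length=30_000,
        noise_rate=3.0,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """One cohort at the full default (study-scale) configuration."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def edit_free_config():
    """Single-donor, single-guide cohort with no planted edits."""
    return CohortConfig(
        seed=3,
        n_donors=1,
        guide_names=("AAVS1",),
        timepoints_days=(0, 10),
        planted_edits=(),
    )
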