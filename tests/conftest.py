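import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capsuletex import features, selection, synthgen

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Seed of the reference synthetic cohort used by the end-to-end tests.
COHORT_SEED = 11


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort: 3 classes x 3 patients, 96-px tiles."""
    spec = synthgen.CohortSpec(
        tiles_per_class=(12, 12, 9),
        patients_per_class=(3, 3, 3),
        tile_size=96,
        seed=7,
    )
    return synthgen.make_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort_df():
    """Feature table of the full default cohort (736 tiles over 7/7/5
    patients) rendered at 256 px — the reference cohort for the
    classification-level checks."""
    spec = synthgen.CohortSpec(tile_size=256, seed=COHORT_SEED)
    tiles = synthgen.make_cohort(spec)
    return features.extract_table(tiles)


@pytest.fixture(scope="session")
def default_table(default_cohort_df):
    return selection.FeatureTable.from_dataframe(default_cohort_df)
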