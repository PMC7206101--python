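import numpy as np
import pytest

from vfa import evaluation as ev
from vfa import feature_selection as fs
from vfa import spot_map as sm
from vfa import synthetic_data as syn


@pytest.fixture(scope="session")
def default_map() -> sm.SpotMap:
    """The standard 9x9, seven-condition membrane layout."""
    return sm.generate_spot_map(9, 9, 1.3, sm.default_conditions(), seed=1)


@pytest.fixture(scope="session")
def dose_models():
    return syn.default_dose_models()


@pytest.fixture(scope="session")
def small_cohort(default_map):
    """A reduced cohort (20 samples x 2) for fast unit tests."""
    design = syn.CohortDesign(
        n_hs_samples=20, replicates=2, acute_concentrations=(200.0, 1000.0)
    )
    return syn.simulate_cohort(design, default_map, seed=3)


@pytest.fixture(scope="session")
def paper_scale_splits(default_map):
    """Five seeded study-scale cohorts split into training set + test tests."""
    out = []
    for seed in range(5):
        cohort = syn.simulate_cohort(syn.CohortDesign(), default_map, seed=seed)
        train_t, test_t = ev.partition_train_test(cohort, 0.21, seed=seed)
        training = fs.TrainingSet.from_tests(train_t, default_map)
        out.append((training, test_t))
    return out
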