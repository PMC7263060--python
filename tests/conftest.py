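import pytest

from mirdiag.fixtures import default_cohort_spec, published_confusion_table
from mirdiag.simulate import generate_cohort


@pytest.fixture(scope="session")
def published_table():
    """Published training-set confusion matrix (58 samples)."""
    return published_confusion_table()


@pytest.fixture(scope="session")
def study_like_cohort():
    """Default synthetic training cohort (27 non-NE / 31 NE), fixed seed."""
    return generate_cohort(default_cohort_spec(seed=11))


@pytest.fixture()
def zero_noise_spec():
    """Fully deterministic cohort: all biological and technical SDs zero."""
    return default_cohort_spec(
        seed=0,
        n_per_class={"non-NE": 10, "NE": 10},
        mu_dct={"non-NE": 1.0, "NE": 5.0},
        sigma_dct={"non-NE": 0.0, "NE": 0.0},
        sigma_u6=0.0, sigma_tech=0.0,
        sigma_dct205=0.0, sigma_dct21=0.0,
    )
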