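import pytest

from leafcable.pipeline import analyze
from leafcable.synthetic import TreatmentConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default study design (n=7/condition, noise_cv=0.15), fixed seed."""
    return generate_dataset(TreatmentConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same design with every noise source off: pipeline should be an identity."""
    return generate_dataset(TreatmentConfig(seed=7, noise_cv=0.0, kox_biological_cv=0.0))


@pytest.fixture(scope="session")
def analyzed_default(default_dataset):
    records, truth = default_dataset
    return analyze(records), truth


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_dataset):
    records, truth = noiseless_dataset
    return analyze(records), truth
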