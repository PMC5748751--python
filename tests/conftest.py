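import pytest
from hypothesis import settings

from flavoperm import descriptor_frame, load_dataset, response_series

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """The packaged 30-flavonoid Caco-2 study dataset."""
    return load_dataset("fang2017")


@pytest.fixture(scope="session")
def train_Xy(study):
    return descriptor_frame(study, "training"), response_series(study, "training")


@pytest.fixture(scope="session")
def test_Xy(study):
    return descriptor_frame(study, "test"), response_series(study, "test")
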