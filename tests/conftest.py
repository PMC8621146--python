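import numpy as np
import pytest

from frimeta import Study2x2, read_studies
from frimeta.fri import load_reference_phenotypes


@pytest.fixture
def toy_study() -> Study2x2:
    return Study2x2(study_id="toy", disease="d", tp=10, fp=2, fn=3, tn=15)


@pytest.fixture(scope="session")
def fixture_path():
    from importlib import resources

    with resources.as_file(
        resources.files("frimeta.data").joinpath("synthetic_studies.csv")
    ) as path:
        yield path


@pytest.fixture(scope="session")
def fixture_studies(fixture_path):
    return read_studies(fixture_path)


@pytest.fixture(scope="session")
def reference_profiles():
    with pytest.warns(UserWarning):
        return load_reference_phenotypes()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
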