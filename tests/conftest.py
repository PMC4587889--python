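import numpy as np
import pytest

from compostom import synthetic_data as sd


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Canonical synthetic fixture set, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    sd.write_fixture_set(out, seed=20240901)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
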