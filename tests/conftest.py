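import numpy as np
import pytest

from mclspace import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smiles_records():
    return fixtures.generate_smiles_set()


@pytest.fixture
def small_feature_table():
    spec = fixtures.FixtureSpec(n=400, seed=7)
    return fixtures.generate_feature_table(spec)
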