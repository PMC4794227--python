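import numpy as np
import pytest

from entprise import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """4 proteins x 50 variants with a strong planted entropy signal."""
    return make_dataset(SyntheticSpec(n_proteins=4, variants_per_protein=50, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
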