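import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gbf1_annotation():
    from lpfoot.datasets import load_gbf1_annotation

    return load_gbf1_annotation()


@pytest.fixture(scope="session")
def gbf1_epitope():
    from lpfoot.datasets import GBF1_EPITOPE

    return GBF1_EPITOPE


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
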