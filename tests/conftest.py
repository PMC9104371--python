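import numpy as np
import pytest

from trisent.synthetic_data import LexiconConfig, StratumSpec, default_lexicon
from trisent.text_prep import default_stopwords


@pytest.fixture(scope="session")
def lexicon() -> LexiconConfig:
    return default_lexicon(seed=11)


@pytest.fixture(scope="session")
def stopwords() -> frozenset[str]:
    return default_stopwords()


@pytest.fixture
def small_strata() -> list[StratumSpec]:
    return [
        StratumSpec("Spain", "student", 5, 3, 2),
        StratumSpec("Colombia", "staff", 4, 2, 4),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
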