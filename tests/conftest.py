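import numpy as np
import pytest

from hbosval.features import extract_features
from hbosval.reference import HistogramBuilder, accumulate
from hbosval.structure_io import deduplicate_chains
from hbosval.synthetic import make_outlier_corpus


@pytest.fixture(scope="session")
def corpus():
    """Reference peptides, probe peptides with planted outliers, truth labels."""
    return make_outlier_corpus(seed=20260926 % 2**31)


@pytest.fixture(scope="session")
def reference_db(corpus):
    """Reference DB built from the corpus's reference peptides."""
    reference, _, _ = corpus
    builder = HistogramBuilder()
    for st in reference:
        for chain in deduplicate_chains(st):
            accumulate(extract_features(chain), builder)
    return builder.finalize()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
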