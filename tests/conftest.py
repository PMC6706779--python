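import numpy as np
import pytest

from alekit.synth_data import GeneUnit, default_unit_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neutral_catalog():
    """Small all-neutral catalog for drift-only simulations."""
    return default_unit_catalog(n_neutral=5, s_generalist=0.0, s_specialist=0.0)


@pytest.fixture
def tiny_catalog():
    """Three-unit catalog with known intervals for annotation tests."""
    return (
        GeneUnit("geneA", "neutral", start=101, end=200),
        GeneUnit("geneB", "neutral", start=301, end=400),
        GeneUnit("geneC", "neutral", start=501, end=600),
    )
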