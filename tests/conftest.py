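import numpy as np
import pytest

from mdtfit import AttributeScale


@pytest.fixture(scope="session")
def myeloma_scales():
    """The three-attribute oncology example: one benefit, two harms.

    PFS = one-year progression-free survival (50-90%, increasing),
    MT = risk of moderate chronic toxicity (45-85%, decreasing),
    ST = risk of severe toxicity (20-80%, decreasing).
    """
    return [
        AttributeScale("PFS", worst=50.0, best=90.0),
        AttributeScale("MT", worst=85.0, best=45.0),
        AttributeScale("ST", worst=80.0, best=20.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
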