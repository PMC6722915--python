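import numpy as np
import pytest

from nemadischarge import mechanics as mech


@pytest.fixture
def carrot_shape():
    """Reference carrot-stylet shape (a=0.2, l=1, d=0.01)."""
    return mech.StyletShape(a=0.2, l=1.0, d=0.01)


@pytest.fixture
def narrow_collar():
    """Narrow elastic collar (beta0 = r0 = 0.005, alpha = Y = 1)."""
    return mech.ElasticRestraint(Y=1.0, alpha=1.0, beta0=0.005)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
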