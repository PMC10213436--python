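import numpy as np
import pytest

from nirquant import SpectraSet, ReferenceValues


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_set(rng):
    """A 6 x 40 random spectra set on an even grid."""
    wn = np.linspace(4000.0, 9000.0, 40)
    A = 0.5 + 0.1 * rng.standard_normal((6, 40))
    return SpectraSet(A, wn, tuple(f"sample-{i}" for i in range(6)))


@pytest.fixture
def small_refs(rng):
    return ReferenceValues(2.5 + 0.5 * rng.standard_normal(6))
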