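import numpy as np
import pytest

import demuxfdr as dx


@pytest.fixture(scope="session")
def bc20():
    """A 20-member [7,3] barcode set, as used in the validation design."""
    full = dx.generate_set(7, 3, rng_seed=1, iterations=60)
    assert len(full) >= 20
    return dx.BarcodeSet(full.barcodes[:20], declared_min_distance=3)


@pytest.fixture(scope="session")
def primed(bc20):
    """The 40 barcoded 27-nt PCR primers (forward + reverse)."""
    return dx.barcoded_primer_set(bc20)


@pytest.fixture(scope="session")
def insert():
    """A synthetic insert standing in for the amplified transcript."""
    return dx.random_sequence(500, np.random.default_rng(424242))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
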