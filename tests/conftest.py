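import numpy as np
import pytest

import confeax as cx


@pytest.fixture(scope="session")
def planted_family():
    """40 proteins, one fully conserved 10-mer planted in ~80% of them."""
    cfg = cx.planted_motif_config(seed=11)
    records, labels, truth = cx.simulate_family(cfg)
    return records, labels, truth


@pytest.fixture(scope="session")
def small_family():
    """A small fast family for I/O and plumbing tests."""
    cfg = cx.planted_motif_config(seed=5, n_proteins=8,
                                  length_range=(80, 120))
    records, labels, truth = cx.simulate_family(cfg)
    return records, labels, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)
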