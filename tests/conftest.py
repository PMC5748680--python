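from __future__ import annotations

import numpy as np
import pytest

from genefam import synthetic_data as synth
from genefam.domain_scan import default_repeat_profile


@pytest.fixture(scope="session")
def profile():
    return default_repeat_profile()


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-family-gene noiseless synthetic genome with planted arrays."""
    models, proteins, truth = synth.simulate_genome(
        n_family_genes=60,
        n_background_genes=500,
        tandem_spec=((2, 3), (3, 2), (4, 1)),
        seed=11,
    )
    return models, proteins, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
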