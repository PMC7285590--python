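import numpy as np
import pytest

from aabench.synthetic import (
    generate_motif_library,
    generate_peptide_dataset,
    generate_ppi_dataset,
)


@pytest.fixture(scope="session")
def peptide_records():
    return generate_peptide_dataset(300, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def ppi_small():
    library = generate_motif_library(4, 12, seed=7)
    proteins, positives = generate_ppi_dataset(
        120, (100, 200), library, n_positive=200, seed=7
    )
    return library, proteins, positives


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
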