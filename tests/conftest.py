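import numpy as np
import pytest

from orfeome import synthetic
from orfeome.synthetic import ContigProfile, LengthParams


@pytest.fixture(scope="session")
def small_refset():
    """Two species x 20 genes, fixed seed."""
    return synthetic.generate_reference_set(
        n_species=2, genes_per_species=20, seed=11,
        length_params=LengthParams(cds_mean=900, cds_sd=200),
    )


@pytest.fixture(scope="session")
def noiseless_assembly(small_refset):
    """Zero-noise contigs + truth derived from small_refset."""
    profile = ContigProfile(substitution_rate=0.0)
    contigs, truth = synthetic.generate_contigs(small_refset, profile, seed=12)
    return contigs, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
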