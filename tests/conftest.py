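import numpy as np
import pytest

from protstoich import abundance as ab
from protstoich import synth


@pytest.fixture(scope="session")
def design():
    return synth.make_design()


@pytest.fixture(scope="session")
def planted(design):
    """Well-separated 3-bicluster matrix (G=60, S=30) plus ground truth."""
    structure = synth.planted_structure(
        design, G=60, K=3, proteins_per_bicluster=15, separation=2.0, noise_sd=0.5
    )
    matrix, _ = synth.simulate_proteome(design, 60, structure, seed=11)
    return matrix, structure


@pytest.fixture
def toy_matrix():
    """3 proteins × 2 samples with one missing cell."""
    return ab.AbundanceMatrix(
        protein_ids=["P1", "P2", "P3"],
        peptide_counts=np.array([1, 2, 3]),
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]]),
        missing_mask=np.array([[False, False], [False, False], [False, True]]),
        sample_ids=["s1", "s2"],
    )
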