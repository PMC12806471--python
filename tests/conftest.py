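import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from hetdti.classifier import ForestConfig
from hetdti.encoder import EncoderConfig
from hetdti.pipeline import Dataset, compute_similarities
from hetdti.synthetic import SyntheticConfig, generate_dataset


SMALL_SYNTH = SyntheticConfig(n_drugs=16, n_proteins=20, n_clusters=2,
                              motif_length=20, interaction_prob_in=0.35,
                              interaction_prob_out=0.04, sequence_noise=0.05,
                              seed=11)

#: small encoder/forest configs keep unit tests quick
SMALL_ENCODER = EncoderConfig(hidden_dims=(32, 16, 8), heads=2, epochs=60, seed=3)
SMALL_FOREST = ForestConfig(n_trees=50, seed=3)


@pytest.fixture(scope="session")
def small_dataset():
    syn = generate_dataset(SMALL_SYNTH)
    return syn


@pytest.fixture(scope="session")
def small_similarities(small_dataset):
    ds = Dataset(drugs=small_dataset.drugs, proteins=small_dataset.proteins,
                 interactions=small_dataset.interactions)
    return compute_similarities(ds)


def random_symmetric_network(rng: np.random.Generator, v: int = 3, m: int = 4):
    """A random valid HeteroNetwork-shaped similarity graph for property tests."""
    from hetdti.hetnet import HeteroNetwork

    n = v + m
    H = rng.random((n, n))
    H = (H + H.T) / 2
    np.fill_diagonal(H, 1.0)
    return HeteroNetwork(drug_ids=[f"d{i}" for i in range(v)],
                         protein_ids=[f"p{i}" for i in range(m)], H=H)
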