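import numpy as np
import pytest

from microsig import preprocess
from microsig.graphs import (
    assemble_hetero_graph,
    build_metabolic_edges,
    build_phylo_edges,
)
from microsig.model import TrainingConfig, train
from microsig.simulate import SynthConfig, generate


TINY_SYNTH = SynthConfig(
    n_species=30, n_samples=60, n_types=3, n_planted_per_type=2,
    n_genera=8, n_compounds=12, seed=7,
)

TINY_TRAIN = dict(
    embedding_dim=64, n_hid=32, n_heads=4, n_layers=2,
    epochs=8, ae_epochs=30, seed=7,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic study shared across tests (30 species x 60 samples)."""
    return generate(TINY_SYNTH)


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    matrix, metadata, metabolic, taxonomy, _ = tiny_dataset
    filtered, _ = preprocess.filter_species(matrix)
    normalized = preprocess.normalize_tss(filtered)
    species = list(normalized.species_ids)
    return assemble_hetero_graph(
        normalized, metadata,
        build_metabolic_edges(species, metabolic),
        build_phylo_edges(species, taxonomy),
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_graph):
    """A quickly trained model for attention/extraction tests."""
    return train(tiny_graph, TrainingConfig(**TINY_TRAIN))
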