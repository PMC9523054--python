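"""Shared fixtures: synthetic corpora with planted ground truth."""

import pytest

import genesem as gs


@pytest.fixture(scope="session")
def planted():
    """2000 contigs, 10 planted 5-token systems over 5 categories at
    insertion rate 0.2, 3 taxonomy groups, no dropout."""
    cfg = gs.SyntheticConfig(
        n_contigs=2000,
        systems=gs.make_systems(10, 5, 5, insertion_rate=0.2),
        group_labels=[("gA", 0.34), ("gB", 0.33), ("gC", 0.33)],
        seed=101,
    )
    corpus, truth = gs.generate_corpus(cfg)
    return cfg, corpus, truth


@pytest.fixture(scope="session")
def small_planted():
    """Cheap corpus for unit tests: 200 contigs, 4 systems over 2 categories."""
    cfg = gs.SyntheticConfig(
        n_contigs=200,
        systems=gs.make_systems(4, 4, 2, insertion_rate=0.4),
        seed=7,
    )
    corpus, truth = gs.generate_corpus(cfg)
    return cfg, corpus, truth


@pytest.fixture(scope="session")
def small_embedding(small_planted):
    _, corpus, _ = small_planted
    return gs.train_embeddings(corpus, dim=16, epochs=3, seed=13)
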