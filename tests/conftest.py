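"""Shared fixtures: small synthetic corpora and prepared model inputs.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

from chemrel.model import Hyperparams
from chemrel.parsetree import right_branching_tree
from chemrel.preprocess import build_vocab, prepare_instances
from chemrel.synthetic import GeneratorConfig, make_corpus, make_embeddings


@pytest.fixture(scope="session")
def small_corpus():
    return make_corpus(GeneratorConfig(n_abstracts=20, seed=11))


@pytest.fixture(scope="session")
def prepared(small_corpus):
    """Instances + trees + embeddings + vocab from the small corpus."""
    sc = small_corpus
    instances, stats = prepare_instances(sc.abstracts, sc.entities, sc.relations)
    trees = [right_branching_tree(i.tokens) for i in instances]
    vocab = build_vocab((t for i in instances for t in i.tokens), min_count=1)
    table = make_embeddings([t for i in instances for t in i.tokens],
                            dim=16, seed=11)
    return instances, trees, table, vocab


@pytest.fixture()
def tiny_hp():
    """Desk-scale hyperparameters used throughout the unit tests."""
    return Hyperparams(hidden_size=8, batch_size=8, epochs=5)


def random_binary_tree(rng: np.random.Generator, n_leaves: int):
    """Uniformly structured random binary tree over synthetic tokens."""
    from chemrel.parsetree import branch, leaf

    nodes = [leaf(f"w{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes) - 1))
        merged = branch(nodes[i], nodes[i + 1])
        nodes[i:i + 2] = [merged]
    return nodes[0]
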