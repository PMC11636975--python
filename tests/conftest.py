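"""Shared fixtures: a small lexicon-separable tagging task and models trained
on it. Training runs are session-scoped so the expensive end-to-end fits are
done once and shared by the training, prediction and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

import dualner as d

TINY_TYPES = tuple(
    d.EntityTypeSpec(name, freq, (2, 4))
    for name, freq in [("alpha", 4.0), ("beta", 2.0), ("gamma", 1.0), ("delta", 1.0)]
)


def tiny_generator_config(seed: int, n_sentences: int) -> d.GeneratorConfig:
    """The synthetic study task: 4 entity types with disjoint lexicons,
    imbalanced 4:2:1:1, short sentences, ~30% of tokens inside entities."""
    return d.GeneratorConfig(
        seed=seed,
        n_sentences=n_sentences,
        sentence_length=(8, 20),
        entity_types=TINY_TYPES,
        entity_density=0.3,
        background_alphabet_size=60,
        lexicon_size=12,
    )


@pytest.fixture(scope="session")
def tiny_corpora() -> tuple[d.Corpus, d.Corpus]:
    train = d.generate_corpus(tiny_generator_config(11, 500), "train")
    dev = d.generate_corpus(tiny_generator_config(12, 100), "dev")
    return train, dev


@pytest.fixture(scope="session")
def trained_tiny(tiny_corpora) -> d.train.TrainResult:
    """Full 30-epoch fused-model fit on the 500-sentence synthetic task."""
    train_c, dev_c = tiny_corpora
    return d.train(d.TrainConfig.tiny_test(seed=1), train_c, dev_c)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
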