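"""Shared fixtures: synthetic corpora and the trained taggers reused by the
benchmark-level tests (training is the expensive step, so it happens once
per session)."""

from __future__ import annotations

import pytest

from stresslens.ner import BiLSTMCRFTagger
from stresslens.synthetic import GeneratorConfig, generate_ner_corpus, generate_topic_corpus

#: Hyperparameters of the synthetic NER recovery benchmark: hidden size is
#: reduced from the reference 200 to 50 and the learning rate raised to a
#: from-scratch-appropriate 0.01 (the 2e-5 default targets fine-tuning).
NER_BENCH = dict(
    hidden_dim=50, lr=0.01, epochs=3, batch_size=32,
    dropout=0.1, embedding_dim=32, seed=7,
)


@pytest.fixture(scope="session")
def planted_topic_corpus():
    """300 docs x 40 tokens from 3 topics with disjoint vocabulary blocks."""
    config = GeneratorConfig(seed=11)
    return generate_topic_corpus(config)


@pytest.fixture(scope="session")
def ner_benchmark():
    """2,000 training / 500 test sentences with planted SEX/EDU/ORG spans."""
    train, _ = generate_ner_corpus(GeneratorConfig(seed=301), n_sentences=2000)
    test, _ = generate_ner_corpus(GeneratorConfig(seed=302), n_sentences=500)
    return train, test


@pytest.fixture(scope="session")
def org_only_corpus():
    """First-stage training data containing only ORG entities."""
    sentences, _ = generate_ner_corpus(
        GeneratorConfig(seed=303), n_sentences=1000, entity_types=("ORG",)
    )
    return sentences


@pytest.fixture(scope="session")
def crf_tagger(ner_benchmark):
    train, _ = ner_benchmark
    return BiLSTMCRFTagger(**NER_BENCH).fit(train)


@pytest.fixture(scope="session")
def argmax_tagger(ner_benchmark):
    train, _ = ner_benchmark
    return BiLSTMCRFTagger(use_crf=False, **NER_BENCH).fit(train)


@pytest.fixture(scope="session")
def two_stage_tagger(org_only_corpus, ner_benchmark):
    train, _ = ner_benchmark
    tagger = BiLSTMCRFTagger(**NER_BENCH)
    tagger.fit(org_only_corpus)
    tagger.fit(train, warm_start=True)
    return tagger


@pytest.fixture
def tiny_overfit_set():
    """30 sentences small enough to memorize."""
    sentences, _ = generate_ner_corpus(GeneratorConfig(seed=41), n_sentences=30)
    return sentences
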