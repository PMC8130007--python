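"""Shared fixtures: scaled-down synthetic corpora so the suite stays fast."""

from __future__ import annotations

import pytest

from altriage import (
    InitialSizes,
    SyntheticSpec,
    generate_corpus,
    paper_like_spec,
)
from altriage.al_engine import FeatureSpace
from altriage.preprocess import build_tdm, select_features


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Miniature study conditions for unit-level engine tests."""
    return SyntheticSpec(
        vocab_size=800,
        n_pos=150,
        n_labeled_neg=120,
        n_random=500,
        hidden_positive_rate=0.02,
        doc_length_mean=60,
        seed=20,
    )


@pytest.fixture(scope="session")
def small_sizes() -> InitialSizes:
    return InitialSizes(
        train_pos=50, train_neg=40, train_random=150, val_pos=50, val_neg=40, val_random=50
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return generate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    corpus, _ = small_corpus
    return select_features(build_tdm(corpus))


@pytest.fixture(scope="session")
def small_fs(small_corpus, small_features):
    corpus, _ = small_corpus
    return FeatureSpace(corpus, small_features)


@pytest.fixture(scope="session")
def midi_corpus():
    """Corpus large enough for the reference first-round set sizes
    (200/200 train, 1000 random-negative train, 200/200/200 validation)."""
    spec = paper_like_spec(n_random=1400, seed=101)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def midi_features(midi_corpus):
    corpus, _ = midi_corpus
    return select_features(build_tdm(corpus))


@pytest.fixture(scope="session")
def midi_fs(midi_corpus, midi_features):
    corpus, _ = midi_corpus
    return FeatureSpace(corpus, midi_features)
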