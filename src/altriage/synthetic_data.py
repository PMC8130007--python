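"""Synthetic abstract corpora with the structure the AL analysis assumes.

Three document classes are emulated with a topic-mixture multinomial
generator: safety-relevant positives, drug-related manually-labeled
negatives (near misses that partially overlap the positives), and a
broad background population standing in for unreviewed PubMed draws,
a small fraction of which are hidden positives. The pipeline consumes
only term counts, so surface realism is unnecessary; stemming is still
exercised by appending inflectional suffixes to a fraction of rendered
tokens. Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, Document, Label, PoolKind

TRUE_POSITIVE = "POSITIVE"
TRUE_LABELED_NEG = "LABELED_NEG_LIKE"
TRUE_BACKGROUND = "BACKGROUND"

_CONSONANTS = "bcdfgkmnprtv"
_VOWELS = "aeiou"
_SUFFIXES = ("s", "ed", "ing")


def _default_mixtures(
    n_topics: int, overlap: float, safety_tail: float
) -> dict[str, np.ndarray]:
    """Class mixing weights over topics.

    Topic roles: 0 = safety/toxicity core (positive-specific), 1 = clinical
    drug studies (shared), 2 = general pharmacology (labeled-negative core),
    3 = general biomedicine (shared), 4..5 = background-only fields. The
    labeled negatives carry a sliver of topic 0 — manually labeled negatives
    are near misses — the background shares a tunable fraction of its mass
    with the labeled-negative topics, and a small safety tail of topic 0
    appears in the background: unreviewed draws include safety-adjacent
    abstracts, which is what makes a positives-vs-random classifier
    genuinely uncertain about part of the pool.
    """
    if n_topics != 6:
        raise ValueError("default mixtures are defined for 6 topics; override them")
    pos = np.array([0.40, 0.30, 0.15, 0.15, 0.0, 0.0])
    lneg = np.array([0.08, 0.17, 0.45, 0.30, 0.0, 0.0])
    rest = 1.0 - safety_tail
    back = np.array(
        [
            safety_tail,
            0.3 * overlap * rest,
            0.2 * overlap * rest,
            0.5 * overlap * rest,
            (1 - overlap) / 2 * rest,
            (1 - overlap) / 2 * rest,
        ]
    )
    return {
        TRUE_POSITIVE: pos / pos.sum(),
        TRUE_LABELED_NEG: lneg / lneg.sum(),
        TRUE_BACKGROUND: back / back.sum(),
    }


@dataclass
class SyntheticSpec:
    vocab_size: int = 5000
    n_pos: int = 600
    n_labeled_neg: int = 400
    n_random: int = 9200
    hidden_positive_rate: float = 0.002
    n_topics: int = 6
    class_topic_mixtures: Mapping[str, Sequence[float]] | None = None
    topic_concentration: float = 0.05
    mixture_concentration: float = 1.5
    doc_length_mean: float = 180.0
    overlap_labeledneg_background: float = 0.5
    background_safety_tail: float = 0.05
    suffix_rate: float = 0.3
    n_filler_terms: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < self.n_topics:
            raise ValueError("vocab_size must be at least n_topics")
        if not (0 <= self.hidden_positive_rate < 0.05):
            raise ValueError("hidden_positive_rate must be in [0, 0.05)")
        if not (0 <= self.overlap_labeledneg_background <= 1):
            raise ValueError("overlap fraction must be in [0, 1]")
        for cls, w in self.mixtures().items():
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"mixture for {cls} must be non-negative and sum to 1")

    def mixtures(self) -> dict[str, np.ndarray]:
        if self.class_topic_mixtures is not None:
            out = {
                c: np.asarray(w, dtype=float) for c, w in self.class_topic_mixtures.items()
            }
            for c in (TRUE_POSITIVE, TRUE_LABELED_NEG, TRUE_BACKGROUND):
                if c not in out or len(out[c]) != self.n_topics:
                    raise ValueError(f"class_topic_mixtures must give {c} over {self.n_topics} topics")
            return out
        return _default_mixtures(
            self.n_topics, self.overlap_labeledneg_background, self.background_safety_tail
        )


@dataclass
class GroundTruth:
    """Per-document true class plus an echo of the generating parameters."""

    true_class: dict[str, str]
    doc_lengths: dict[str, int]
    spec: SyntheticSpec
    seed: int

    def hidden_positive_ids(self, corpus: Corpus) -> list[str]:
        random_ids = set(corpus.pool_ids(PoolKind.RANDOM))
        return [
            i for i, c in self.true_class.items() if c == TRUE_POSITIVE and i in random_ids
        ]


def _make_vocab(rng: np.random.Generator, size: int) -> list[str]:
    """Pronounceable unique base words whose Porter stems stay distinct.

    Words end in a consonant (never y/z/s and never the "-at"-free set
    Porter re-expands awkwardly), so appending -s/-ed/-ing strips back to
    the same stem.
    """
    from ._porter import stem

    words: list[str] = []
    seen_stems: set[str] = set()
    while len(words) < size:
        n_syl = int(rng.integers(2, 4))
        syllables = [
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syl)
        ]
        word = "".join(syllables) + _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
        s = stem(word)
        if s in seen_stems:
            continue
        # a base whose stem changes when suffixed would split one term in two
        if any(stem(word + suf) != s for suf in _SUFFIXES):
            continue
        seen_stems.add(s)
        words.append(word)
    return words


def generate_corpus(spec: SyntheticSpec, seed: int | None = None) -> tuple[Corpus, GroundTruth]:
    """Draw a corpus of positives, labeled negatives and a random pool.

    Per document: a Dirichlet topic mixture centred on its class mixture,
    a Poisson length, multinomial topic counts, and words drawn from each
    topic's Dirichlet word distribution. A small block of filler words is
    appended once per document; their cross-document count SD is exactly
    zero, so the SD feature filter removes them by construction.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    vocab = _make_vocab(rng, spec.vocab_size)
    filler = [f"filler{i}x" for i in range(spec.n_filler_terms)]

    topic_word = rng.dirichlet(
        np.full(spec.vocab_size, spec.topic_concentration), size=spec.n_topics
    )
    topic_cum = np.cumsum(topic_word, axis=1)
    mixtures = spec.mixtures()

    classes: list[tuple[str, str, Label, PoolKind]] = []  # id, class, label, pool
    for i in range(spec.n_pos):
        classes.append((f"POS{i:05d}", TRUE_POSITIVE, Label.POSITIVE, PoolKind.LABELED))
    for i in range(spec.n_labeled_neg):
        classes.append((f"NEG{i:05d}", TRUE_LABELED_NEG, Label.NEGATIVE, PoolKind.LABELED))
    hidden = rng.random(spec.n_random) < spec.hidden_positive_rate
    for i in range(spec.n_random):
        cls = TRUE_POSITIVE if hidden[i] else TRUE_BACKGROUND
        classes.append((f"RND{i:05d}", cls, Label.UNLABELED, PoolKind.RANDOM))

    docs: list[Document] = []
    true_class: dict[str, str] = {}
    doc_lengths: dict[str, int] = {}
    for doc_id, cls, label, pool in classes:
        alpha = mixtures[cls] * spec.mixture_concentration + 1e-6
        mixture = rng.dirichlet(alpha)
        length = max(1, int(rng.poisson(spec.doc_length_mean)))
        topic_counts = rng.multinomial(length, mixture)
        token_idx: list[int] = []
        for t, c in enumerate(topic_counts):
            if c:
                token_idx.extend(
                    np.searchsorted(topic_cum[t], rng.random(c)).tolist()
                )
        rng.shuffle(token_idx)
        tokens = []
        suffix_draw = rng.random(len(token_idx))
        suffix_pick = rng.integers(0, len(_SUFFIXES), size=len(token_idx))
        for j, w in enumerate(token_idx):
            word = vocab[int(w)]
            if suffix_draw[j] < spec.suffix_rate:
                word += _SUFFIXES[int(suffix_pick[j])]
            tokens.append(word)
        tokens.extend(filler)
        n_title = min(8, len(tokens))
        docs.append(
            Document(
                doc_id=doc_id,
                title=" ".join(tokens[:n_title]),
                abstract=" ".join(tokens[n_title:]),
                label=label,
                pool=pool,
            )
        )
        true_class[doc_id] = cls
        doc_lengths[doc_id] = length

    corpus = Corpus(docs, provenance={"source": "synthetic", "seed": seed})
    return corpus, GroundTruth(true_class=true_class, doc_lengths=doc_lengths, spec=spec, seed=seed)


class SyntheticOracle:
    """Ground-truth labeling oracle standing in for manual review.

    Counts every query so manual-labeling effort is auditable; an
    optional noise rate flips labels for robustness experiments.
    """

    def __init__(self, ground_truth: GroundTruth, noise_rate: float = 0.0, seed: int = 0):
        if not (0 <= noise_rate < 1):
            raise ValueError("noise_rate must be in [0, 1)")
        self._truth = ground_truth.true_class
        self.noise_rate = noise_rate
        self._rng = np.random.default_rng(seed)
        self.query_count = 0

    def label(self, doc_id: str) -> Label:
        if doc_id not in self._truth:
            raise KeyError(f"oracle has no ground truth for {doc_id!r}")
        self.query_count += 1
        truth = (
            Label.POSITIVE if self._truth[doc_id] == TRUE_POSITIVE else Label.NEGATIVE
        )
        if self.noise_rate and self._rng.random() < self.noise_rate:
            return Label.NEGATIVE if truth is Label.POSITIVE else Label.POSITIVE
        return truth


def synthetic_oracle(
    ground_truth: GroundTruth, noise_rate: float = 0.0, seed: int = 0
) -> SyntheticOracle:
    return SyntheticOracle(ground_truth, noise_rate=noise_rate, seed=seed)


def paper_like_spec(**overrides) -> SyntheticSpec:
    """The default study conditions: 600+/400- labeled, 9,200 random pool.

    The overlap structure is set so that (a) a classifier trained only on
    positives vs labeled negatives loses precision on the random pool,
    and (b) uncertainty samples concentrate in the class-overlap region —
    the failure modes the validation-updating workflow exists to fix.
    """
    return replace(SyntheticSpec(), **overrides)
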