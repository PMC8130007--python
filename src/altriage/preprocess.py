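"""Text normalization, stemming, term-document matrix, SD feature filter.

The pipeline is deliberately minimal: lowercase, strip punctuation,
drop pure-digit tokens, Porter-stem, count. Terms whose count standard
deviation across documents falls at or below a threshold (default 0.03)
are judged uninformative — they are either near-constant boilerplate or
too rare to discriminate — and removed. No stop-word list and no TF-IDF
weighting: the SD filter is the only pruning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import CountVectorizer

from ._porter import stem
from .corpus_io import Corpus

logger = logging.getLogger(__name__)

_NON_ALNUM = re.compile(r"[^a-z0-9]+")

__all__ = [
    "normalize_and_tokenize",
    "stem",
    "TermDocumentMatrix",
    "FeatureSet",
    "build_tdm",
    "term_sd",
    "select_features",
    "vectorize",
    "write_features_tsv",
    "read_features_tsv",
]


def normalize_and_tokenize(title: str, abstract: str) -> list[str]:
    """Lowercase, replace punctuation with spaces, split, drop digit-only tokens.

    Title and abstract are concatenated with a single space; hyphens count
    as punctuation, so "Drug-Drug" yields two tokens. Single-letter tokens
    are retained.
    """
    text = f"{title} {abstract}".lower()
    tokens = _NON_ALNUM.sub(" ", text).split()
    return [t for t in tokens if not t.isdigit()]


def _analyze(text_pair: tuple[str, str]) -> list[str]:
    return [stem(t) for t in normalize_and_tokenize(*text_pair)]


@dataclass
class TermDocumentMatrix:
    """Counts of stemmed terms (rows) across documents (columns)."""

    terms: list[str]
    doc_ids: list[str]
    counts: sp.csr_matrix  # shape (n_terms, n_docs), non-negative ints

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.terms), len(self.doc_ids)):
            raise ValueError("counts shape does not match terms x doc_ids")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def total_count(self) -> int:
        return int(self.counts.sum())


@dataclass
class FeatureSet:
    """SD-selected term subset; every selected term has SD > sd_threshold."""

    selected_terms: list[str]
    sd_values: dict[str, float]
    sd_threshold: float
    sd_ddof: int = 0  # 0 = population SD (divide by N)

    def __post_init__(self) -> None:
        if not all(t in self.sd_values for t in self.selected_terms):
            raise ValueError("every selected term needs an SD value")

    def __len__(self) -> int:
        return len(self.selected_terms)


def build_tdm(corpus: Corpus) -> TermDocumentMatrix:
    """Count stemmed-term occurrences per document (titles + abstracts).

    Terms are ordered lexicographically so the matrix is reproducible
    bit-for-bit for a given corpus.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a term-document matrix from an empty corpus")
    vec = CountVectorizer(analyzer=_analyze, lowercase=False)
    X = vec.fit_transform([(d.title, d.abstract) for d in corpus])
    terms = vec.get_feature_names_out().tolist()  # lexicographic
    return TermDocumentMatrix(terms=terms, doc_ids=corpus.ids(), counts=X.T.tocsr())


def term_sd(tdm: TermDocumentMatrix, ddof: int = 0) -> np.ndarray:
    """Standard deviation of each term's count vector across documents.

    Population SD by default (``ddof=0``); switchable to the sample
    convention. A single-document matrix has no meaningful spread and is
    rejected.
    """
    n = tdm.n_docs
    if n < 2:
        raise ValueError("term SD needs at least 2 documents")
    counts = tdm.counts
    s = np.asarray(counts.sum(axis=1)).ravel()
    sq = np.asarray(counts.multiply(counts).sum(axis=1)).ravel()
    var = sq / n - (s / n) ** 2
    var = np.maximum(var, 0.0)
    if ddof:
        var = var * n / (n - ddof)
    return np.sqrt(var)


def select_features(
    tdm: TermDocumentMatrix, sd_threshold: float = 0.03, ddof: int = 0
) -> FeatureSet:
    """Keep terms with count SD strictly greater than ``sd_threshold``."""
    if sd_threshold < 0:
        raise ValueError("sd_threshold must be non-negative")
    sds = term_sd(tdm, ddof=ddof)
    keep = sds > sd_threshold
    selected = [t for t, k in zip(tdm.terms, keep) if k]
    logger.info(
        "selected %d/%d terms with SD > %g", len(selected), tdm.n_terms, sd_threshold
    )
    return FeatureSet(
        selected_terms=selected,
        sd_values={t: float(v) for t, v in zip(tdm.terms, sds)},
        sd_threshold=float(sd_threshold),
        sd_ddof=ddof,
    )


def vectorize(corpus: Corpus, features: FeatureSet) -> sp.csr_matrix:
    """Document x selected-term count matrix; out-of-vocabulary stems dropped."""
    if len(features) == 0:
        raise ValueError("empty FeatureSet")
    vec = CountVectorizer(
        analyzer=_analyze, lowercase=False, vocabulary=features.selected_terms
    )
    X = vec.transform([(d.title, d.abstract) for d in corpus])
    empty = int((np.asarray(X.sum(axis=1)).ravel() == 0).sum())
    if empty:
        logger.info("%d documents contain no selected term (all-zero rows)", empty)
    return X.tocsr()


def write_features_tsv(features: FeatureSet, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# sd_threshold={features.sd_threshold!r}\tsd_ddof={features.sd_ddof}",
        "term\tsd",
    ]
    for t in features.selected_terms:
        lines.append(f"{t}\t{features.sd_values[t]!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_features_tsv(path: str | Path) -> FeatureSet:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    meta = dict(kv.split("=", 1) for kv in lines[0].lstrip("# ").split("\t"))
    terms: list[str] = []
    sds: dict[str, float] = {}
    for line in lines[2:]:
        term, sd_str = line.split("\t")
        terms.append(term)
        sds[term] = float(sd_str)
    return FeatureSet(
        selected_terms=terms,
        sd_values=sds,
        sd_threshold=float(meta["sd_threshold"]),
        sd_ddof=int(meta["sd_ddof"]),
    )
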