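"""Sample-acquisition mechanisms for the active-learning loop.

Three mechanisms: uncertainty sampling inside a probability band
(inclusive ends, default [0.4, 0.6]), mining of high-confidence
predicted positives from the random pool (strictly above 0.7, all of
them — they are candidate mislabeled positives and every one goes to
the oracle), and seeded uniform draws that build the random-negative
pool in the first place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import Corpus, Label, PoolKind

logger = logging.getLogger(__name__)


@dataclass
class SamplingConfig:
    band_low: float = 0.4
    band_high: float = 0.6
    high_conf_threshold: float = 0.7
    uncertainty_budget: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.band_low < self.band_high <= 1):
            raise ValueError("need 0 <= band_low < band_high <= 1")
        if not (self.band_high <= self.high_conf_threshold <= 1):
            raise ValueError("need band_high <= high_conf_threshold <= 1")
        if self.uncertainty_budget <= 0:
            raise ValueError("uncertainty_budget must be positive")


def uncertainty_sample(
    probs: Sequence[float], pool: Sequence[str], cfg: SamplingConfig
) -> list[str]:
    """Seeded uniform subset (<= budget) of pool ids with prob in the band."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(pool):
        raise ValueError("probs and pool must align")
    in_band = [
        doc_id
        for doc_id, p in zip(pool, probs)
        if cfg.band_low <= p <= cfg.band_high
    ]
    if not in_band:
        logger.warning("uncertainty band [%g, %g] is empty", cfg.band_low, cfg.band_high)
        return []
    rng = np.random.default_rng(cfg.seed)
    k = min(cfg.uncertainty_budget, len(in_band))
    chosen = rng.choice(len(in_band), size=k, replace=False)
    return [in_band[i] for i in sorted(chosen)]


def high_confidence_positives(
    probs: Sequence[float], random_pool: Sequence[str], cfg: SamplingConfig
) -> list[str]:
    """All random-pool ids predicted positive strictly above the threshold."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(random_pool):
        raise ValueError("probs and random_pool must align")
    return [
        doc_id for doc_id, p in zip(random_pool, probs) if p > cfg.high_conf_threshold
    ]


def draw_random_pool(source: Corpus, n: int, seed: int) -> Corpus:
    """Uniform seeded draw of n documents, marked RANDOM/UNLABELED."""
    if n > len(source):
        raise ValueError(f"cannot draw {n} documents from a corpus of {len(source)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(source), size=n, replace=False)
    docs = []
    for i in idx:
        d = source.documents[int(i)]
        docs.append(
            type(d)(
                doc_id=d.doc_id,
                title=d.title,
                abstract=d.abstract,
                label=Label.UNLABELED,
                pool=PoolKind.RANDOM,
            )
        )
    out = Corpus(docs, provenance=dict(source.provenance))
    out.provenance["random_pool_seed"] = seed
    return out
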