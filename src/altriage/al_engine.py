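"""Active-learning workflow engine.

Four workflow variants over a pool of unreviewed abstracts:

* ``TRADITIONAL`` — one classifier (positives vs labeled negatives),
  uncertainty sampling, fixed validation set.
* ``TRADITIONAL_PLUS_RANDOM`` — one classifier trained against a drawn
  random-negative stratum, plus high-confidence positive mining.
* ``DUAL_MODEL`` — two classifiers: ml1 separates positives from random
  negatives, ml2 separates positives from manually labeled negatives.
* ``DUAL_MODEL_VAL_UPDATE`` — dual classifiers, and every batch of newly
  oracle-labeled documents is re-split between the two training sets and
  the validation set, so the validation distribution tracks the evolving
  sample population.

Each round: fit, score the unlabeled pool, acquire uncertainty samples
(plus mined high-confidence positives where the variant uses the random
pool), send them to the oracle, route the labeled documents, refit.
Train/validation/unlabeled pools stay pairwise disjoint at all times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .classifier import ClassifierSpec, FittedModel, fit
from .corpus_io import Corpus, Label, PoolKind
from .evaluation import MetricsReport, evaluate_scores, evaluate_uncertainty_subset
from .preprocess import FeatureSet, build_tdm, select_features, vectorize
from .sampling import SamplingConfig, high_confidence_positives, uncertainty_sample

logger = logging.getLogger(__name__)


def derive_seed(master: int, *parts: int) -> int:
    """Independent child seed for one stochastic step (stable, < 2**31)."""
    return int(
        np.random.SeedSequence(entropy=(int(master),) + tuple(int(p) for p in parts))
        .generate_state(1)[0]
        % (2**31)
    )


class ALVariant(Enum):
    TRADITIONAL = "traditional"
    TRADITIONAL_PLUS_RANDOM = "traditional_plus_random"
    DUAL_MODEL = "dual_model"
    DUAL_MODEL_VAL_UPDATE = "dual_model_val_update"

    @property
    def uses_random_negatives(self) -> bool:
        return self is not ALVariant.TRADITIONAL

    @property
    def dual_models(self) -> bool:
        return self in (ALVariant.DUAL_MODEL, ALVariant.DUAL_MODEL_VAL_UPDATE)

    @property
    def updates_validation(self) -> bool:
        return self is ALVariant.DUAL_MODEL_VAL_UPDATE


class Oracle(Protocol):
    query_count: int

    def label(self, doc_id: str) -> Label: ...


@dataclass
class Strata:
    """A labeled document set, kept as strata of known provenance."""

    pos: list[str] = field(default_factory=list)
    neg: list[str] = field(default_factory=list)
    rand: list[str] = field(default_factory=list)

    def all_ids(self) -> list[str]:
        return self.pos + self.neg + self.rand

    def counts(self) -> dict[str, int]:
        return {"pos": len(self.pos), "neg": len(self.neg), "rand": len(self.rand)}

    def copy(self) -> "Strata":
        return Strata(pos=list(self.pos), neg=list(self.neg), rand=list(self.rand))

    def labels(self) -> np.ndarray:
        """1 for the positive stratum, 0 for labeled-negative and random strata."""
        return np.array([1] * len(self.pos) + [0] * (len(self.neg) + len(self.rand)))


@dataclass
class InitialSizes:
    train_pos: int = 200
    train_neg: int = 200
    train_random: int = 1000
    val_pos: int = 200
    val_neg: int = 200
    val_random: int = 200


@dataclass
class SplitRatios:
    """How a newly labeled batch is divided in the validation-updating variant."""

    to_train_ml1: float = 0.4
    to_train_ml2: float = 0.3
    to_validation: float = 0.3

    def __post_init__(self) -> None:
        parts = (self.to_train_ml1, self.to_train_ml2, self.to_validation)
        if any(p < 0 for p in parts) or not np.isclose(sum(parts), 1.0):
            raise ValueError("split ratios must be non-negative and sum to 1")


@dataclass
class AcquisitionRecord:
    round: int
    doc_id: str
    probability: float
    mechanism: str  # "uncertainty" | "high_conf_positive"
    oracle_label: Label


@dataclass
class ALState:
    round: int
    train_ml1: Strata | None
    train_ml2: Strata | None
    validation: Strata
    unlabeled_pool: list[str]
    models: dict[str, FittedModel] = field(default_factory=dict)
    acquisitions: list[AcquisitionRecord] = field(default_factory=list)

    def assert_disjoint(self) -> None:
        named = {
            "train_ml1": set(self.train_ml1.all_ids()) if self.train_ml1 else set(),
            "train_ml2": set(self.train_ml2.all_ids()) if self.train_ml2 else set(),
            "validation": set(self.validation.all_ids()),
            "unlabeled": set(self.unlabeled_pool),
        }
        # the two training sets legitimately share documents (the paper's
        # dual sets share their positives); everything else must not overlap
        for a in ("train_ml1", "train_ml2"):
            for b in ("validation", "unlabeled"):
                common = named[a] & named[b]
                if common:
                    raise AssertionError(f"{a} and {b} share ids: {sorted(common)[:5]}")
        common = named["validation"] & named["unlabeled"]
        if common:
            raise AssertionError(f"validation and unlabeled share ids: {sorted(common)[:5]}")

    def size_manifest(self) -> dict[str, int]:
        out: dict[str, int] = {"round": self.round, "unlabeled": len(self.unlabeled_pool)}
        for name, strata in (
            ("train_ml1", self.train_ml1),
            ("train_ml2", self.train_ml2),
            ("validation", self.validation),
        ):
            if strata is not None:
                for k, v in strata.counts().items():
                    out[f"{name}_{k}"] = v
        return out


class FeatureSpace:
    """Vectorized corpus with a doc_id -> row lookup."""

    def __init__(self, corpus: Corpus, features: FeatureSet):
        self.features = features
        self.X = vectorize(corpus, features)
        self._row = {doc_id: i for i, doc_id in enumerate(corpus.ids())}

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.features.selected_terms)

    def rows(self, doc_ids: Sequence[str]) -> sp.csr_matrix:
        return self.X[[self._row[d] for d in doc_ids], :]


def initialize(
    variant: ALVariant,
    corpus: Corpus,
    sizes: InitialSizes = InitialSizes(),
    seed: int = 0,
) -> ALState:
    """Draw the disjoint first-round training/validation/unlabeled pools.

    The dual training sets share their positive stratum, as in the
    reference set sizes (the same 200 positives anchor both models).
    The unlabeled pool is the random pool minus any drawn random-negative
    strata, keeping all pools disjoint.
    """
    rng = np.random.default_rng(derive_seed(seed, 0))
    pos_pool = corpus.label_ids(Label.POSITIVE)
    neg_pool = corpus.label_ids(Label.NEGATIVE)
    rand_pool = corpus.pool_ids(PoolKind.RANDOM)

    need_neg = sizes.train_neg + sizes.val_neg
    need_rand = (
        sizes.train_random + sizes.val_random if variant.uses_random_negatives else 0
    )
    for name, pool, need in (
        ("positive", pos_pool, sizes.train_pos + sizes.val_pos),
        ("labeled-negative", neg_pool, need_neg),
        ("random", rand_pool, need_rand),
    ):
        if len(pool) < need:
            raise ValueError(
                f"insufficient {name} stratum: need {need}, have {len(pool)}"
            )

    pos = [pos_pool[i] for i in rng.permutation(len(pos_pool))]
    neg = [neg_pool[i] for i in rng.permutation(len(neg_pool))]
    rand = [rand_pool[i] for i in rng.permutation(len(rand_pool))]

    train_pos = pos[: sizes.train_pos]
    val_pos = pos[sizes.train_pos : sizes.train_pos + sizes.val_pos]
    train_neg = neg[: sizes.train_neg]
    val_neg = neg[sizes.train_neg : sizes.train_neg + sizes.val_neg]

    if variant is ALVariant.TRADITIONAL:
        train_ml1 = None
        train_ml2 = Strata(pos=train_pos, neg=train_neg)
        validation = Strata(pos=val_pos, neg=val_neg)
        unlabeled = rand
    elif variant is ALVariant.TRADITIONAL_PLUS_RANDOM:
        train_rand = rand[: sizes.train_random]
        val_rand = rand[sizes.train_random : sizes.train_random + sizes.val_random]
        train_ml1 = Strata(pos=train_pos, rand=train_rand)
        train_ml2 = None
        validation = Strata(pos=val_pos, neg=val_neg, rand=val_rand)
        unlabeled = rand[sizes.train_random + sizes.val_random :]
    else:
        train_rand = rand[: sizes.train_random]
        val_rand = rand[sizes.train_random : sizes.train_random + sizes.val_random]
        train_ml1 = Strata(pos=list(train_pos), rand=train_rand)
        train_ml2 = Strata(pos=list(train_pos), neg=train_neg)
        validation = Strata(pos=val_pos, neg=val_neg, rand=val_rand)
        unlabeled = rand[sizes.train_random + sizes.val_random :]

    state = ALState(
        round=1,
        train_ml1=train_ml1,
        train_ml2=train_ml2,
        validation=validation,
        unlabeled_pool=list(unlabeled),
    )
    state.assert_disjoint()
    return state


def fit_models(
    state: ALState,
    variant: ALVariant,
    fs: FeatureSpace,
    classifier_spec: ClassifierSpec,
    seed: int,
) -> dict[str, FittedModel]:
    """Fit the variant's model(s) on the current training strata.

    Model seeds derive from the run seed only (not the round), so a
    refit on unchanged data reproduces identical probabilities.
    """
    models: dict[str, FittedModel] = {}
    for name, strata in (("ml1", state.train_ml1), ("ml2", state.train_ml2)):
        if strata is None:
            continue
        spec = replace(classifier_spec, seed=derive_seed(seed, 1, 0 if name == "ml1" else 1))
        X = fs.rows(strata.all_ids())
        models[name] = fit(spec, X, strata.labels(), fs.terms)
    return models


def acquisition_scores(
    models: dict[str, FittedModel], X, preference: str = "union"
) -> dict[str, np.ndarray]:
    """Pool scores used for acquisition.

    ``preference`` selects which fitted model(s) nominate documents:
    ``"union"`` (default) scores with every fitted model — a document is
    acquirable if ANY model finds it uncertain or confidently positive,
    which is what lets each model's own blind spots reach the oracle —
    while ``"ml1"``/``"ml2"`` restrict nomination to that single model.
    """
    if preference == "union":
        return {name: m.predict_proba(X) for name, m in models.items()}
    if preference in models:
        return {preference: models[preference].predict_proba(X)}
    name, model = next(iter(models.items()))
    return {name: model.predict_proba(X)}


def run_round(
    state: ALState,
    variant: ALVariant,
    fs: FeatureSpace,
    sampling_cfg: SamplingConfig,
    oracle: Oracle,
    ratios: SplitRatios = SplitRatios(),
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
    acquisition_preference: str = "union",
) -> ALState:
    """One acquisition round; returns the next round's state.

    The input state is not mutated: on oracle failure the caller's state
    is unchanged.
    """
    models = state.models or fit_models(state, variant, fs, classifier_spec, seed)

    pool = list(state.unlabeled_pool)
    X_pool = fs.rows(pool) if pool else None
    scores = (
        acquisition_scores(models, X_pool, acquisition_preference) if pool else {}
    )
    round_cfg = replace(sampling_cfg, seed=derive_seed(seed, 2, state.round))
    # a document is in the band if any nominating model is uncertain about it;
    # the logged probability is the nominating model's (ml1 first)
    prob_of: dict[str, float] = {}
    in_band: list[str] = []
    for name in sorted(scores):
        for doc_id, p in zip(pool, scores[name]):
            if round_cfg.band_low <= p <= round_cfg.band_high and doc_id not in prob_of:
                prob_of[doc_id] = float(p)
                in_band.append(doc_id)
    band_probs = [prob_of[d] for d in in_band]
    unc = uncertainty_sample(band_probs, in_band, round_cfg)
    mechanisms = {d: "uncertainty" for d in unc}
    if variant.uses_random_negatives:
        for name in sorted(scores):
            by_doc = dict(zip(pool, scores[name]))
            for d in high_confidence_positives(scores[name], pool, round_cfg):
                if d not in mechanisms:
                    mechanisms[d] = "high_conf_positive"
                    prob_of.setdefault(d, float(by_doc[d]))
    acquired = list(mechanisms)

    oracle_labels = {d: oracle.label(d) for d in acquired}
    records = [
        AcquisitionRecord(
            round=state.round,
            doc_id=d,
            probability=float(prob_of[d]),
            mechanism=mechanisms[d],
            oracle_label=oracle_labels[d],
        )
        for d in acquired
    ]

    train_ml1 = state.train_ml1.copy() if state.train_ml1 else None
    train_ml2 = state.train_ml2.copy() if state.train_ml2 else None
    validation = state.validation.copy()

    def route(strata: Strata, doc_ids: Sequence[str], neg_stratum: str) -> None:
        for d in doc_ids:
            if oracle_labels[d] is Label.POSITIVE:
                strata.pos.append(d)
            elif neg_stratum == "rand":
                strata.rand.append(d)
            else:
                strata.neg.append(d)

    if variant is ALVariant.TRADITIONAL:
        route(train_ml2, acquired, "neg")
    elif variant is ALVariant.TRADITIONAL_PLUS_RANDOM:
        # confirmed negatives return to the random-negative stratum
        route(train_ml1, acquired, "rand")
    elif variant is ALVariant.DUAL_MODEL:
        route(train_ml1, acquired, "rand")
        route(train_ml2, acquired, "neg")
    else:  # DUAL_MODEL_VAL_UPDATE: re-split the batch across all three sets
        rng = np.random.default_rng(derive_seed(seed, 3, state.round))
        shuffled = [acquired[i] for i in rng.permutation(len(acquired))]
        n = len(shuffled)
        n1 = int(round(ratios.to_train_ml1 * n))
        n2 = int(round(ratios.to_train_ml2 * n))
        route(train_ml1, shuffled[:n1], "rand")
        route(train_ml2, shuffled[n1 : n1 + n2], "neg")
        # validation negatives are now manually reviewed: labeled-negative stratum
        route(validation, shuffled[n1 + n2 :], "neg")

    acquired_set = set(acquired)
    new_state = ALState(
        round=state.round + 1,
        train_ml1=train_ml1,
        train_ml2=train_ml2,
        validation=validation,
        unlabeled_pool=[d for d in state.unlabeled_pool if d not in acquired_set],
        acquisitions=state.acquisitions + records,
    )
    new_state.assert_disjoint()
    new_state.models = fit_models(new_state, variant, fs, classifier_spec, seed)
    logger.info("round %d -> %d: acquired %d", state.round, new_state.round, len(acquired))
    return new_state


def combined_retrieve(
    ml1: FittedModel, ml2: FittedModel, X, threshold: float = 0.5
) -> np.ndarray:
    """Deployment rule for the dual models: retrieve iff both agree.

    Boolean per row: positive probability >= threshold under ml1 AND ml2.
    """
    if ml1.feature_terms != ml2.feature_terms:
        raise ValueError("models were fitted on different feature spaces")
    return (ml1.predict_proba(X) >= threshold) & (ml2.predict_proba(X) >= threshold)


# ---------------------------------------------------------------------------
# Whole-run orchestration


@dataclass
class RoundSnapshot:
    round: int
    models: dict[str, FittedModel]
    sizes: dict[str, int]


@dataclass
class RunResult:
    variant: ALVariant
    rounds: list[RoundSnapshot]
    final_state: ALState
    metrics: pd.DataFrame  # variant, round, model, TP..., recall, precision, f1, p_at_r
    fs: FeatureSpace

    def acquisitions(self, in_round: int | None = None) -> list[AcquisitionRecord]:
        recs = self.final_state.acquisitions
        return recs if in_round is None else [r for r in recs if r.round == in_round]

    def uncertainty_subset_metrics(self, acquired_round: int = 1) -> pd.DataFrame:
        """Every round's models evaluated on one round's acquired samples."""
        recs = self.acquisitions(acquired_round)
        if not recs:
            raise ValueError(f"no acquisitions in round {acquired_round}")
        ids = [r.doc_id for r in recs]
        truth = [1 if r.oracle_label is Label.POSITIVE else 0 for r in recs]
        X = self.fs.rows(ids)
        rows = []
        for snap in self.rounds:
            for name, model in snap.models.items():
                rep = evaluate_uncertainty_subset(model, X, truth)
                rows.append(
                    {
                        "round": snap.round,
                        "model": name,
                        "recall": rep.recall,
                        "precision": rep.precision,
                        "f1": rep.f1,
                        "degenerate": rep.degenerate,
                        "n": len(ids),
                    }
                )
        return pd.DataFrame(rows)


def run_active_learning(
    corpus: Corpus,
    oracle: Oracle,
    variant: ALVariant,
    classifier_spec: ClassifierSpec = ClassifierSpec(),
    sizes: InitialSizes = InitialSizes(),
    sampling_cfg: SamplingConfig = SamplingConfig(),
    ratios: SplitRatios = SplitRatios(),
    rounds: int = 2,
    seed: int = 0,
    features: FeatureSet | None = None,
    sd_threshold: float = 0.03,
    eval_threshold: float = 0.5,
    recall_target: float = 0.99,
    acquisition_preference: str = "union",
) -> RunResult:
    """Run a full multi-round workflow and evaluate every round's models.

    All rounds are evaluated on the run's final validation set: for the
    validation-updating variant that is the updated set (so first-round
    models face the corrected sample population); for the other variants
    the validation set never changes.
    """
    if rounds < 1:
        raise ValueError("need at least one round")
    if features is None:
        features = select_features(build_tdm(corpus), sd_threshold=sd_threshold)
    fs = FeatureSpace(corpus, features)

    state = initialize(variant, corpus, sizes=sizes, seed=derive_seed(seed, 4))
    snapshots: list[RoundSnapshot] = []
    for r in range(1, rounds + 1):
        if not state.models:
            state.models = fit_models(state, variant, fs, classifier_spec, seed)
        snapshots.append(
            RoundSnapshot(round=r, models=dict(state.models), sizes=state.size_manifest())
        )
        if r < rounds:
            state = run_round(
                state,
                variant,
                fs,
                sampling_cfg,
                oracle,
                ratios=ratios,
                classifier_spec=classifier_spec,
                seed=seed,
                acquisition_preference=acquisition_preference,
            )

    val = state.validation
    val_ids = val.all_ids()
    truth = val.labels()
    X_val = fs.rows(val_ids)
    rows = []
    for snap in snapshots:
        for name, model in snap.models.items():
            scores = model.predict_proba(X_val)
            cm, rep = evaluate_scores(
                scores, truth, threshold=eval_threshold, recall_target=recall_target
            )
            rows.append(
                {
                    "variant": variant.value,
                    "round": snap.round,
                    "model": name,
                    "TP": cm.tp,
                    "FP": cm.fp,
                    "TN": cm.tn,
                    "FN": cm.fn,
                    "recall": rep.recall,
                    "precision": rep.precision,
                    "f1": rep.f1,
                    "p_at_r": rep.precision_at_recall,
                }
            )
    return RunResult(
        variant=variant,
        rounds=snapshots,
        final_state=state,
        metrics=pd.DataFrame(rows),
        fs=fs,
    )
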