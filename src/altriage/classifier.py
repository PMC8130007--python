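"""Probabilistic binary classifiers used inside the active-learning loop.

Two linear families: a max-margin classifier (linear SVM, Platt-calibrated
so the loop's probability bands apply) and logistic regression. Both are
deterministic for a fixed spec seed and input, and both are bound to the
feature space they were fitted on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC


class Family(str, Enum):
    MAX_MARGIN = "max_margin"
    LOGISTIC = "logistic"


class Calibration(str, Enum):
    NONE = "none"
    PLATT = "platt"


@dataclass
class ClassifierSpec:
    """Configuration of one learner.

    regularization_strength is the usual inverse-penalty C. The paper's
    loop always consumes probabilities, so a max-margin spec must carry
    Platt calibration.
    """

    family: Family = Family.LOGISTIC
    regularization_strength: float = 1.0
    calibration: Calibration = Calibration.PLATT
    seed: int = 0
    class_weight: str | None = None

    def __post_init__(self) -> None:
        self.family = Family(self.family)
        self.calibration = Calibration(self.calibration)
        if self.regularization_strength <= 0:
            raise ValueError("regularization_strength must be positive")
        if self.family is Family.MAX_MARGIN and self.calibration is not Calibration.PLATT:
            raise ValueError(
                "MAX_MARGIN requires Platt calibration for probability outputs"
            )


@dataclass
class FittedModel:
    spec: ClassifierSpec
    feature_terms: tuple[str, ...]
    estimator: object

    def predict_proba(self, X: sp.spmatrix | np.ndarray) -> np.ndarray:
        """Probability of the POSITIVE class, aligned with input rows."""
        if X.shape[1] != len(self.feature_terms):
            raise ValueError(
                f"feature-space mismatch: model has {len(self.feature_terms)} "
                f"features, input has {X.shape[1]}"
            )
        proba = self.estimator.predict_proba(X)
        pos_col = list(self.estimator.classes_).index(1)
        return proba[:, pos_col]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))


def load_model(path: str | Path) -> FittedModel:
    model = joblib.load(Path(path))
    if not isinstance(model, FittedModel):
        raise ValueError(f"{path} does not contain a FittedModel")
    return model


def fit(
    spec: ClassifierSpec,
    X: sp.spmatrix | np.ndarray,
    y: Sequence[int],
    feature_terms: Sequence[str],
) -> FittedModel:
    """Fit one classifier; y uses 1 = positive, 0 = negative.

    Raises on a single-class y (degenerate training set) and on a
    row/label length mismatch.
    """
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("number of rows and labels differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    if X.shape[1] != len(feature_terms):
        raise ValueError("X columns do not match feature_terms")

    if spec.family is Family.LOGISTIC:
        est = LogisticRegression(
            C=spec.regularization_strength,
            solver="liblinear",
            class_weight=spec.class_weight,
            random_state=spec.seed,
        )
    else:
        base = LinearSVC(
            C=spec.regularization_strength,
            class_weight=spec.class_weight,
            random_state=spec.seed,
            dual=True,
            max_iter=5000,
        )
        # Platt scaling with internal CV turns margins into probabilities;
        # folds adapt to tiny classes (2 minimum)
        n_min = int(np.bincount(y).min())
        if n_min < 2:
            raise ValueError("Platt calibration needs >= 2 examples per class")
        est = CalibratedClassifierCV(base, method="sigmoid", cv=min(3, n_min))
    est.fit(X, y)
    return FittedModel(spec=spec, feature_terms=tuple(feature_terms), estimator=est)
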