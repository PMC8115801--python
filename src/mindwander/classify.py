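"""The two attention-state classifier families behind a uniform contract.

A non-linear RBF-kernel support-vector classifier and a linear
(L2-penalised) logistic regression, both operating on the four block
features (n1_mean, n1_sd, p3_mean, p3_sd) or a named subset.  Both expose
continuous decision scores oriented so that larger means more
mind-wandering-like; thresholding a score at the family's natural
boundary (0 for both) yields the hard predictions used for accuracy, MCC
and confusion matrices, while the scores themselves feed AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .features import FEATURE_NAMES

_FAMILY_ALIASES = {
    "svm": "rbf_svm", "rbf_svm": "rbf_svm", "rbf": "rbf_svm",
    "logreg": "logistic", "logistic": "logistic",
}


@dataclass
class ModelSpec:
    """Classifier family and hyperparameters.

    ``gamma="scale"`` is the kernel-width heuristic
    1 / (n_features * Var(X)); C is the SVM cost and, for the logistic
    family, the inverse penalty strength.  ``feature_subset`` restricts
    the model to named feature columns (used for single-feature
    ablation).
    """

    family: str = "rbf_svm"
    C: float = 1.0
    gamma: float | str = "scale"
    feature_subset: tuple[str, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_ALIASES:
            raise ValueError(f"unknown model family {self.family!r}")
        self.family = _FAMILY_ALIASES[self.family]
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.feature_subset is not None:
            self.feature_subset = tuple(self.feature_subset)
            unknown = set(self.feature_subset) - set(FEATURE_NAMES)
            if unknown:
                raise ValueError(f"unknown feature name(s): {sorted(unknown)}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    feature_names: tuple[str, ...]

    def decision_scores(self, X) -> np.ndarray:
        """Continuous scores; larger means more mind-wandering-like."""
        return self.estimator.decision_function(self._matrix(X))

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(self._matrix(X))

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise ValueError(f"missing feature column(s): {sorted(missing)}")
            return X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns "
                f"({self.feature_names}), got {X.shape[1]}")
        return X


def fit(X, y, spec: ModelSpec | None = None,
        feature_names: tuple[str, ...] | None = None) -> TrainedModel:
    """Fit the requested family; mind wandering (label 1) is positive.

    ``X`` may be a DataFrame (feature columns selected by name, honouring
    ``spec.feature_subset``) or a plain matrix whose columns follow
    ``feature_names`` (default: the four canonical features).
    """
    spec = spec or ModelSpec()
    if isinstance(X, pd.DataFrame):
        names = spec.feature_subset or tuple(
            c for c in FEATURE_NAMES if c in X.columns)
        Xm = X[list(names)].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        all_names = tuple(feature_names) if feature_names else FEATURE_NAMES[:Xm.shape[1]]
        if spec.feature_subset:
            cols = [all_names.index(f) for f in spec.feature_subset]
            Xm = Xm[:, cols]
            names = spec.feature_subset
        else:
            names = all_names
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if spec.family == "rbf_svm":
        est = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma,
                  random_state=spec.seed)
    else:
        est = LogisticRegression(C=spec.C, max_iter=1000)
    est.fit(Xm, y)
    return TrainedModel(spec, est, tuple(names))
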