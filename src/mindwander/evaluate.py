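"""Evaluation: metrics, person-dependent and person-independent CV, ablation.

Two evaluation regimes mirror the two use cases of an attention-state
decoder.  Person-dependent: stratified 5-fold cross-validation over one
subject's 25 blocks, metrics computed once on the pooled out-of-fold
predictions.  Person-independent: leave-one-subject-out (LOSO) — train on
all other subjects, test on the held-out one, aggregate per-subject
metrics as mean with dispersion (SE within subjects, SD across).  SMOTE
is applied to training rows only, inside every fold/iteration.  Mind
wandering (label 1) is the positive class throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .balance import BalanceConfig, exclude_low_minority_subjects, smote
from .classify import ModelSpec, fit
from .features import FEATURE_NAMES, normalize_features

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionMatrix:
    """Counts with mind wandering as the positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    def normalized(self) -> np.ndarray:
        """2x2 array, rows = predicted (MW, not MW), columns = actual
        (MW, not MW); each column sums to 1 when its actual class occurs."""
        out = np.zeros((2, 2))
        pos = self.tp + self.fn
        neg = self.fp + self.tn
        if pos:
            out[0, 0] = self.tp / pos
            out[1, 0] = self.fn / pos
        if neg:
            out[0, 1] = self.fp / neg
            out[1, 1] = self.tn / neg
        return out


def confusion(predictions, actuals) -> ConfusionMatrix:
    p = np.asarray(predictions).astype(int)
    a = np.asarray(actuals).astype(int)
    if len(p) != len(a) or len(p) == 0:
        raise ValueError("predictions and actuals must be equal-length, non-empty")
    return ConfusionMatrix(
        tp=int(((p == 1) & (a == 1)).sum()),
        fp=int(((p == 1) & (a == 0)).sum()),
        fn=int(((p == 0) & (a == 1)).sum()),
        tn=int(((p == 0) & (a == 0)).sum()),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation; 0 when any marginal is empty."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    denom2 = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
              * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if denom2 == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / np.sqrt(denom2)


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    accuracy: float
    auc: float
    mcc: float
    confusion: ConfusionMatrix
    n_test_rows: int
    subject_id: str | None = None
    fold_mean_accuracy: float | None = None

    @property
    def normalized_confusion(self) -> np.ndarray:
        return self.confusion.normalized()


@dataclass
class CohortResult:
    per_subject: list[MetricsReport]
    dispersion: str  # "se" (person-dependent) or "sd" (person-independent)
    excluded_subjects: list[str] = field(default_factory=list)

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        total = ConfusionMatrix()
        for rep in self.per_subject:
            total = total + rep.confusion
        return total

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Per-metric (mean, dispersion) over subjects."""
        out = {}
        for name in ("accuracy", "auc", "mcc"):
            vals = np.array([getattr(r, name) for r in self.per_subject])
            if self.dispersion == "se":
                disp = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            else:
                disp = vals.std(ddof=1) if len(vals) > 1 else 0.0
            out[name] = (float(vals.mean()), float(disp))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": r.subject_id, "accuracy": r.accuracy,
              "auc": r.auc, "mcc": r.mcc, "n": r.n_test_rows}
             for r in self.per_subject]
        )


def _score_report(scores, y_true, subject_id=None,
                  fold_mean_accuracy=None) -> MetricsReport:
    preds = (np.asarray(scores) > 0).astype(int)
    cm = confusion(preds, y_true)
    return MetricsReport(
        accuracy=accuracy(cm),
        auc=auc(scores, y_true),
        mcc=mcc(cm),
        confusion=cm,
        n_test_rows=len(y_true),
        subject_id=subject_id,
        fold_mean_accuracy=fold_mean_accuracy,
    )


# ---------------------------------------------------------------------------
# cross-validation

def make_folds(y, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled, disjoint, covering folds with sizes within one of each
    other; stratified by label whenever each class has at least k rows."""
    y = np.asarray(y)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} invalid for n={n}")
    classes, counts = np.unique(y, return_counts=True)
    folds: list[list[int]] = [[] for _ in range(k)]
    if len(classes) > 1 and counts.min() >= k:
        start = 0
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            # round-robin with a rotating start so fold sizes stay balanced
            for j, i in enumerate(idx):
                folds[(start + j) % k].append(int(i))
            start = (start + len(idx)) % k
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _smote_train(X, y, balance: BalanceConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    try:
        return smote(X, y, balance, rng)
    except ValueError as err:
        logger.warning("SMOTE skipped for a training fold (%s)", err)
        return np.asarray(X, dtype=float), np.asarray(y)


def person_dependent_eval(table: pd.DataFrame, spec: ModelSpec | None = None,
                          k: int = 5, balance: BalanceConfig | None = None,
                          rng: np.random.Generator | int | None = None
                          ) -> MetricsReport:
    """5-fold CV within one subject; metrics on pooled out-of-fold scores."""
    spec = spec or ModelSpec()
    balance = balance or BalanceConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    subjects = table["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("person_dependent_eval expects one subject's rows")
    feats = list(spec.feature_subset or FEATURE_NAMES)
    X = table[feats].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("subject has a single attention state; cannot evaluate")
    folds = make_folds(y, k, rng)
    scores = np.empty(len(y))
    fold_accs = []
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        Xb, yb = _smote_train(X[train_mask], y[train_mask], balance, rng)
        model = fit(Xb, yb, spec, feature_names=tuple(feats))
        s = model.decision_scores(X[test_idx])
        scores[test_idx] = s
        fold_accs.append(float(((s > 0).astype(int) == y[test_idx]).mean()))
    return _score_report(scores, y, subject_id=str(subjects[0]),
                         fold_mean_accuracy=float(np.mean(fold_accs)))


def person_dependent_cohort(table: pd.DataFrame, spec: ModelSpec | None = None,
                            k: int = 5, balance: BalanceConfig | None = None,
                            rng: np.random.Generator | int | None = None
                            ) -> CohortResult:
    """Person-dependent evaluation for every retained subject."""
    balance = balance or BalanceConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    retained, excluded = exclude_low_minority_subjects(table, balance)
    reports = []
    for subject, sub in retained.groupby("subject_id", sort=True):
        reports.append(person_dependent_eval(sub, spec, k, balance, rng))
    return CohortResult(reports, dispersion="se", excluded_subjects=excluded)


def person_independent_eval(table: pd.DataFrame, spec: ModelSpec | None = None,
                            balance: BalanceConfig | None = None,
                            rng: np.random.Generator | int | None = None,
                            normalization: str = "per_subject",
                            smote_scope: str = "pooled") -> CohortResult:
    """Leave-one-subject-out evaluation across the cohort.

    ``table`` holds unnormalised (or per-subject normalised) feature rows
    for all subjects.  ``normalization="per_subject"`` centres every
    subject — including the held-out one — on their own on-task mean, as
    published; ``"train_stats"`` instead centres the held-out subject on
    the pooled on-task mean of the training cohort, avoiding the use of
    the test subject's labels.  ``smote_scope`` controls whether the
    oversampling runs once on the pooled training rows (default) or
    within each training subject separately.  Subjects with fewer than
    five minority-class blocks are excluded before the loop.
    """
    spec = spec or ModelSpec()
    balance = balance or BalanceConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if normalization not in ("per_subject", "train_stats"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if smote_scope not in ("pooled", "per_subject"):
        raise ValueError(f"unknown smote_scope {smote_scope!r}")
    retained, excluded = exclude_low_minority_subjects(table, balance)
    subjects = sorted(retained["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError(
            f"person-independent evaluation needs at least 3 retained "
            f"subjects, got {len(subjects)}")
    if normalization == "per_subject" and not (retained["normalized"] == 1).all():
        retained = normalize_features(retained)
    feats = list(spec.feature_subset or FEATURE_NAMES)
    reports = []
    for held_out in subjects:
        test = retained[retained["subject_id"] == held_out]
        train = retained[retained["subject_id"] != held_out]
        assert held_out not in set(train["subject_id"])
        if normalization == "train_stats":
            train = normalize_features(train)
            on_task_mean = retained.loc[
                (retained["subject_id"] != held_out)
                & (retained["label"] == 0), feats].mean()
            test = test.copy()
            test.loc[:, feats] = test[feats] - on_task_mean
        if smote_scope == "pooled":
            Xb, yb = _smote_train(train[feats].to_numpy(dtype=float),
                                  train["label"].to_numpy(dtype=int),
                                  balance, rng)
        else:
            parts = [
                _smote_train(sub[feats].to_numpy(dtype=float),
                             sub["label"].to_numpy(dtype=int), balance, rng)
                for _, sub in train.groupby("subject_id", sort=True)
            ]
            Xb = np.vstack([p[0] for p in parts])
            yb = np.concatenate([p[1] for p in parts])
        model = fit(Xb, yb, spec, feature_names=tuple(feats))
        scores = model.decision_scores(test[feats].to_numpy(dtype=float))
        reports.append(_score_report(scores, test["label"].to_numpy(dtype=int),
                                     subject_id=str(held_out)))
    return CohortResult(reports, dispersion="sd", excluded_subjects=excluded)


def feature_ablation(table: pd.DataFrame, spec: ModelSpec | None = None,
                     features: tuple[str, ...] = FEATURE_NAMES,
                     balance: BalanceConfig | None = None,
                     rng: np.random.Generator | int | None = None,
                     normalization: str = "per_subject") -> pd.DataFrame:
    """Person-independent evaluation with one feature at a time.

    Returns a table with one row per feature (accuracy, AUC, MCC of the
    LOSO aggregate means), mirroring a single-feature importance report.
    """
    spec = spec or ModelSpec()
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for name in features:
        sub_spec = ModelSpec(family=spec.family, C=spec.C, gamma=spec.gamma,
                             feature_subset=(name,), seed=spec.seed)
        res = person_independent_eval(table, sub_spec, balance, rng,
                                      normalization)
        agg = res.aggregate()
        rows.append({"feature": name,
                     "accuracy": agg["accuracy"][0],
                     "auc": agg["auc"][0],
                     "mcc": agg["mcc"][0]})
    return pd.DataFrame(rows)
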