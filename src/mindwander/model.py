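"""Model/Results facade over the detection pipeline.

`MindWanderingModel` bundles a block-level feature table with a
classifier family and balancing policy; `fit()` runs the requested
cross-validated evaluation and returns a `MindWanderingResults` holding
per-subject metrics, aggregates with their dispersion, the pooled
confusion matrix, and a text `summary()`.  Simulation (`from_simulation`)
and plotting (`Results.plot_metrics`) hang off these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import BalanceConfig
from .classify import ModelSpec
from .evaluate import (CohortResult, feature_ablation,
                       person_dependent_cohort, person_independent_eval)
from .features import FeatureSpec, cohort_features, normalize_features
from .simulate import GeneratorConfig, iter_cohort


class MindWanderingModel:
    """Attention-state decoder built from a block-level feature table.

    Parameters
    ----------
    features : DataFrame
        One row per block with the canonical feature columns
        (see :data:`mindwander.features.FEATURE_COLUMNS`).
    spec : ModelSpec, optional
        Classifier family and hyperparameters (default RBF SVM, C=1).
    balance : BalanceConfig, optional
        SMOTE neighbourhood size and the minority-count exclusion floor.
    """

    def __init__(self, features: pd.DataFrame, spec: ModelSpec | None = None,
                 balance: BalanceConfig | None = None,
                 normalization: str = "per_subject"):
        self.features = features
        self.spec = spec or ModelSpec()
        self.balance = balance or BalanceConfig()
        self.normalization = normalization

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "MindWanderingModel":
        return cls(frame.copy(), **kwargs)

    @classmethod
    def from_simulation(cls, config: GeneratorConfig | None = None,
                        feature_spec: FeatureSpec | None = None,
                        seed: int | None = None, **kwargs) -> "MindWanderingModel":
        """Generate a synthetic cohort and extract its feature table."""
        config = config or GeneratorConfig()
        rng = np.random.default_rng(config.seed if seed is None else seed)
        table = cohort_features(iter_cohort(config, rng), feature_spec)
        return cls(table, **kwargs)

    def fit(self, mode: str = "across",
            seed: int | None = None) -> "MindWanderingResults":
        """Run the cross-validated evaluation.

        ``mode="within"`` is person-dependent 5-fold CV per subject;
        ``mode="across"`` is leave-one-subject-out.
        """
        rng = np.random.default_rng(seed)
        table = self.features
        if self.normalization == "per_subject" and not (
                table["normalized"] == 1).all():
            table = normalize_features(table)
        if mode == "within":
            cohort = person_dependent_cohort(table, self.spec,
                                             balance=self.balance, rng=rng)
        elif mode == "across":
            source = self.features if self.normalization == "train_stats" else table
            cohort = person_independent_eval(source, self.spec,
                                             balance=self.balance, rng=rng,
                                             normalization=self.normalization)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return MindWanderingResults(self, mode, cohort)

    def ablate(self, seed: int | None = None) -> pd.DataFrame:
        """Single-feature person-independent evaluation per feature."""
        table = self.features
        if self.normalization == "per_subject" and not (
                table["normalized"] == 1).all():
            table = normalize_features(table)
        return feature_ablation(table, self.spec, balance=self.balance,
                                rng=np.random.default_rng(seed),
                                normalization=self.normalization)


@dataclass
class MindWanderingResults:
    model: MindWanderingModel
    mode: str
    cohort: CohortResult

    @property
    def per_subject(self) -> pd.DataFrame:
        return self.cohort.to_frame()

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        return self.cohort.aggregate()

    def summary(self) -> str:
        disp = "SE" if self.cohort.dispersion == "se" else "SD"
        lines = [
            "Mind-wandering detection results",
            "=" * 46,
            f"mode:              {'person-dependent (5-fold)' if self.mode == 'within' else 'person-independent (LOSO)'}",
            f"model family:      {self.model.spec.family}",
            f"subjects:          {len(self.cohort.per_subject)}"
            + (f"  (excluded: {', '.join(self.cohort.excluded_subjects)})"
               if self.cohort.excluded_subjects else ""),
            "-" * 46,
            f"{'metric':<10}{'mean':>10}{disp:>10}",
        ]
        for name, (mean, d) in self.aggregate.items():
            lines.append(f"{name:<10}{mean:>10.3f}{d:>10.3f}")
        cm = self.cohort.pooled_confusion.normalized()
        lines += [
            "-" * 46,
            "confusion (columns: actual MW, actual not-MW)",
            f"  pred MW      {cm[0, 0]:.3f}    {cm[0, 1]:.3f}",
            f"  pred not-MW  {cm[1, 0]:.3f}    {cm[1, 1]:.3f}",
        ]
        return "\n".join(lines)

    def plot_metrics(self, ax=None):
        """Per-subject AUC and MCC bars with chance lines."""
        import matplotlib.pyplot as plt

        frame = self.per_subject
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 + 0.6 * len(frame), 3.5))
        x = np.arange(len(frame))
        ax.bar(x - 0.2, frame["auc"], width=0.4, label="AUC")
        ax.bar(x + 0.2, frame["mcc"], width=0.4, label="MCC")
        ax.axhline(0.5, color="k", lw=0.8, ls="--")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xticks(x, frame["subject_id"], rotation=45, ha="right")
        ax.set_ylabel("metric value")
        ax.legend(frameon=False)
        return ax
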