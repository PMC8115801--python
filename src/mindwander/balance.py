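"""Class balancing: SMOTE oversampling and the low-minority exclusion rule.

Thought-probe labels are rarely balanced (the cohort here splits roughly
55/45 mind wandering vs on task), so the minority class is oversampled
before training with SMOTE: each synthetic row is a uniform point on the
segment between a real minority row and one of its k nearest minority
neighbours.  Subjects reporting fewer than five blocks of the minority
class are excluded outright — too few real points to interpolate between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class BalanceConfig:
    k_neighbors: int = 5
    min_minority_per_subject: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote(X: np.ndarray, y: np.ndarray, config: BalanceConfig | None = None,
          rng: np.random.Generator | None = None
          ) -> tuple[np.ndarray, np.ndarray]:
    """Equalise class counts by interpolated minority oversampling.

    Each synthetic point is ``x + g * (z - x)`` where ``x`` is a real
    minority row (parents cycle deterministically over the minority rows
    until the deficit is met), ``z`` one of its k nearest minority
    neighbours by Euclidean distance, and ``g`` a fresh uniform draw on
    [0, 1].  Original rows are returned unchanged, synthetic rows
    appended.  k is reduced (with a warning) when the minority class has
    fewer than k + 1 rows.
    """
    config = config or BalanceConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE requires exactly two classes, got {len(classes)}")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 rows for SMOTE")
    k = config.k_neighbors
    if n_min - 1 < k:
        logger.warning("reducing SMOTE k from %d to %d (minority has %d rows)",
                       k, n_min - 1, n_min)
        k = n_min - 1
    Xmin = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neighbor_idx = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self
    deficit = n_maj - n_min
    synthetic = np.empty((deficit, X.shape[1]))
    for i in range(deficit):
        parent = i % n_min
        z = Xmin[neighbor_idx[parent, rng.integers(k)]]
        g = rng.random()
        synthetic[i] = Xmin[parent] + g * (z - Xmin[parent])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


def exclude_low_minority_subjects(table: pd.DataFrame,
                                  config: BalanceConfig | None = None
                                  ) -> tuple[pd.DataFrame, list[str]]:
    """Drop subjects whose minority-class block count is below the floor.

    The minority class is determined per subject (the rarer of the two
    labels in that subject's rows; with a single label present the
    minority count is zero).  The strict rule is count < 5 by default.
    """
    config = config or BalanceConfig()
    floor = config.min_minority_per_subject
    excluded: list[str] = []
    for subject, sub in table.groupby("subject_id"):
        counts = sub["label"].value_counts()
        minority_count = int(counts.min()) if len(counts) == 2 else 0
        if minority_count < floor:
            excluded.append(subject)
    if excluded:
        logger.info("excluded %d subject(s) with minority class < %d: %s",
                    len(excluded), floor, ", ".join(map(str, excluded)))
    retained = table[~table["subject_id"].isin(excluded)].reset_index(drop=True)
    return retained, excluded
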