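"""Univariate checks: 2x2 attention x tone ANOVA and paired t-tests.

Before any decoding, the ERP measures are sanity-checked the classical
way: per subject and condition cell (attention state x tone type), the
mean per-trial peak amplitude is computed, and a two-factor ANOVA with
attention and tone as factors is run on the cell means, separately for
the N1 minimum and the P3 maximum.  With n subjects the fixed-effects
layout on the 4n cell means gives effect df = 1 and error df = 4n - 4;
a within-subject (subject-as-blocking-factor) variant is available via
``within_subject=True``.  Post-hoc paired t-tests compare attention
states per tone, and the behavioral reaction-time contrast uses the
same paired test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureSpec, extract_peak, preprocess_epoch, \
    select_preprobe_trials
from .simulate import MIND_WANDERING, ON_TASK, STANDARD, TARGET, SubjectSession


def paired_t(x, y) -> tuple[float, int, float]:
    """Dependent-samples t-test: returns (t, df, two-tailed p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)


def cell_means(sessions, spec: FeatureSpec | None = None,
               component: str = "n1") -> pd.DataFrame:
    """Per subject x attention x tone mean per-trial peak amplitude.

    Uses the pre-probe trials of every block (both tone types), filtered
    and baselined as in the feature pipeline.  Subjects missing any of
    the four cells are dropped with their id recorded in
    ``frame.attrs["incomplete_subjects"]``.
    """
    spec = spec or FeatureSpec()
    window = getattr(spec, component)
    rows = []
    for session in sessions:
        peaks: dict[tuple[str, str], list[float]] = {}
        for block in session.blocks:
            for trial in select_preprobe_trials(block, spec.trials_per_block):
                pre = preprocess_epoch(trial, spec)
                peak = extract_peak(pre, window.channels, window.window_ms,
                                    window.polarity)
                peaks.setdefault((block.probe_response, trial.tone_type),
                                 []).append(peak)
        rows.extend(
            {"subject_id": session.subject_id, "attention": state,
             "tone": tone, "value": float(np.mean(vals))}
            for (state, tone), vals in peaks.items()
        )
    frame = pd.DataFrame(rows, columns=["subject_id", "attention", "tone",
                                        "value"])
    complete, incomplete = [], []
    for subject, sub in frame.groupby("subject_id"):
        if len(sub) == 4:
            complete.append(sub)
        else:
            incomplete.append(subject)
    out = (pd.concat(complete, ignore_index=True) if complete
           else frame.iloc[0:0].copy())
    out.attrs["incomplete_subjects"] = incomplete
    return out


@dataclass
class AnovaEffect:
    F: float
    df_effect: int
    df_error: int
    p: float


def anova_2x2(cells: pd.DataFrame,
              within_subject: bool = False) -> dict[str, AnovaEffect]:
    """Two-factor ANOVA on a complete 2x2 cell-means table.

    ``cells`` must hold one row per subject x attention x tone with a
    ``value`` column.  The default fixed-effects analysis treats the 4n
    cell means as independent observations (error df = 4n - 4); the
    within-subject variant uses each effect's subject-interaction error
    term (error df = n - 1).
    """
    required = {"subject_id", "attention", "tone", "value"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells table needs columns {sorted(required)}")
    counts = cells.groupby("subject_id").size()
    if (counts != 4).any() or cells.empty:
        raise ValueError("incomplete 2x2 design: every subject needs all "
                         "four attention x tone cells")
    n = cells["subject_id"].nunique()
    a = np.where(cells["attention"] == MIND_WANDERING, 1, 0)
    b = np.where(cells["tone"] == TARGET, 1, 0)
    v = cells["value"].to_numpy(dtype=float)

    if within_subject:
        from statsmodels.stats.anova import AnovaRM
        res = AnovaRM(cells, depvar="value", subject="subject_id",
                      within=["attention", "tone"]).fit().anova_table
        mapping = {"attention": "attention", "tone": "tone",
                   "interaction": "attention:tone"}
        return {
            key: AnovaEffect(F=float(res.loc[row, "F Value"]),
                             df_effect=int(res.loc[row, "Num DF"]),
                             df_error=int(res.loc[row, "Den DF"]),
                             p=float(res.loc[row, "Pr > F"]))
            for key, row in mapping.items()
        }

    # balanced fixed-effects decomposition on the 4n cell means
    grand = v.mean()
    ss_total = ((v - grand) ** 2).sum()
    mean_a = {lvl: v[a == lvl].mean() for lvl in (0, 1)}
    mean_b = {lvl: v[b == lvl].mean() for lvl in (0, 1)}
    ss_a = sum(2 * n * (mean_a[lvl] - grand) ** 2 for lvl in (0, 1))
    ss_b = sum(2 * n * (mean_b[lvl] - grand) ** 2 for lvl in (0, 1))
    ss_ab = 0.0
    for la in (0, 1):
        for lb in (0, 1):
            cell = v[(a == la) & (b == lb)].mean()
            ss_ab += n * (cell - mean_a[la] - mean_b[lb] + grand) ** 2
    ss_err = ss_total - ss_a - ss_b - ss_ab
    df_err = 4 * n - 4
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    def effect(ss: float) -> AnovaEffect:
        if ms_err == 0 or not np.isfinite(ms_err):
            f = 0.0 if ss == 0 else np.inf
        else:
            f = ss / ms_err
        p = float(sps.f.sf(f, 1, df_err)) if np.isfinite(f) else 0.0
        return AnovaEffect(F=float(f), df_effect=1, df_error=df_err, p=p)

    return {"attention": effect(ss_a), "tone": effect(ss_b),
            "interaction": effect(ss_ab)}


def posthoc_attention_by_tone(cells: pd.DataFrame) -> dict[str, tuple[float, int, float]]:
    """Paired t-tests (on task vs mind wandering) separately per tone."""
    out = {}
    for tone in (STANDARD, TARGET):
        sub = cells[cells["tone"] == tone].pivot(
            index="subject_id", columns="attention", values="value").dropna()
        out[tone] = paired_t(sub[MIND_WANDERING].to_numpy(),
                             sub[ON_TASK].to_numpy())
    return out


def rt_comparison(sessions: list[SubjectSession]) -> tuple[float, int, float]:
    """Paired t-test of per-subject mean target RT, on task vs MW.

    Subjects lacking target responses in either state are dropped.
    """
    on_task, mw = [], []
    for session in sessions:
        by_state: dict[str, list[float]] = {ON_TASK: [], MIND_WANDERING: []}
        for block in session.blocks:
            by_state[block.probe_response].extend(rt for _, rt in block.rts_ms)
        if by_state[ON_TASK] and by_state[MIND_WANDERING]:
            on_task.append(np.mean(by_state[ON_TASK]))
            mw.append(np.mean(by_state[MIND_WANDERING]))
    return paired_t(np.asarray(on_task), np.asarray(mw))


def anova_table(sessions, spec: FeatureSpec | None = None,
                within_subject: bool = False) -> pd.DataFrame:
    """ANOVA summary for both components (rows: N1 Min, P3 Max)."""
    spec = spec or FeatureSpec()
    rows = []
    for comp, label in (("n1", "N1 Min"), ("p3", "P3 Max")):
        cells = cell_means(sessions, spec, component=comp)
        effects = anova_2x2(cells, within_subject=within_subject)
        row = {"feature": label}
        for key, eff in effects.items():
            row[f"F_{key}"] = eff.F
            row[f"p_{key}"] = eff.p
            row[f"df_{key}"] = f"({eff.df_effect},{eff.df_error})"
        rows.append(row)
    return pd.DataFrame(rows)
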