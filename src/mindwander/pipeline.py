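"""End-to-end run: simulate -> features -> normalize -> evaluate (-> stats).

Each stage draws from a child seed derived deterministically from the
global one, so a stage can be rerun in isolation and two runs of the
same configuration produce identical artifacts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mwio
from .evaluate import (feature_ablation, person_dependent_cohort,
                       person_independent_eval)
from .features import normalize_features, session_features
from .simulate import iter_cohort
from .stats import anova_table, rt_comparison

logger = logging.getLogger(__name__)


def run_pipeline(config: mwio.RunConfig, write: bool = True) -> dict:
    """Execute all requested stages; returns (and optionally writes) results."""
    out_dir = Path(config.output_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        mwio.save_config(config, out_dir / "config.yaml")

    # --- simulate + features (streamed per subject to bound memory)
    try:
        gen_rng = np.random.default_rng(mwio.child_seed(config.seed, "simulate"))
        tables = []
        sessions_for_stats = [] if config.run_stats else None
        for session in iter_cohort(config.generator, gen_rng):
            if write:
                mwio.write_events(session, out_dir / f"{session.subject_id}_events.tsv")
                mwio.write_epochs(session, out_dir / "epochs")
            tables.append(session_features(session, config.features))
            if sessions_for_stats is not None:
                sessions_for_stats.append(session)
        features = pd.concat(tables, ignore_index=True)
    except Exception as err:
        raise RuntimeError(f"[simulate/features] {err}") from err

    try:
        normalized = normalize_features(features)
        if write:
            mwio.write_features(features, out_dir / "features.csv")
            mwio.write_features(normalized, out_dir / "features_normalized.csv")
    except Exception as err:
        raise RuntimeError(f"[normalize] {err}") from err

    # --- evaluation
    results: dict = {"config_seed": config.seed,
                     "evaluation_mode": config.evaluation_mode,
                     "normalization": config.normalization}
    try:
        eval_rng = np.random.default_rng(mwio.child_seed(config.seed, "evaluate"))
        if config.evaluation_mode == "within":
            cohort = person_dependent_cohort(normalized, config.model,
                                             balance=config.balance,
                                             rng=eval_rng)
        elif config.evaluation_mode == "across":
            cohort = person_independent_eval(
                features if config.normalization == "train_stats" else normalized,
                config.model, balance=config.balance, rng=eval_rng,
                normalization=config.normalization)
        else:
            raise ValueError(f"unknown evaluation mode {config.evaluation_mode!r}")
        agg = cohort.aggregate()
        disp_name = "se" if config.evaluation_mode == "within" else "sd"
        results["metrics"] = {k: {"mean": m, disp_name: d}
                              for k, (m, d) in agg.items()}
        results["per_subject"] = cohort.to_frame().to_dict(orient="records")
        results["excluded_subjects"] = cohort.excluded_subjects
        results["confusion_normalized"] = cohort.pooled_confusion.normalized()
    except Exception as err:
        raise RuntimeError(f"[evaluate] {err}") from err

    if config.run_ablation:
        try:
            abl_rng = np.random.default_rng(mwio.child_seed(config.seed, "ablate"))
            ablation = feature_ablation(
                features if config.normalization == "train_stats" else normalized,
                config.model, balance=config.balance, rng=abl_rng,
                normalization=config.normalization)
            results["ablation"] = ablation.to_dict(orient="records")
        except Exception as err:
            raise RuntimeError(f"[ablate] {err}") from err

    if config.run_stats and sessions_for_stats:
        try:
            stats_frame = anova_table(sessions_for_stats, config.features)
            results["anova"] = stats_frame.to_dict(orient="records")
            try:
                t, df, p = rt_comparison(sessions_for_stats)
                results["rt_paired_t"] = {"t": t, "df": df, "p": p}
            except ValueError as err:
                logger.warning("RT comparison skipped: %s", err)
            if write:
                stats_frame.round(4).to_csv(out_dir / "stats_table.txt",
                                            sep="\t", index=False)
        except Exception as err:
            raise RuntimeError(f"[stats] {err}") from err

    if write:
        mwio.write_results(results, out_dir / "results.json")
    return results
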