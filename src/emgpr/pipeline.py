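"""End-to-end experiment orchestration.

``run_experiment`` mirrors the study's per-subject structure: synthesize a
recording session per simulated subject, train the pairwise-LDA classifier
per condition (channel subset), run the motion test the configured number
of times, collect a per-subject metric table per condition, and compare
conditions with the nonparametric tests.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from emgpr.config import PipelineConfig
from emgpr.features import FeatureMatrix, extract_features, split_sets
from emgpr.lda import OvoClassifier, fit_ovo, offline_accuracy
from emgpr.motiontest import (
    MotionTestResult,
    classifier_stream_source,
    run_motion_test,
)
from emgpr.preprocess import movement_signals, segment_windows
from emgpr.sessions import EmgSession, select_channels
from emgpr.stats import compare_conditions, comparison_report, summarize
from emgpr.synth import ActivationModel, generate_session

logger = logging.getLogger(__name__)


def session_features(session: EmgSession, cfg: PipelineConfig, split_seed: int):
    """Trim, window, featurize, and split one session."""
    signals = movement_signals(session, cfg.segmentation)
    ws = segment_windows(signals, cfg.segmentation, session.protocol.sampling_rate)
    fm = extract_features(ws, cfg.features)
    split = split_sets(fm, rng_seed=split_seed)
    return fm, split


def train_session(session: EmgSession, cfg: PipelineConfig, split_seed: int = 0):
    """Fit the one-vs-one classifier on a session; returns (clf, accuracy)."""
    fm, split = session_features(session, cfg, split_seed)
    clf = fit_ovo(fm, split, ridge_lambda=cfg.ridge_lambda)
    return clf, offline_accuracy(clf, fm, split)


def subject_metrics(
    session: EmgSession,
    model: ActivationModel,
    cfg: PipelineConfig,
    subject_seed: int,
    channel_subset: list[int] | None = None,
) -> dict[str, float]:
    """One subject x condition: train, run motion tests, report metric row."""
    if channel_subset is not None:
        session = select_channels(session, channel_subset)
        model = replace(
            model, activation=model.activation[:, channel_subset],
            mixing=None if model.mixing is None else model.mixing[np.ix_(channel_subset, channel_subset)],
        )
    clf, acc = train_session(session, cfg, split_seed=subject_seed)
    source = classifier_stream_source(
        clf, session.protocol, model, cfg.frontend, cfg.features, cfg.motion_test
    )
    result = run_motion_test(
        source, list(session.protocol.movements), cfg.motion_test, rng_seed=subject_seed
    )
    agg = result.aggregates()
    return {
        "offline_accuracy": acc,
        "completion_percentage": result.completion_percentage,
        "selection_time_s": agg["selection_time_s"]["mean"],
        "completion_time_s": agg["completion_time_s"]["mean"],
        "realtime_accuracy": agg["realtime_accuracy"]["mean"],
    }


def run_experiment(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Full experiment: per-subject sessions -> training -> motion tests ->
    per-condition metric tables -> condition comparison.

    Deterministic for a fixed global seed. Returns a bundle dict with the
    metric tables (DataFrames), summaries, and comparison results; when
    *out_dir* is given, writes CSV/JSON artifacts stamped with the config
    hash.
    """
    t_start = time.time()
    cond_names = list(cfg.experiment.conditions)
    n_subjects = cfg.experiment.n_subjects
    tables: dict[str, list[dict]] = {c: [] for c in cond_names}

    for subj in range(n_subjects):
        subj_seed = cfg.stage_seed("subject", subj)
        model = cfg.make_activation(seed=cfg.stage_seed("activation", subj))
        session = generate_session(cfg.protocol, replace(model, rng_seed=subj_seed), cfg.frontend)
        if cfg.experiment.paired:
            assigned = cond_names
        else:
            assigned = [cond_names[subj % len(cond_names)]]
        for cond in assigned:
            logger.info("subject %d condition %s", subj, cond)
            row = subject_metrics(
                session, replace(model, rng_seed=subj_seed), cfg,
                subject_seed=subj_seed,
                channel_subset=cfg.experiment.conditions[cond],
            )
            row["subject"] = subj
            tables[cond].append(row)

    frames = {c: pd.DataFrame(rows).set_index("subject") for c, rows in tables.items()}
    summaries = {c: summarize(df) for c, df in frames.items()}

    comparisons = {}
    for i, a in enumerate(cond_names):
        for b in cond_names[i + 1:]:
            res = compare_conditions(
                frames[a], frames[b], paired=cfg.experiment.paired,
                m=cfg.stats.m, alpha=cfg.stats.alpha,
            )
            comparisons[f"{a}_vs_{b}"] = res

    bundle = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "tables": frames,
        "summaries": summaries,
        "comparisons": comparisons,
        "elapsed_s": time.time() - t_start,
    }
    if out_dir is not None:
        _write_bundle(bundle, cfg, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": bundle["config_hash"], "seed": bundle["seed"]}
    for cond, df in bundle["tables"].items():
        df.to_csv(out_dir / f"metrics_{cond}.csv")
    for cond, df in bundle["summaries"].items():
        df.to_csv(out_dir / f"summary_{cond}.csv")
    for name, res in bundle["comparisons"].items():
        comparison_report(res).to_csv(out_dir / f"comparison_{name}.csv", index=False)
    (out_dir / "experiment.json").write_text(json.dumps({
        **stamp,
        "elapsed_s": bundle["elapsed_s"],
        "conditions": list(bundle["tables"]),
        "comparisons": {
            name: [r.__dict__ for r in res]
            for name, res in bundle["comparisons"].items()
        },
    }, indent=1))
    logger.info("experiment bundle written to %s", out_dir)
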