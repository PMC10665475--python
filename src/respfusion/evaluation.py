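"""Confusion counting, the P = (PPV + S)/2 performance metric, the LOSO
experiment grid, and report aggregation.

Every (held-out subject, scenario, strategy, signal subset) cell trains on
the remaining subjects' recordings of that scenario (training overlap 190)
and tests on the held-out subject (test overlap 200).  Per-cell results are
summarized per scenario and overall by averaging P across folds, matching
how repeated leave-one-subject-out results are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import fusion
from .preprocess import prepare_model_channels
from .snippets import SnippetSet, snippets_from_recording
from .types import (
    MODEL_CHANNEL_ORDER,
    MultimodalRecording,
    PipelineConfig,
    RespFusionError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise RespFusionError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceRecord:
    """PPV, sensitivity and the combined performance P (percent) for one cell."""

    counts: ConfusionCounts
    ppv: float
    sensitivity: float
    p: float
    subject: str = ""
    scenario: str = ""
    strategy: str = ""
    signals: tuple[str, ...] = ()


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """2x2 cross-tabulation of binary prediction against binary truth."""
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise RespFusionError("prediction and truth differ in length")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def performance(counts: ConfusionCounts, **keys) -> PerformanceRecord:
    """P = 100 * (PPV + S) / 2 with PPV = TP/(TP+FP) and S = TP/(TP+FN).

    A zero denominator (no predicted positives, or no true positives in the
    truth) sets the affected term to 0 — the conservative choice — and logs it.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0:
        log.warning("performance: no predicted positives; PPV defined as 0")
        ppv = 0.0
    else:
        ppv = tp / (tp + fp)
    if tp + fn == 0:
        log.warning("performance: no positive snippets in truth; S defined as 0")
        sens = 0.0
    else:
        sens = tp / (tp + fn)
    p = 100.0 * (ppv + sens) / 2.0
    return PerformanceRecord(counts, ppv, sens, p, **keys)


def evaluate_predictions(pred: np.ndarray, truth: np.ndarray, **keys) -> PerformanceRecord:
    return performance(confusion(pred, truth), **keys)


def _round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (report-table convention)."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def run_experiment(
    recordings: Sequence[MultimodalRecording],
    strategies: Sequence[str] = fusion.STRATEGIES,
    signal_subsets: Sequence[tuple[str, ...]] = (MODEL_CHANNEL_ORDER,),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """LOSO x scenario x strategy x signal-subset grid.

    Returns a tidy frame with one row per cell: subject, scenario, strategy,
    signals, confusion counts, PPV, S and P.  The three network strategies in
    a cell are trained once and reused by the hybrid vote, on the same
    deterministic seed schedule as :func:`respfusion.fusion.train_hybrid`.
    """
    config = config or PipelineConfig()
    for subset in signal_subsets:
        unknown = [s for s in subset if s not in MODEL_CHANNEL_ORDER]
        if unknown:
            raise RespFusionError(f"grid cell with unknown signal(s): {unknown}")
    strategies = list(strategies)
    bad = [s for s in strategies if s not in fusion.STRATEGIES]
    if bad:
        raise RespFusionError(f"unknown strategies: {bad}")

    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise RespFusionError("experiment needs at least 2 subjects")
    scenarios = sorted({r.scenario for r in recordings})

    member_strats = set(fusion._MEMBER_SEED_OFFSET) if "hybrid" in strategies else (
        set(strategies)
    )

    prepared = {
        i: prepare_model_channels(rec, config) for i, rec in enumerate(recordings)
    }

    rows = []
    for scenario in scenarios:
        idx_in_scenario = [i for i, r in enumerate(recordings) if r.scenario == scenario]
        snips_train = {
            i: snippets_from_recording(
                recordings[i], config, config.train_overlap, prepared=prepared[i]
            )
            for i in idx_in_scenario
        }
        for held_out in subjects:
            test_idx = [
                i for i in idx_in_scenario if recordings[i].subject_id == held_out
            ]
            train_idx = [
                i for i in idx_in_scenario if recordings[i].subject_id != held_out
            ]
            if not test_idx or not train_idx:
                continue
            train_set = SnippetSet.concat([snips_train[i] for i in train_idx])
            test_set = SnippetSet.concat(
                [
                    snippets_from_recording(
                        recordings[i], config, config.test_overlap, prepared=prepared[i]
                    )
                    for i in test_idx
                ]
            )
            for subset in signal_subsets:
                preds: dict[str, np.ndarray] = {}
                for strategy in sorted(member_strats):
                    spec = fusion.FusionArchitectureSpec(
                        strategy=strategy,
                        signals=tuple(subset),
                        n_filters=config.n_filters,
                        filter_len=config.filter_len,
                        dropout=config.dropout,
                        pool_size=config.pool_size,
                        threshold=config.threshold,
                        seed=config.seed + fusion._MEMBER_SEED_OFFSET[strategy],
                    )
                    model = fusion.build_model(
                        spec, config.snippet_len, tuple(train_set.channel_names)
                    )
                    fusion.train(model, train_set, config)
                    preds[strategy] = fusion.predict(model, test_set).y
                if "hybrid" in strategies:
                    preds["hybrid"] = fusion.majority_vote(
                        preds["early"], preds["signal_late"], preds["sensor_late"]
                    )
                for strategy in strategies:
                    rec_perf = evaluate_predictions(
                        preds[strategy],
                        test_set.labels,
                        subject=held_out,
                        scenario=scenario,
                        strategy=strategy,
                        signals=tuple(subset),
                    )
                    rows.append(
                        {
                            "subject": held_out,
                            "scenario": scenario,
                            "strategy": strategy,
                            "signals": "+".join(subset),
                            "tp": rec_perf.counts.tp,
                            "tn": rec_perf.counts.tn,
                            "fp": rec_perf.counts.fp,
                            "fn": rec_perf.counts.fn,
                            "ppv": rec_perf.ppv,
                            "s": rec_perf.sensitivity,
                            "p": rec_perf.p,
                        }
                    )
    return pd.DataFrame(rows)


def aggregate_scenarios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-strategy scenario means of P and the overall Mean_P.

    ``table`` is tidy with at least columns ``strategy``, ``scenario``, ``p``
    (one row per fold or one pre-averaged row per scenario).  P is first
    averaged within each scenario across folds; Mean_P is the arithmetic mean
    of the scenario means.  Rounding (2 decimals, half away from zero) is
    applied only at this report stage.
    """
    if table.empty:
        raise RespFusionError("empty results table")
    from .types import SCENARIOS

    present = [s for s in SCENARIOS if s in set(table["scenario"])]
    missing = set(SCENARIOS) - set(present)
    if missing:
        log.warning("aggregate_scenarios: missing scenarios %s; averaging the rest",
                    sorted(missing))
    out = {}
    for strategy, grp in table.groupby("strategy", sort=False):
        means = {sc: grp.loc[grp["scenario"] == sc, "p"].mean() for sc in present}
        mean_p = float(np.mean(list(means.values())))
        out[strategy] = {**{sc: _round2(v) for sc, v in means.items()},
                         "mean_p": _round2(mean_p)}
    return pd.DataFrame(out).T.rename_axis("strategy")


def usable_time_report(summary: pd.DataFrame) -> dict:
    """Restate the best strategy's overall Mean_P as the usable share of
    driving time.

    The equation of snippet-classification performance with usable driving
    time is an interpretation (a correctly classified snippet = a usable
    moment); the report labels it as such rather than asserting it.
    """
    if summary.empty:
        raise RespFusionError("empty summary")
    best_p = summary["mean_p"].max()
    best = sorted(summary.index[summary["mean_p"] == best_p].tolist())
    return {
        "best_strategies": best,
        "mean_p": float(best_p),
        "usable_time_percent": float(best_p),
        "note": (
            "usable-time share equals the best strategy's mean snippet "
            "performance P; this equation is an interpretation, not a "
            "separately measured duty cycle"
        ),
    }
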