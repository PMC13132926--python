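"""Exclusion cascade and participant-level quality control.

The cascade mirrors the standard treatment of untimed RT paradigms:

1. responses slower than a hard cutoff (default 5000 ms, strict ``>``) are
   flagged ``too_long``;
2. among the remaining *correct* responses, RTs deviating more than k
   standard deviations (default k = 2, strict) from the participant's mean
   correct RT — computed separately for each trial type x experimental
   block cell — are flagged ``rt_outlier``.

Flags never delete rows; downstream stages select on them. Error trials are
kept for percentage-error analyses and are excluded from RT analyses only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_data import ParticipantDataset, SWITCHING_KINDS

__all__ = [
    "DEFAULT_RT_CUTOFF_MS",
    "DiscardSummary",
    "QCReport",
    "analysis_mask",
    "flag_long_rts",
    "flag_outliers",
    "discard_summary",
    "qc_participant",
]

log = logging.getLogger(__name__)

DEFAULT_RT_CUTOFF_MS = 5000.0
QC_MAX_BLOCK_ERROR_PCT = 20.0
QC_MIN_TRIALS_PER_TASK_CONDITION = 40


def analysis_mask(trials: pd.DataFrame, include_warmup: bool = False) -> pd.Series:
    """Boolean mask of trials entering the analysis.

    Defaults to experimental-phase trials excluding the warm-up switching
    block each run starts with (it exists to prepare participants).
    """
    kinds = {"task_switching", "single_task"}
    if include_warmup:
        kinds = kinds | {"warmup_switching"}
    return (trials["phase"] == "experimental") & trials["block_kind"].isin(kinds)


def flag_long_rts(
    dataset: ParticipantDataset, cutoff_ms: float = DEFAULT_RT_CUTOFF_MS
) -> ParticipantDataset:
    """Flag responses with rt_ms strictly greater than ``cutoff_ms``."""
    if cutoff_ms <= 0:
        raise ValueError("cutoff_ms must be positive")
    trials = dataset.trials.copy()
    trials["too_long"] = trials["rt_ms"] > cutoff_ms
    n = int(trials["too_long"].sum())
    if n:
        log.info("%s: %d trial(s) flagged too_long (> %g ms)", dataset.participant_id, n, cutoff_ms)
    return dataset.with_trials(trials)


def flag_outliers(
    dataset: ParticipantDataset, k: float = 2.0, min_cell: int = 3
) -> ParticipantDataset:
    """Flag correct RTs outside mean +- k*SD of their trial-type x block cell.

    The cell statistics use only correct, not-too-long trials; the sample SD
    (n-1 denominator) is used, the band is strict, and cells with fewer than
    ``min_cell`` eligible trials produce no flags (the SD is unreliable
    there). A single pass is made — no iterative re-trimming.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    trials = dataset.trials.copy()
    if "too_long" not in trials.columns:
        raise ValueError("run flag_long_rts before flag_outliers")
    eligible = trials["correct"] & ~trials["too_long"]
    stats = (
        trials[eligible]
        .groupby(["block_id", "trial_type"])["rt_ms"]
        .agg(["mean", "std", "size"])
    )
    flags = np.zeros(len(trials), dtype=bool)
    rt = trials["rt_ms"].to_numpy()
    for (bid, tt), row in stats.iterrows():
        if row["size"] < min_cell or not np.isfinite(row["std"]) or row["std"] == 0:
            continue
        in_cell = (
            eligible
            & (trials["block_id"] == bid)
            & (trials["trial_type"] == tt)
        ).to_numpy()
        flags |= in_cell & (np.abs(rt - row["mean"]) > k * row["std"])
    trials["rt_outlier"] = flags
    n = int(flags.sum())
    if n:
        log.info("%s: %d RT outlier(s) flagged (k=%g)", dataset.participant_id, n, k)
    return dataset.with_trials(trials)


@dataclass
class DiscardSummary:
    """Per-participant discard rates in one condition, plus cohort summary.

    Two accounting conventions are supported: convention "A" counts
    too-long and outlier trials over all analyzed trials of the condition;
    convention "B" additionally counts error trials (which leave the RT
    analysis although they stay in the error analysis).
    """

    condition: str
    convention: str
    per_participant: pd.DataFrame  # participant_id, n_total, n_too_long, n_outlier, n_error, discard_rate
    mean_rate: float = field(init=False)
    sd_rate: float = field(init=False)

    def __post_init__(self) -> None:
        rates = self.per_participant["discard_rate"]
        self.mean_rate = float(rates.mean())
        self.sd_rate = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0


def discard_summary(
    datasets: list[ParticipantDataset],
    condition: str,
    convention: str = "A",
    include_warmup: bool = False,
) -> DiscardSummary:
    if convention not in {"A", "B"}:
        raise ValueError("convention must be 'A' or 'B'")
    rows = []
    for ds in datasets:
        t = ds.trials
        sel = t[analysis_mask(t, include_warmup) & (t["condition"] == condition)]
        if len(sel) == 0:
            continue
        n_total = len(sel)
        n_long = int(sel["too_long"].sum())
        n_out = int(sel["rt_outlier"].sum())
        n_err = int((~sel["correct"] & ~sel["too_long"]).sum())
        n_disc = n_long + n_out + (n_err if convention == "B" else 0)
        rows.append(
            dict(
                participant_id=ds.participant_id,
                n_total=n_total,
                n_too_long=n_long,
                n_outlier=n_out,
                n_error=n_err,
                discard_rate=100.0 * n_disc / n_total,
            )
        )
    if not rows:
        raise ValueError(f"no trials for condition {condition!r}")
    return DiscardSummary(condition, convention, pd.DataFrame(rows))


@dataclass
class QCReport:
    participant_id: str
    passed: bool
    max_block_error_rate: float
    min_trials_per_task_condition: int
    reasons: list[str]


def qc_participant(dataset: ParticipantDataset, include_warmup: bool = True) -> QCReport:
    """Participant-level inclusion check.

    A participant passes iff every experimental block of every condition has
    strictly less than 20% errors and every task x condition cell holds at
    least 40 trials. The warm-up switching blocks count as blocks for the
    error criterion (they are blocks of the condition) but trial counts use
    the analyzed blocks only.
    """
    t = dataset.trials
    exp = t[t["phase"] == "experimental"]
    reasons: list[str] = []
    if len(exp) == 0:
        return QCReport(dataset.participant_id, False, float("nan"), 0, ["no experimental trials"])
    per_block_err = exp.groupby("block_id")["correct"].apply(lambda c: 100.0 * (~c).mean())
    max_err = float(per_block_err.max())
    if max_err >= QC_MAX_BLOCK_ERROR_PCT:
        worst = per_block_err.idxmax()
        reasons.append(f"block {worst} error rate {max_err:.1f}% >= {QC_MAX_BLOCK_ERROR_PCT:g}%")
    analyzed = exp[analysis_mask(exp, include_warmup=False)]
    counts = analyzed.groupby(["condition", "task"]).size()
    min_trials = int(counts.min()) if len(counts) else 0
    if min_trials < QC_MIN_TRIALS_PER_TASK_CONDITION:
        cell = counts.idxmin() if len(counts) else ("-", "-")
        reasons.append(
            f"min trials {min_trials} (< {QC_MIN_TRIALS_PER_TASK_CONDITION}) "
            f"in condition {cell[0]!r}, task {cell[1]!r}"
        )
    return QCReport(dataset.participant_id, not reasons, max_err, min_trials, reasons)
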