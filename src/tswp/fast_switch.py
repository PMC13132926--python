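"""Fast-switch scoring and the fast switch rate (FSR).

A *fast switch* is a correct switch response that (i) is at least as fast as
the 25% fastest single-task responses in the upcoming single-task block(s)
of the same experimental run, and (ii) does not owe its speed to
compensatory prolongation of the three same-task trials immediately
preceding the switch. The compensation check contrasts the summed response
time of those three trials (the *interval*) with the mean interval
preceding non-candidate switches of the same participant and condition; if
the surplus exceeds the performance benefit of the switch (mean single-task
RT minus switch RT), the switch is declassified.

The FSR is the proportion of correct fast switches among all correct switch
trials, per participant and condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import analysis_mask
from .trial_data import ParticipantDataset

__all__ = [
    "SwitchReference",
    "ConditionFSR",
    "FastSwitchError",
    "single_task_reference",
    "references_for_dataset",
    "annotate_fast_switches",
    "compute_fsr",
]

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "participant_id",
    "condition",
    "block_id",
    "trial_index",
    "task",
    "rt_ms",
    "correct",
    "flagged",
    "threshold_ms",
    "mean_single_rt_ms",
    "candidate",
    "interval_ms",
    "baseline_interval_ms",
    "prolongation_ms",
    "benefit_ms",
    "comp_checked",
    "is_fast",
]


class FastSwitchError(ValueError):
    """Raised when a fast-switch reference cannot be constructed."""


@dataclass(frozen=True)
class SwitchReference:
    """Single-task reference for one switching block and target task.

    ``threshold_ms`` is the first RT quartile (linear-interpolation
    quantile) of the eligible single-task responses from the run's
    subsequent single-task block(s); ``mean_single_rt_ms`` the arithmetic
    mean of the same sample.
    """

    threshold_ms: float
    mean_single_rt_ms: float
    n: int
    task: str
    source_blocks: tuple
    low_n: bool = False


def _eligible_rt_mask(trials: pd.DataFrame) -> pd.Series:
    m = trials["correct"]
    if "too_long" in trials.columns:
        m = m & ~trials["too_long"]
    if "rt_outlier" in trials.columns:
        m = m & ~trials["rt_outlier"]
    return m


def single_task_reference(
    dataset: ParticipantDataset,
    switching_block_id,
    task: str,
    policy: str = "task_matched",
) -> SwitchReference:
    """Reference from the single-task block(s) following a switching block.

    ``policy`` selects ``task_matched`` (a switch into the digit task is
    referenced against digit single-task RTs) or ``pooled`` (both tasks'
    single-task RTs pooled).
    """
    if policy not in {"task_matched", "pooled"}:
        raise ValueError(f"unknown reference policy {policy!r}")
    blocks = dataset.blocks
    sw = blocks[blocks["block_id"] == switching_block_id]
    if len(sw) == 0:
        raise FastSwitchError(f"unknown block {switching_block_id!r}")
    sw = sw.iloc[0]
    singles = blocks[
        (blocks["block_kind"] == "single_task")
        & (blocks["phase"] == sw["phase"])
        & (blocks["condition"] == sw["condition"])
        & (blocks["run_index"] == sw["run_index"])
        & (blocks["block_id"] > switching_block_id)
    ]
    trials = dataset.trials
    pool = trials[trials["block_id"].isin(singles["block_id"])]
    if policy == "task_matched":
        pool = pool[pool["task"] == task]
    if len(pool) == 0:
        raise FastSwitchError(
            f"no subsequent single-task block for task {task!r} in run "
            f"{sw['run_index']} of condition {sw['condition']!r}"
        )
    rts = pool.loc[_eligible_rt_mask(pool), "rt_ms"].to_numpy()
    if len(rts) == 0:
        raise FastSwitchError(
            f"no eligible single-task RTs for task {task!r} in run {sw['run_index']}"
        )
    low_n = len(rts) < 4
    if low_n:
        warnings.warn(
            f"single-task reference for block {switching_block_id!r}, task {task!r} "
            f"built from only {len(rts)} RT(s)",
            stacklevel=2,
        )
    return SwitchReference(
        threshold_ms=float(np.quantile(rts, 0.25)),  # linear interpolation ("type 7")
        mean_single_rt_ms=float(rts.mean()),
        n=int(len(rts)),
        task=task if policy == "task_matched" else "pooled",
        source_blocks=tuple(sorted(pool["block_id"].unique())),
        low_n=low_n,
    )


def references_for_dataset(
    dataset: ParticipantDataset,
    policy: str = "task_matched",
    include_warmup: bool = False,
) -> dict:
    """References for every analyzed switching block, keyed (block_id, task)."""
    kinds = {"task_switching"} | ({"warmup_switching"} if include_warmup else set())
    blocks = dataset.blocks
    out: dict = {}
    for row in blocks[
        blocks["block_kind"].isin(kinds) & (blocks["phase"] == "experimental")
    ].itertuples():
        for task in ("letter", "digit"):
            out[(row.block_id, task)] = single_task_reference(
                dataset, row.block_id, task, policy
            )
    return out


def annotate_fast_switches(
    dataset: ParticipantDataset,
    condition: str,
    references: dict,
    compensation: bool = True,
    include_warmup: bool = False,
) -> pd.DataFrame:
    """Annotate every switch trial of one condition with its fast verdict.

    Candidate status uses the RT criterion alone (inclusive: "at least as
    fast" means rt <= threshold) on correct, unflagged switch trials. The
    preceding interval sums all three same-task responses regardless of
    correctness ("total time taken to respond"); runs containing a
    too-long-flagged response yield a null interval. The baseline is the
    mean interval over the condition's non-candidate switches (errors and
    flagged switches are non-candidates). For candidates whose interval and
    baseline exist, ``is_fast = prolongation <= benefit``; where the check
    is inapplicable (truncated first run, null interval, undefined
    baseline, or ``compensation=False``) the candidate verdict stands.
    Declassified candidates do not re-enter the baseline (single pass).
    """
    trials = dataset.trials
    if "too_long" not in trials.columns or "rt_outlier" not in trials.columns:
        raise ValueError("preprocessing flags must be set before annotation")
    kinds = {"task_switching"} | ({"warmup_switching"} if include_warmup else set())
    sel = trials[
        analysis_mask(trials, include_warmup)
        & (trials["condition"] == condition)
        & trials["block_kind"].isin(kinds)
    ]
    rows: list[dict] = []
    for bid, block in sel.groupby("block_id", sort=True):
        block = block.sort_values("trial_index").reset_index(drop=True)
        rt = block["rt_ms"].to_numpy()
        too_long = block["too_long"].to_numpy()
        for i in np.flatnonzero((block["trial_type"] == "switch").to_numpy()):
            t = block.iloc[i]
            ref = references.get((bid, t["task"]))
            if ref is None:
                raise FastSwitchError(f"missing reference for block {bid!r}, task {t['task']!r}")
            flagged = bool(t["too_long"] or t["rt_outlier"])
            candidate = bool(t["correct"] and not flagged and t["rt_ms"] <= ref.threshold_ms)
            if i >= 3 and not too_long[i - 3 : i].any():
                interval = float(rt[i - 3 : i].sum())
            else:
                interval = np.nan
            rows.append(
                dict(
                    participant_id=dataset.participant_id,
                    condition=condition,
                    block_id=bid,
                    trial_index=int(t["trial_index"]),
                    task=t["task"],
                    rt_ms=float(t["rt_ms"]),
                    correct=bool(t["correct"]),
                    flagged=flagged,
                    threshold_ms=ref.threshold_ms,
                    mean_single_rt_ms=ref.mean_single_rt_ms,
                    candidate=candidate,
                    interval_ms=interval,
                )
            )
    ann = pd.DataFrame(rows, columns=[c for c in ANNOTATION_COLUMNS if c not in
                                      ("baseline_interval_ms", "prolongation_ms",
                                       "benefit_ms", "comp_checked", "is_fast")])
    if len(ann) == 0:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)

    noncand = ann[~ann["candidate"] & ann["interval_ms"].notna()]
    baseline = float(noncand["interval_ms"].mean()) if len(noncand) else np.nan
    ann["baseline_interval_ms"] = baseline
    ann["prolongation_ms"] = ann["interval_ms"] - baseline
    ann["benefit_ms"] = ann["mean_single_rt_ms"] - ann["rt_ms"]
    applicable = (
        ann["candidate"]
        & ann["interval_ms"].notna()
        & np.isfinite(baseline)
        & bool(compensation)
    )
    ann["comp_checked"] = applicable
    ann["is_fast"] = ann["candidate"] & (
        ~applicable | (ann["prolongation_ms"] <= ann["benefit_ms"])
    )
    return ann[ANNOTATION_COLUMNS]


@dataclass(frozen=True)
class ConditionFSR:
    """A participant x condition FSR with its count provenance.

    ``fsr`` is a proportion in [0, 1], or None when the participant produced
    no correct unflagged switch trials in the condition (reported, never
    silently 0).
    """

    participant_id: str
    condition: str
    n_correct_switches: int
    n_fast: int
    fsr: float | None
    reason: str | None = None

    @property
    def fsr_pct(self) -> float | None:
        return None if self.fsr is None else 100.0 * self.fsr


def compute_fsr(annotations: pd.DataFrame, participant_id: str, condition: str) -> ConditionFSR:
    """FSR = correct fast switches / all correct (unflagged) switch trials."""
    sel = annotations[
        (annotations["participant_id"] == participant_id)
        & (annotations["condition"] == condition)
    ]
    denom = int((sel["correct"] & ~sel["flagged"]).sum())
    n_fast = int(sel["is_fast"].sum())
    if denom == 0:
        log.info("%s/%s: FSR undefined (no correct switch trials)", participant_id, condition)
        return ConditionFSR(participant_id, condition, 0, 0, None, "no correct switch trials")
    return ConditionFSR(participant_id, condition, denom, n_fast, n_fast / denom)
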