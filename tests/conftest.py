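"""Shared fixtures: synthetic cohorts generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tswp.fast_switch import annotate_fast_switches, compute_fsr, references_for_dataset
from tswp.preprocess import flag_long_rts, flag_outliers
from tswp.synthetic import default_config, simulate_cohort
from tswp.trial_data import EXPERIMENT_CONDITIONS, ParticipantDataset, build_block_table


@pytest.fixture(scope="session")
def exp2_cohort():
    """The study-condition exp2 cohort: 16 participants per mode, seed 42."""
    return simulate_cohort(default_config("exp2", seed=42, n_per_mode=16))


@pytest.fixture(scope="session")
def exp2_scored(exp2_cohort):
    """Preprocessed + fast-switch-scored exp2 cohort.

    Returns (flagged datasets, fsr dict keyed (participant, condition),
    annotations dict keyed participant).
    """
    flagged, fsrs, anns = [], {}, {}
    for ds in exp2_cohort.datasets:
        d2 = flag_outliers(flag_long_rts(ds))
        flagged.append(d2)
        refs = references_for_dataset(d2)
        frames = []
        for cond in EXPERIMENT_CONDITIONS["exp2"]:
            ann = annotate_fast_switches(d2, cond, refs)
            frames.append(ann)
            fsrs[(ds.participant_id, cond)] = compute_fsr(ann, ds.participant_id, cond).fsr
        anns[ds.participant_id] = pd.concat(frames, ignore_index=True)
    return flagged, fsrs, anns


@pytest.fixture(scope="session")
def small_exp1_cohort():
    """Tiny exp1 cohort (2 per mode) for data-model and round-trip tests."""
    return simulate_cohort(default_config("exp1", seed=7, n_per_mode=2))


def make_dataset(rows, participant_id="p0", experiment="exp1"):
    """Build a ParticipantDataset from a list of trial dicts, filling the
    long-format columns that the scenario does not care about."""
    defaults = dict(
        participant_id=participant_id,
        experiment=experiment,
        phase="experimental",
        condition="full",
        block_id="b000",
        block_kind="single_task",
        block_duration_s=60.0,
        run_index=0,
        task="letter",
        trial_type="single",
        seq_position=None,
        preview_visible=False,
        rt_ms=500.0,
        correct=True,
        stimulus="A",
        response="S",
    )
    full = []
    for i, r in enumerate(rows):
        rec = dict(defaults)
        rec["trial_index"] = i
        rec.update(r)
        full.append(rec)
    trials = pd.DataFrame(full)
    # trial_index restarts at 0 within each block
    trials["trial_index"] = trials.groupby("block_id").cumcount()
    trials["seq_position"] = trials["seq_position"].astype("Int64")
    return ParticipantDataset(participant_id, experiment, trials, build_block_table(trials))


def switching_run_rows(rts, condition="full", block_id="b001", start_task="letter",
                       correct=None, duration=120.0):
    """Rows of a task-switching block with AAABBB structure from RT list."""
    from tswp.trial_data import PREVIEW_POSITIONS, TRIAL_TYPE_BY_POSITION

    visible = PREVIEW_POSITIONS[condition]
    rows = []
    task = start_task
    for i, rt in enumerate(rts):
        pos = i % 3 + 1
        if i > 0 and pos == 1:
            task = "digit" if task == "letter" else "letter"
        rows.append(
            dict(block_id=block_id, block_kind="task_switching", condition=condition,
                 block_duration_s=duration, task=task,
                 trial_type=TRIAL_TYPE_BY_POSITION[pos], seq_position=pos,
                 preview_visible=pos in visible, rt_ms=float(rt),
                 correct=True if correct is None else correct[i])
        )
    return rows


def single_block_rows(rts, task="letter", condition="full", block_id="b002"):
    return [
        dict(block_id=block_id, block_kind="single_task", condition=condition,
             block_duration_s=60.0, task=task, trial_type="single",
             seq_position=None, preview_visible=False, rt_ms=float(rt))
        for rt in rts
    ]
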