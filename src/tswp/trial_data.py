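"""Trial-stream data model for task switching with preview (TSWP).

A TSWP session is a sequence of fixed-duration blocks. In *task-switching*
blocks two classification tasks (letter, digit) alternate in a predictable
AAABBB pattern, so every trial occupies one of three positions within its
three-trial same-task run: position 1 is a *switch* trial (the task just
changed), position 2 a pure *repeat* trial, position 3 a *pre-switch* trial
(the last trial before the next switch). *Single-task* blocks present one
task only. Depending on the experimental condition, the upcoming task's
stimulus is visible in advance (the preview) at some subset of the three
run positions.

This module defines the long-format trial log (one row per response), its
reader/writer, and a validator that checks the structural invariants the
downstream analysis relies on.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "PREVIEW_POSITIONS",
    "EXPERIMENT_CONDITIONS",
    "TRIAL_TYPE_BY_POSITION",
    "ColumnSchema",
    "ParticipantDataset",
    "ReadResult",
    "SchemaError",
    "StructureError",
    "Violation",
    "read_trial_log",
    "write_trial_log",
    "validate_dataset",
    "build_block_table",
    "derive_trial_types",
]

#: Canonical column order of a trial log. One row per response.
TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "phase",
    "condition",
    "block_id",
    "block_kind",
    "block_duration_s",
    "run_index",
    "trial_index",
    "task",
    "trial_type",
    "seq_position",
    "preview_visible",
    "rt_ms",
    "correct",
    "stimulus",
    "response",
]

EXPERIMENTS = {"exp1", "exp2"}
PHASES = {"practice", "experimental"}
BLOCK_KINDS = {"single_task", "warmup_switching", "task_switching"}
TASKS = {"letter", "digit"}
TRIAL_TYPES = {"single", "switch", "repeat", "preswitch"}

#: Run positions (1..3) at which the preview is visible, per condition.
PREVIEW_POSITIONS: dict[str, frozenset[int]] = {
    "full": frozenset({1, 2, 3}),
    "medium": frozenset({2, 3}),
    "short": frozenset({3}),
    "early": frozenset({1}),
    "middle": frozenset({2}),
    "late": frozenset({3}),
}

EXPERIMENT_CONDITIONS: dict[str, list[str]] = {
    "exp1": ["full", "medium", "short"],
    "exp2": ["full", "early", "middle", "late"],
}

TRIAL_TYPE_BY_POSITION = {1: "switch", 2: "repeat", 3: "preswitch"}
POSITION_BY_TRIAL_TYPE = {v: k for k, v in TRIAL_TYPE_BY_POSITION.items()}

SWITCHING_KINDS = {"warmup_switching", "task_switching"}


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class StructureError(ValueError):
    """A trial log violates the block/sequence structure beyond repair."""


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping from external column / label names onto the canonical schema.

    ``columns`` maps external column names to canonical ``TRIAL_COLUMNS``
    entries; canonical names that already appear in the file need no entry.
    ``condition_labels`` maps external condition labels (e.g. ``"fullP"``)
    onto the canonical condition names, ``task_labels`` and
    ``trial_type_labels`` likewise. This lets externally deposited logs be
    ingested through configuration alone.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    condition_labels: Mapping[str, str] = field(default_factory=dict)
    task_labels: Mapping[str, str] = field(default_factory=dict)
    trial_type_labels: Mapping[str, str] = field(default_factory=dict)
    true_values: tuple[str, ...] = ("True", "true", "TRUE", "1", "yes")
    false_values: tuple[str, ...] = ("False", "false", "FALSE", "0", "no")

    def rename(self, columns: Iterable[str]) -> dict[str, str]:
        return {c: self.columns.get(c, c) for c in columns}


@dataclass
class ParticipantDataset:
    """All trials of one participant, ordered by (block_id, trial_index).

    ``trials`` is a long-format DataFrame over ``TRIAL_COLUMNS`` plus any
    flag columns added downstream; ``blocks`` is the per-block metadata
    table derived from the trials (see :func:`build_block_table`).
    """

    participant_id: str
    experiment: str
    trials: pd.DataFrame
    blocks: pd.DataFrame

    def __post_init__(self) -> None:
        if self.blocks is None:
            self.blocks = build_block_table(self.trials)

    def with_trials(self, trials: pd.DataFrame) -> "ParticipantDataset":
        """Copy of this dataset with a replaced trial table."""
        return ParticipantDataset(
            self.participant_id, self.experiment, trials, build_block_table(trials)
        )


@dataclass
class Violation:
    invariant: str
    block_id: object
    trial_index: object
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.invariant}] block {self.block_id}, trial {self.trial_index}: {self.message}"


@dataclass
class ReadResult:
    """Datasets parsed from a trial log plus the rows that were rejected."""

    datasets: list[ParticipantDataset]
    rejections: pd.DataFrame  # original row plus a "reason" column


def build_block_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive the per-block metadata table from a trial table.

    ``follows_block`` is, for a single-task block, the id of the most recent
    preceding switching block in the same experimental run (the switching
    block whose fast-switch reference it provides); null otherwise.
    """
    if len(trials) == 0:
        return pd.DataFrame(
            columns=[
                "block_id",
                "block_kind",
                "condition",
                "duration_s",
                "run_index",
                "phase",
                "n_trials",
                "follows_block",
            ]
        )
    grp = trials.groupby("block_id", sort=True)
    blocks = grp.agg(
        block_kind=("block_kind", "first"),
        condition=("condition", "first"),
        duration_s=("block_duration_s", "first"),
        run_index=("run_index", "first"),
        phase=("phase", "first"),
        n_trials=("trial_index", "size"),
    ).reset_index()
    follows: list[object] = []
    last_switching: dict[tuple, object] = {}
    for row in blocks.itertuples(index=False):
        key = (row.phase, row.condition, row.run_index)
        if row.block_kind == "task_switching":
            last_switching[key] = row.block_id
            follows.append(None)
        elif row.block_kind == "single_task":
            follows.append(last_switching.get(key))
        else:
            follows.append(None)
    blocks["follows_block"] = follows
    return blocks


def derive_trial_types(tasks: Sequence[str]) -> list[str]:
    """Reconstruct trial types from the task sequence of one switching block.

    Positions within each same-task run are found by scanning run
    boundaries; the first trial of a block starts a run and is labelled a
    switch, matching the AAABBB convention.
    """
    out: list[str] = []
    pos = 0
    prev: str | None = None
    for t in tasks:
        pos = pos + 1 if t == prev else 1
        if pos > 3:
            raise StructureError(f"run of more than three consecutive '{t}' trials")
        out.append(TRIAL_TYPE_BY_POSITION[pos])
        prev = t
    return out


def _parse_bool(value: str, schema: ColumnSchema, column: str) -> bool:
    if value in schema.true_values:
        return True
    if value in schema.false_values:
        return False
    raise ValueError(f"unparseable boolean {value!r} in column {column!r}")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_trial_log(path: str | Path, schema: ColumnSchema | None = None) -> ReadResult:
    """Read a long-format trial log into validated participant datasets.

    Rows violating hard row-level invariants (non-positive or non-numeric
    RT, unknown enum labels) are rejected with a reason and returned in
    ``rejections``. A missing ``trial_type`` or ``seq_position`` column is
    reconstructed from the task sequence. Structural inconsistencies in the
    AAABBB pattern raise :class:`StructureError` via validation downstream;
    here only per-row parsing is enforced.
    """
    schema = schema or ColumnSchema()
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            return ReadResult([], pd.DataFrame(columns=TRIAL_COLUMNS + ["reason"]))
        delim = _sniff_delimiter(header_line)
        fh.seek(0)
        raw = pd.read_csv(fh, sep=delim, dtype=str, keep_default_na=False)

    raw = raw.rename(columns=schema.rename(raw.columns))
    optional = {"trial_type", "seq_position", "stimulus", "response", "run_index"}
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns and c not in optional]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in optional:
        if c not in raw.columns:
            raw[c] = ""

    rows: list[dict] = []
    rejected: list[dict] = []

    def reject(rec: dict, reason: str) -> None:
        rec = dict(rec)
        rec["reason"] = reason
        rejected.append(rec)

    for rec in raw.to_dict("records"):
        out = dict(rec)
        try:
            rt = float(rec["rt_ms"])
        except (TypeError, ValueError):
            reject(rec, "non-numeric RT")
            continue
        if not np.isfinite(rt) or rt <= 0:
            reject(rec, "non-positive RT")
            continue
        out["rt_ms"] = rt
        out["condition"] = schema.condition_labels.get(rec["condition"], rec["condition"])
        out["task"] = schema.task_labels.get(rec["task"], rec["task"])
        tt = rec.get("trial_type", "")
        out["trial_type"] = schema.trial_type_labels.get(tt, tt)
        try:
            out["correct"] = _parse_bool(rec["correct"], schema, "correct")
            out["preview_visible"] = _parse_bool(
                rec["preview_visible"], schema, "preview_visible"
            )
            out["trial_index"] = int(rec["trial_index"])
            out["block_duration_s"] = float(rec["block_duration_s"])
            out["run_index"] = int(rec["run_index"]) if str(rec["run_index"]) != "" else 0
        except ValueError as exc:
            reject(rec, str(exc))
            continue
        for col, allowed in [
            ("experiment", EXPERIMENTS),
            ("phase", PHASES),
            ("block_kind", BLOCK_KINDS),
            ("task", TASKS),
        ]:
            if out[col] not in allowed:
                reject(rec, f"unknown {col} label {out[col]!r}")
                out = None
                break
        if out is None:
            continue
        out["seq_position"] = (
            int(rec["seq_position"]) if str(rec["seq_position"]) != "" else None
        )
        rows.append(out)

    rejections = pd.DataFrame(rejected)
    if len(rows) == 0:
        return ReadResult([], rejections)

    trials = pd.DataFrame(rows)
    trials = trials[TRIAL_COLUMNS]
    trials = trials.sort_values(["participant_id", "block_id", "trial_index"], kind="stable")
    trials = trials.reset_index(drop=True)

    # Reconstruct trial_type / seq_position where absent.
    def _fill_types(block: pd.DataFrame) -> pd.DataFrame:
        if block["block_kind"].iat[0] in SWITCHING_KINDS:
            need_tt = (block["trial_type"] == "").any()
            need_sp = block["seq_position"].isna().any()
            if need_tt or need_sp:
                types = derive_trial_types(list(block["task"]))
                if need_tt:
                    block = block.assign(trial_type=types)
                if need_sp:
                    block = block.assign(
                        seq_position=[POSITION_BY_TRIAL_TYPE[t] for t in types]
                    )
        else:
            if (block["trial_type"] == "").any():
                block = block.assign(trial_type="single")
        return block

    parts = [
        _fill_types(block)
        for _, block in trials.groupby(["participant_id", "block_id"], sort=False)
    ]
    trials = pd.concat(parts, ignore_index=True)
    trials["seq_position"] = trials["seq_position"].astype("Int64")

    datasets = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        sub = sub.reset_index(drop=True)
        datasets.append(
            ParticipantDataset(
                participant_id=str(pid),
                experiment=sub["experiment"].iat[0],
                trials=sub,
                blocks=build_block_table(sub),
            )
        )
    return ReadResult(datasets, rejections)


def write_trial_log(
    datasets: Iterable[ParticipantDataset], path: str | Path, sep: str = ","
) -> Path:
    """Write datasets as a long-format delimited text file (UTF-8).

    The canonical columns are written in fixed order with a header line;
    ``read_trial_log(write_trial_log(x))`` reproduces every field, and
    writing the same datasets twice produces byte-identical files.
    """
    path = Path(path)
    frames = [ds.trials[TRIAL_COLUMNS] for ds in datasets]
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=TRIAL_COLUMNS)
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=sep, lineterminator="\n")
    writer.writerow(TRIAL_COLUMNS)
    for row in table.itertuples(index=False):
        rec = list(row)
        sp = rec[TRIAL_COLUMNS.index("seq_position")]
        rec[TRIAL_COLUMNS.index("seq_position")] = "" if pd.isna(sp) else int(sp)
        writer.writerow(rec)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def _check(violations: list[Violation], cond: bool, invariant: str, block, idx, msg: str):
    if not cond:
        violations.append(Violation(invariant, block, idx, msg))


def validate_dataset(dataset: ParticipantDataset) -> list[Violation]:
    """Check every structural invariant; an empty list means a valid dataset.

    Violations are data, not exceptions: each one names the invariant, the
    block and the trial index concerned.
    """
    v: list[Violation] = []
    trials = dataset.trials
    known_blocks = set(dataset.blocks["block_id"])

    for bid, block in trials.groupby("block_id", sort=True):
        block = block.sort_values("trial_index")
        _check(
            v,
            list(block["trial_index"]) == list(range(len(block))),
            "trial ordering",
            bid,
            None,
            "trial_index not consecutive from 0",
        )
        _check(v, bid in known_blocks, "block integrity", bid, None, "block_id missing from block table")
        kind = block["block_kind"].iat[0]
        cond = block["condition"].iat[0]
        for t in block.itertuples():
            _check(v, t.rt_ms > 0, "positive RT", bid, t.trial_index, f"rt_ms={t.rt_ms}")
        if kind == "single_task":
            _check(
                v,
                (block["trial_type"] == "single").all(),
                "single-task trial type",
                bid,
                None,
                "non-'single' trial_type in single-task block",
            )
            _check(
                v,
                block["task"].nunique() == 1,
                "single-task constancy",
                bid,
                None,
                "task varies within single-task block",
            )
            _check(
                v,
                (~block["preview_visible"]).all(),
                "preview/condition consistency",
                bid,
                None,
                "preview visible in a single-task block",
            )
        elif kind in SWITCHING_KINDS:
            try:
                expected = derive_trial_types(list(block["task"]))
            except StructureError as exc:
                v.append(Violation("AAABBB structure", bid, None, str(exc)))
                expected = None
            if expected is not None:
                for t, exp in zip(block.itertuples(), expected):
                    _check(
                        v,
                        t.trial_type == exp,
                        "AAABBB structure",
                        bid,
                        t.trial_index,
                        f"trial_type {t.trial_type!r}, task sequence implies {exp!r}",
                    )
                    _check(
                        v,
                        pd.notna(t.seq_position)
                        and POSITION_BY_TRIAL_TYPE.get(t.trial_type) == t.seq_position,
                        "seq_position/trial_type match",
                        bid,
                        t.trial_index,
                        f"seq_position {t.seq_position} vs trial_type {t.trial_type!r}",
                    )
            visible = PREVIEW_POSITIONS.get(cond)
            if visible is not None:
                for t in block.itertuples():
                    if pd.isna(t.seq_position):
                        continue
                    _check(
                        v,
                        t.preview_visible == (int(t.seq_position) in visible),
                        "preview/condition consistency",
                        bid,
                        t.trial_index,
                        f"preview_visible={t.preview_visible} at position {t.seq_position} "
                        f"in condition {cond!r}",
                    )

    # Every experimental task-switching block needs a subsequent single-task
    # block per task in the same run (the fast-switch reference).
    blocks = dataset.blocks
    exp_sw = blocks[(blocks["block_kind"] == "task_switching") & (blocks["phase"] == "experimental")]
    singles = blocks[blocks["block_kind"] == "single_task"]
    for row in exp_sw.itertuples():
        later = singles[
            (singles["condition"] == row.condition)
            & (singles["run_index"] == row.run_index)
            & (singles["phase"] == row.phase)
            & (singles["block_id"] > row.block_id)
        ]
        tasks_covered = set(
            trials[trials["block_id"].isin(later["block_id"])]["task"].unique()
        )
        _check(
            v,
            tasks_covered >= TASKS,
            "single-task reference availability",
            row.block_id,
            None,
            f"missing subsequent single-task block(s) for {sorted(TASKS - tasks_covered)}",
        )
    return v
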