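"""Synthetic TSWP cohorts with known ground truth.

The generator is a measurement-level emulator of the two preview
experiments: fixed-duration blocks in which the trial count is endogenous
(trials are drawn until their summed response time crosses the block
duration; the crossing trial is kept), predictable AAABBB task alternation,
preview visibility governed by the condition, and mode-dependent RT
structure. It is not a process model of task-set reconfiguration — its job
is to give every pipeline stage a testable input with a known answer.

Response times are lognormal (positive, right-skewed). A participant of a
given processing mode uses a visible preview for the upcoming switch with a
per-participant probability attached to the *latest* run position at which
the preview is visible; a used preview makes the next switch response a
draw from a fast distribution (the single-task distribution sped up by
``fast_factor``) and, with probability ``q_comp``, spreads
``compensation_ms`` over the three trials of the preceding run
(compensatory prolongation). Unused previews leave the switch with an
additive switch cost.

Between-participant heterogeneity is part of the design: preview-use
propensities are Beta-dispersed around the mode means (the serial mode is
strongly right-skewed, mirroring the wide spread of individual no-preview
FSRs in empirical reference distributions) and switch costs vary uniformly
across participants, which gives serial participants a small, bounded rate
of ordinary switches crossing the quantile threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .trial_data import (
    EXPERIMENT_CONDITIONS,
    PREVIEW_POSITIONS,
    TRIAL_COLUMNS,
    TRIAL_TYPE_BY_POSITION,
    ParticipantDataset,
    build_block_table,
)

__all__ = [
    "ModeParams",
    "SimulationConfig",
    "CohortResult",
    "default_mode_params",
    "default_config",
    "simulate_participant",
    "simulate_cohort",
    "ground_truth_fsr",
    "williams_square",
]

# stimulus sets and key mappings of the letter/digit classification tasks
LETTERS_VOWEL = "AEIU"
LETTERS_CONS = "GKMR"
DIGITS_EVEN = "2468"
DIGITS_ODD = "3579"
KEYS = {
    "letter": {"A": "S", "E": "S", "I": "S", "U": "S", "G": "A", "K": "A", "M": "A", "R": "A"},
    "digit": {"2": "K", "4": "K", "6": "K", "8": "K", "3": "L", "5": "L", "7": "L", "9": "L"},
}
STIMULI = {"letter": LETTERS_VOWEL + LETTERS_CONS, "digit": DIGITS_EVEN + DIGITS_ODD}

DEFAULT_BLOCK_PLAN = (
    ("warmup_switching", 60.0),
    ("task_switching", 120.0),
    ("task_switching", 120.0),
    ("single_task", 60.0),
    ("single_task", 60.0),
)


@dataclass(frozen=True)
class ModeParams:
    """Generative parameters of one processing mode.

    ``p_use`` maps run position (1..3) to the mode-mean probability that a
    preview visible up to that position is processed; per-participant
    propensities are Beta(mean * conc, (1-mean) * conc) draws
    (``p_use_concentration``; ``inf`` for a homogeneous mode).
    ``switch_cost_range`` bounds the per-participant uniform switch cost in
    ms. RTs are lognormal with log-median ``base_log_mu`` (per-participant
    jitter ``participant_mu_sd`` on the log scale) and ``base_log_sigma``.
    """

    label: str
    base_log_mu: float = float(np.log(600.0))
    base_log_sigma: float = 0.25
    participant_mu_sd: float = 0.06
    delta_repeat_ms: float = 20.0
    delta_preswitch_ms: float = 10.0
    switch_cost_range: tuple[float, float] = (120.0, 500.0)
    p_use: Mapping[int, float] = field(default_factory=lambda: {1: 0.0, 2: 0.0, 3: 0.02})
    p_use_concentration: float = 10.0
    fast_factor: float = 0.4
    fast_sigma: float = 0.1
    compensation_ms: float = 100.0
    q_comp: float = 0.2
    error_rate: float = 0.035

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.p_use.values()):
            raise ValueError("p_use entries must be probabilities")
        if self.switch_cost_range[0] < 0:
            raise ValueError("switch costs must be nonnegative")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be a probability")


def default_mode_params() -> dict[str, ModeParams]:
    """Frozen study-condition defaults for the three processing modes.

    Preview use is concentrated at run position 3 (just before the switch)
    with mode means 0.02 / 0.15 / 0.45; the serial mode is heavily
    dispersed across participants, the other two only mildly.
    """
    return {
        "serial": ModeParams(
            label="serial",
            switch_cost_range=(50.0, 500.0),
            p_use={1: 0.0, 2: 0.0, 3: 0.02},
            p_use_concentration=10.0,
        ),
        "semi_overlapper": ModeParams(
            label="semi_overlapper",
            switch_cost_range=(90.0, 160.0),
            p_use={1: 0.0, 2: 0.0, 3: 0.15},
            p_use_concentration=150.0,
        ),
        "overlapper": ModeParams(
            label="overlapper",
            switch_cost_range=(90.0, 160.0),
            p_use={1: 0.0, 2: 0.0, 3: 0.45},
            p_use_concentration=150.0,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    experiment: str = "exp2"
    n_per_mode: Mapping[str, int] = field(
        default_factory=lambda: {"serial": 16, "semi_overlapper": 16, "overlapper": 16}
    )
    mode_params: Mapping[str, ModeParams] = field(default_factory=default_mode_params)
    block_plan: tuple = DEFAULT_BLOCK_PLAN
    condition_order_scheme: str = "latin_square"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_CONDITIONS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if any(d <= 0 for _, d in self.block_plan):
            raise ValueError("block durations must be positive")
        kinds = [k for k, _ in self.block_plan]
        if "task_switching" not in kinds or kinds.count("single_task") < 2:
            raise ValueError("block plan needs switching and two single-task blocks per run")

    @property
    def conditions(self) -> list[str]:
        return EXPERIMENT_CONDITIONS[self.experiment]


def default_config(experiment: str = "exp2", seed: int = 0, n_per_mode: int | Mapping[str, int] = 16) -> SimulationConfig:
    if isinstance(n_per_mode, int):
        n_per_mode = {m: n_per_mode for m in ("serial", "semi_overlapper", "overlapper")}
    return SimulationConfig(experiment=experiment, seed=seed, n_per_mode=dict(n_per_mode))


def williams_square(n: int) -> list[list[int]]:
    """Williams design (balanced Latin square) row orders for n conditions.

    Standard construction: first row 0, 1, n-1, 2, n-2, ...; later rows add
    1 mod n; for odd n the mirrored rows are appended so every condition
    also follows every other equally often.
    """
    first = []
    lo, hi = 0, n - 1
    for j in range(n):
        first.append(lo if j % 2 == 0 else hi)
        if j % 2 == 0:
            lo += 1
        else:
            hi -= 1
    rows = [[(c + i) % n for c in first] for i in range(n)]
    if n % 2 == 1:
        rows += [list(reversed(r)) for r in rows]
    return rows


def _condition_orders(config: SimulationConfig) -> list[list[str]]:
    conds = config.conditions
    if config.condition_order_scheme == "fixed":
        return [list(conds)]
    if config.experiment == "exp2":
        # the full-preview baseline always comes first; the remaining
        # conditions are counterbalanced with a Williams design
        rest = [c for c in conds if c != "full"]
        return [["full"] + [rest[i] for i in row] for row in williams_square(len(rest))]
    return [[conds[i] for i in row] for row in williams_square(len(conds))]


@dataclass
class CohortResult:
    datasets: list[ParticipantDataset]
    truth_participants: pd.DataFrame  # participant_id, mode, p_use_1..3, switch_cost_ms, log_mu
    truth_trials: pd.DataFrame  # participant_id, block_id, trial_index, preview_used, injected_fast, comp_ms


class _TrialSink:
    def __init__(self) -> None:
        self.rows: list[tuple] = []
        self.truth: list[tuple] = []

    def add(self, trial: tuple, truth: tuple) -> None:
        self.rows.append(trial)
        self.truth.append(truth)


def _draw_stimulus(rng: np.random.Generator, task: str, last: dict) -> str:
    pool = STIMULI[task]
    while True:
        s = pool[rng.integers(len(pool))]
        if s != last.get(task):
            last[task] = s
            return s


def simulate_participant(
    participant_id: str,
    mode_params: ModeParams,
    config: SimulationConfig,
    participant_seed,
    condition_order: list[str] | None = None,
) -> tuple[ParticipantDataset, dict, pd.DataFrame]:
    """Simulate one participant; returns (dataset, latent truth, trial truth).

    Blocks run for a fixed time: trials are drawn until the summed RT
    reaches the block duration, and the boundary-crossing trial is kept.
    """
    rng = np.random.default_rng(participant_seed)
    mp = mode_params
    mu_i = mp.base_log_mu + rng.normal(0.0, mp.participant_mu_sd)
    cost_i = rng.uniform(*mp.switch_cost_range)
    p_i: dict[int, float] = {}
    for pos in (1, 2, 3):
        mean = float(mp.p_use.get(pos, 0.0))
        if mean <= 0.0 or mean >= 1.0 or not np.isfinite(mp.p_use_concentration):
            p_i[pos] = mean
        else:
            k = mp.p_use_concentration
            p_i[pos] = float(rng.beta(mean * k, (1 - mean) * k))
    order = condition_order or config.conditions
    sink = _TrialSink()
    last_stim: dict[str, str] = {}
    block_seq = 0

    for run_index, condition in enumerate(order):
        visible = PREVIEW_POSITIONS[condition]
        latest = max(visible)
        single_tasks = ["letter", "digit"] if run_index % 2 == 0 else ["digit", "letter"]
        single_iter = iter(single_tasks)
        start_task = "letter" if run_index % 2 == 0 else "digit"
        for kind, duration in config.block_plan:
            bid = f"b{block_seq:03d}"
            block_seq += 1
            budget = duration * 1000.0
            elapsed = 0.0
            idx = 0
            if kind == "single_task":
                task = next(single_iter)
                while elapsed < budget:
                    rt = float(rng.lognormal(mu_i, mp.base_log_sigma))
                    correct = bool(rng.random() >= mp.error_rate)
                    stim = _draw_stimulus(rng, task, last_stim)
                    resp = KEYS[task][stim] if correct else _wrong_key(task, stim)
                    sink.add(
                        (participant_id, config.experiment, "experimental", condition,
                         bid, kind, duration, run_index, idx, task, "single", None,
                         False, rt, correct, stim, resp),
                        (participant_id, bid, idx, False, False, 0.0),
                    )
                    elapsed += rt
                    idx += 1
            else:
                task = start_task
                pos = 0  # position within the current run, 0-based
                use_next = False   # preview used for the upcoming switch
                comp_add = 0.0     # compensation spread over this run's trials
                pending_fast = False
                while elapsed < budget:
                    if pos == 0:
                        # run start: decide preview use for the *next* switch
                        pending_fast = use_next
                        use_next = bool(rng.random() < p_i[latest])
                        comp_add = (
                            mp.compensation_ms / 3.0
                            if use_next and rng.random() < mp.q_comp
                            else 0.0
                        )
                    seq_position = pos + 1
                    trial_type = TRIAL_TYPE_BY_POSITION[seq_position]
                    injected = False
                    if seq_position == 1:
                        if pending_fast:
                            rt = float(rng.lognormal(mu_i + np.log(mp.fast_factor), mp.fast_sigma))
                            injected = True
                        else:
                            rt = float(rng.lognormal(mu_i, mp.base_log_sigma)) + cost_i
                    elif seq_position == 2:
                        rt = float(rng.lognormal(mu_i, mp.base_log_sigma)) + mp.delta_repeat_ms
                    else:
                        rt = float(rng.lognormal(mu_i, mp.base_log_sigma)) + mp.delta_preswitch_ms
                    comp_here = comp_add if seq_position in (1, 2, 3) else 0.0
                    rt += comp_here
                    correct = bool(rng.random() >= mp.error_rate)
                    stim = _draw_stimulus(rng, task, last_stim)
                    resp = KEYS[task][stim] if correct else _wrong_key(task, stim)
                    sink.add(
                        (participant_id, config.experiment, "experimental", condition,
                         bid, kind, duration, run_index, idx, task, trial_type,
                         seq_position, seq_position in visible, rt, correct, stim, resp),
                        (participant_id, bid, idx, bool(use_next and seq_position == 3),
                         injected, comp_here),
                    )
                    elapsed += rt
                    idx += 1
                    pos += 1
                    if pos == 3:
                        pos = 0
                        task = "digit" if task == "letter" else "letter"

    trials = pd.DataFrame(sink.rows, columns=TRIAL_COLUMNS)
    trials["seq_position"] = trials["seq_position"].astype("Int64")
    truth_trials = pd.DataFrame(
        sink.truth,
        columns=["participant_id", "block_id", "trial_index", "preview_used",
                 "injected_fast", "comp_ms"],
    )
    truth = dict(
        participant_id=participant_id,
        mode=mp.label,
        p_use_1=p_i[1],
        p_use_2=p_i[2],
        p_use_3=p_i[3],
        switch_cost_ms=cost_i,
        log_mu=mu_i,
    )
    ds = ParticipantDataset(participant_id, config.experiment, trials, build_block_table(trials))
    return ds, truth, truth_trials


def _wrong_key(task: str, stim: str) -> str:
    keys = sorted(set(KEYS[task].values()))
    right = KEYS[task][stim]
    return keys[0] if right != keys[0] else keys[1]


def simulate_cohort(config: SimulationConfig) -> CohortResult:
    """Simulate n_per_mode participants per mode, deterministically.

    Per-participant seeds are spawned from the master seed; identical
    config and seed give identical output, trial for trial.
    """
    orders = _condition_orders(config)
    ss = np.random.SeedSequence(config.seed)
    modes = [m for m in ("serial", "semi_overlapper", "overlapper") if config.n_per_mode.get(m, 0) > 0]
    total = sum(config.n_per_mode[m] for m in modes)
    child_seeds = ss.spawn(total)
    datasets, truths, truth_trials = [], [], []
    i = 0
    for mode in modes:
        mp = config.mode_params[mode]
        for _ in range(config.n_per_mode[mode]):
            pid = f"p{i:03d}"
            ds, truth, tt = simulate_participant(
                pid, mp, config, child_seeds[i], orders[i % len(orders)]
            )
            datasets.append(ds)
            truths.append(truth)
            truth_trials.append(tt)
            i += 1
    return CohortResult(
        datasets=datasets,
        truth_participants=pd.DataFrame(truths),
        truth_trials=pd.concat(truth_trials, ignore_index=True),
    )


def ground_truth_fsr(
    dataset: ParticipantDataset,
    truth_trials: pd.DataFrame,
    condition: str,
    include_warmup: bool = False,
) -> float | None:
    """Generator-truth FSR: correct injected fast switches / correct switches.

    Uses the same analyzed-block scope as the pipeline (experimental
    switching blocks, warm-up excluded by default).
    """
    t = dataset.trials
    kinds = {"task_switching"} | ({"warmup_switching"} if include_warmup else set())
    sel = t[
        (t["phase"] == "experimental")
        & t["block_kind"].isin(kinds)
        & (t["condition"] == condition)
        & (t["trial_type"] == "switch")
    ]
    merged = sel.merge(
        truth_trials[truth_trials["participant_id"] == dataset.participant_id],
        on=["participant_id", "block_id", "trial_index"],
        how="left",
    )
    denom = int(merged["correct"].sum())
    if denom == 0:
        return None
    return float((merged["correct"] & merged["injected_fast"]).sum() / denom)
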