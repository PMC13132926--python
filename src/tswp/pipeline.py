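"""End-to-end analysis: preprocessing -> fast-switch scoring -> FSR ->
classification -> summary tables and robust statistics.

`analyze_experiment` reproduces the structure of the preview experiments'
result tables for either experiment: per-participant FSRs by condition,
processing-mode classification on the full-preview condition, trimmed-mean
summaries of FSRs and RTs per mode x condition (x trial type), switch-RT
prolongation contrasts, percentage-error and discard tables, the robust
between x within ANOVA on FSRs, and per-group exploratory ANOVAs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import ModeCutoffs, classify_cohort, derive_cutoffs
from .fast_switch import annotate_fast_switches, compute_fsr, references_for_dataset
from .preprocess import (
    DEFAULT_RT_CUTOFF_MS,
    analysis_mask,
    discard_summary,
    flag_long_rts,
    flag_outliers,
    qc_participant,
)
from .stats import bw_trimmed_anova, rm_anova_gg, trimmed_mean
from .trial_data import EXPERIMENT_CONDITIONS, ParticipantDataset, validate_dataset

__all__ = ["AnalysisConfig", "SummaryTables", "analyze_experiment"]

log = logging.getLogger(__name__)

TRIAL_TYPE_ORDER = ["single", "switch", "repeat", "preswitch"]


@dataclass
class AnalysisConfig:
    """Every analytic choice of the pipeline, with its documented default."""

    experiment: str = "exp2"
    rt_cutoff_ms: float = DEFAULT_RT_CUTOFF_MS
    outlier_k: float = 2.0
    outlier_min_cell: int = 3
    reference_policy: str = "task_matched"  # or "pooled"
    trim: float = 0.20
    cutoffs: ModeCutoffs | None = None
    reference_fsrs: list[float] | None = None  # proportions; used if cutoffs is None
    discard_convention: str = "A"
    include_warmup: bool = False
    compensation: bool = True
    basis_condition: str = "full"
    seed: int = 0

    def resolve_cutoffs(self) -> ModeCutoffs:
        if self.cutoffs is not None:
            return self.cutoffs
        if self.reference_fsrs is not None:
            return derive_cutoffs(self.reference_fsrs, provenance="configured reference sample")
        raise ValueError(
            "no classification cutoffs configured: set cutoffs.c1/cutoffs.c3 "
            "or provide a reference FSR sample"
        )


@dataclass
class SummaryTables:
    fsr: pd.DataFrame                       # participant x condition FSRs with counts
    classification: pd.DataFrame            # participant, basis_fsr, label
    fsr_by_group_condition: pd.DataFrame    # trimmed mean / SE / n per mode x condition
    rt_by_group_condition_trialtype: pd.DataFrame
    delta_hat: pd.DataFrame                 # switch prolongation, both contrasts
    pe_by_condition_trialtype: pd.DataFrame
    discard: pd.DataFrame
    qc: pd.DataFrame
    anova_fsr: pd.DataFrame                 # robust between x within ANOVA
    anova_exploratory: pd.DataFrame         # per-group one-way (within) ANOVAs
    annotations: pd.DataFrame               # per-switch-trial audit table
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "fsr", "classification", "fsr_by_group_condition",
            "rt_by_group_condition_trialtype", "delta_hat",
            "pe_by_condition_trialtype", "discard", "qc", "anova_fsr",
            "anova_exploratory", "annotations",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return outdir


def analyze_experiment(datasets: list[ParticipantDataset], config: AnalysisConfig) -> SummaryTables:
    conditions = EXPERIMENT_CONDITIONS[config.experiment]
    if not datasets:
        raise ValueError("no participants supplied")

    # --- validation and QC ------------------------------------------------
    qc_rows, kept, dropped = [], [], []
    for ds in datasets:
        violations = validate_dataset(ds)
        if violations:
            dropped.append((ds.participant_id, f"{len(violations)} structural violation(s)"))
            log.warning("%s: dropped (%s)", ds.participant_id, violations[0])
            continue
        rep = qc_participant(ds)
        qc_rows.append(
            dict(participant_id=ds.participant_id, passed=rep.passed,
                 max_block_error_rate=rep.max_block_error_rate,
                 min_trials_per_task_condition=rep.min_trials_per_task_condition,
                 reasons="; ".join(rep.reasons))
        )
        if rep.passed:
            kept.append(ds)
        else:
            dropped.append((ds.participant_id, "; ".join(rep.reasons)))
    if not kept:
        raise ValueError("no participants after QC")
    qc_table = pd.DataFrame(qc_rows)

    # --- preprocessing flags ---------------------------------------------
    kept = [
        flag_outliers(flag_long_rts(ds, config.rt_cutoff_ms), config.outlier_k,
                      config.outlier_min_cell)
        for ds in kept
    ]

    # --- discard accounting ----------------------------------------------
    discard_rows = []
    for cond in conditions:
        summ = discard_summary(kept, cond, config.discard_convention, config.include_warmup)
        discard_rows.append(
            dict(condition=cond, convention=summ.convention,
                 mean_discard_pct=summ.mean_rate, sd_discard_pct=summ.sd_rate,
                 n_participants=len(summ.per_participant))
        )
    discard_table = pd.DataFrame(discard_rows)

    # --- fast-switch scoring and FSRs ------------------------------------
    ann_frames, fsr_rows = [], []
    for ds in kept:
        refs = references_for_dataset(ds, config.reference_policy, config.include_warmup)
        for cond in conditions:
            ann = annotate_fast_switches(ds, cond, refs, config.compensation,
                                         config.include_warmup)
            ann_frames.append(ann)
            f = compute_fsr(ann, ds.participant_id, cond)
            fsr_rows.append(
                dict(participant_id=f.participant_id, condition=f.condition,
                     n_correct_switches=f.n_correct_switches, n_fast=f.n_fast,
                     fsr=f.fsr, fsr_pct=f.fsr_pct)
            )
    annotations = pd.concat(ann_frames, ignore_index=True)
    fsr_table = pd.DataFrame(fsr_rows)

    # --- classification ---------------------------------------------------
    cutoffs = config.resolve_cutoffs()
    classification = classify_cohort(fsr_table, cutoffs, config.basis_condition)
    unclass = classification[classification["label"] == "unclassifiable"]
    for pid in unclass["participant_id"]:
        log.info("%s: excluded from group analyses (unclassifiable)", pid)
    labels = classification.set_index("participant_id")["label"]
    fsr_table = fsr_table.merge(
        classification[["participant_id", "label"]], on="participant_id", how="left"
    )

    # --- summary tables ---------------------------------------------------
    grouped = fsr_table[fsr_table["label"].isin(("serial", "semi_overlapper", "overlapper"))]
    fsr_group_rows = []
    for (lab, cond), sub in grouped.groupby(["label", "condition"], sort=True):
        vals = sub["fsr"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        ts = trimmed_mean(vals, config.trim if len(vals) >= 5 else 0.0)
        fsr_group_rows.append(
            dict(label=lab, condition=cond, n=ts.n, fsr_mt=ts.mt, fsr_ma=ts.ma,
                 fsr_se_trimmed=ts.se_trimmed, fsr_mt_pct=100 * ts.mt)
        )
    fsr_by_group = pd.DataFrame(fsr_group_rows)

    rt_rows = []
    pe_rows = []
    for ds in kept:
        t = ds.trials
        lab = labels.get(ds.participant_id, "unclassifiable")
        sel = t[analysis_mask(t, config.include_warmup)]
        rt_ok = sel[sel["correct"] & ~sel["too_long"] & ~sel["rt_outlier"]]
        for (cond, tt), sub in rt_ok.groupby(["condition", "trial_type"], sort=True):
            rt_rows.append(dict(participant_id=ds.participant_id, label=lab,
                                condition=cond, trial_type=tt,
                                mean_rt_ms=float(sub["rt_ms"].mean()), n=len(sub)))
        for (cond, kind), sub in sel.groupby(["condition", "block_kind"], sort=True):
            pe_rows.append(dict(participant_id=ds.participant_id, condition=cond,
                                block_kind=kind, pe_pct=100.0 * float((~sub["correct"]).mean())))
    rt_participant = pd.DataFrame(rt_rows)

    rt_group_rows = []
    for (lab, cond, tt), sub in rt_participant.groupby(["label", "condition", "trial_type"], sort=True):
        vals = sub["mean_rt_ms"].to_numpy()
        ts = trimmed_mean(vals, config.trim if len(vals) >= 5 else 0.0)
        rt_group_rows.append(dict(label=lab, condition=cond, trial_type=tt, n=ts.n,
                                  rt_mt_ms=ts.mt, rt_ma_ms=ts.ma, rt_se_trimmed=ts.se_trimmed))
    rt_by_group = pd.DataFrame(rt_group_rows)

    # switch prolongation: switch trimmed mean minus the mean of the other
    # trial types' trimmed means, with and without the single-task baseline
    delta_rows = []
    for (lab, cond), sub in rt_by_group.groupby(["label", "condition"], sort=True):
        by_tt = sub.set_index("trial_type")["rt_mt_ms"]
        if "switch" not in by_tt:
            continue
        others_all = [by_tt[t] for t in ("single", "repeat", "preswitch") if t in by_tt]
        others_sw = [by_tt[t] for t in ("repeat", "preswitch") if t in by_tt]
        delta_rows.append(
            dict(label=lab, condition=cond,
                 delta_vs_all_ms=float(by_tt["switch"] - np.mean(others_all)) if others_all else np.nan,
                 delta_vs_mixed_ms=float(by_tt["switch"] - np.mean(others_sw)) if others_sw else np.nan)
        )
    delta_hat = pd.DataFrame(delta_rows)

    pe_participant = pd.DataFrame(pe_rows)
    pe_table = (
        pe_participant.groupby(["condition", "block_kind"], sort=True)["pe_pct"]
        .agg(["mean", "std", "size"])
        .rename(columns={"mean": "pe_mean_pct", "std": "pe_sd_pct", "size": "n"})
        .reset_index()
    )

    # --- inferential statistics -------------------------------------------
    anova_input = grouped.dropna(subset=["fsr"])
    complete = (
        anova_input.groupby("participant_id")["condition"].nunique() == len(conditions)
    )
    anova_input = anova_input[anova_input["participant_id"].map(complete)]
    try:
        anova_fsr = bw_trimmed_anova(
            anova_input, dv="fsr", between="label", within="condition",
            subject="participant_id", trim=config.trim,
        )
    except ValueError as exc:
        log.warning("robust ANOVA unavailable: %s", exc)
        anova_fsr = pd.DataFrame()

    expl_frames = []
    for lab, sub in anova_input.groupby("label", sort=True):
        if sub["participant_id"].nunique() < 3:
            continue
        tab = rm_anova_gg(sub, dv="fsr", within="condition", subject="participant_id")
        tab.insert(0, "group", lab)
        expl_frames.append(tab)
    anova_expl = pd.concat(expl_frames, ignore_index=True) if expl_frames else pd.DataFrame()

    manifest = dict(
        tswp_version=__version__,
        experiment=config.experiment,
        n_input=len(datasets),
        n_after_qc=len(kept),
        dropped=[{"participant_id": p, "reason": r} for p, r in dropped],
        unclassifiable=list(unclass["participant_id"]),
        cutoffs=dict(c1=cutoffs.c1, c3=cutoffs.c3, provenance=cutoffs.provenance),
        config=dict(
            rt_cutoff_ms=config.rt_cutoff_ms, outlier_k=config.outlier_k,
            outlier_min_cell=config.outlier_min_cell,
            reference_policy=config.reference_policy, trim=config.trim,
            discard_convention=config.discard_convention,
            include_warmup=config.include_warmup, compensation=config.compensation,
            basis_condition=config.basis_condition, seed=config.seed,
        ),
    )

    return SummaryTables(
        fsr=fsr_table,
        classification=classification,
        fsr_by_group_condition=fsr_by_group,
        rt_by_group_condition_trialtype=rt_by_group,
        delta_hat=delta_hat,
        pe_by_condition_trialtype=pe_table,
        discard=discard_table,
        qc=qc_table,
        anova_fsr=anova_fsr,
        anova_exploratory=anova_expl,
        annotations=annotations,
        manifest=manifest,
    )
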