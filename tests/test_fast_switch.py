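"""Fast-switch scoring: quartile references, compensation correction, FSR."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _oracles import naive_fast_switch_analysis, naive_quantile25
from conftest import make_dataset, single_block_rows, switching_run_rows
from tswp.fast_switch import (
    FastSwitchError,
    annotate_fast_switches,
    compute_fsr,
    references_for_dataset,
    single_task_reference,
)
from tswp.preprocess import flag_long_rts, flag_outliers
from tswp.synthetic import SimulationConfig, default_mode_params, simulate_cohort


def _prepped(rows, **kw):
    return flag_outliers(flag_long_rts(make_dataset(rows, **kw)), k=100.0)


class TestSingleTaskReference:
    def test_interpolated_first_quartile(self):
        ds = _prepped(
            switching_run_rows([500] * 6, block_id="b001")
            + single_block_rows([400, 500, 600, 700], block_id="b002")
            + single_block_rows([500, 500, 500, 500], task="digit", block_id="b003")
        )
        ref = single_task_reference(ds, "b001", "letter")
        assert ref.threshold_ms == pytest.approx(475.0)  # 400 + 0.75 * 100
        assert ref.mean_single_rt_ms == pytest.approx(550.0)

    def test_constant_sample(self):
        ds = _prepped(
            switching_run_rows([500] * 6, block_id="b001")
            + single_block_rows([500] * 4, block_id="b002")
            + single_block_rows([500] * 4, task="digit", block_id="b003")
        )
        ref = single_task_reference(ds, "b001", "letter")
        assert (ref.threshold_ms, ref.mean_single_rt_ms) == (500.0, 500.0)
        assert not ref.low_n

    def test_single_rt_flagged_low_n(self):
        ds = _prepped(
            switching_run_rows([500] * 6, block_id="b001")
            + single_block_rows([500], block_id="b002")
            + single_block_rows([500] * 4, task="digit", block_id="b003")
        )
        with pytest.warns(UserWarning, match="only 1"):
            ref = single_task_reference(ds, "b001", "letter")
        assert ref.low_n and ref.threshold_ms == 500.0

    def test_missing_single_task_block_raises(self):
        ds = _prepped(switching_run_rows([500] * 6, block_id="b001"))
        with pytest.raises(FastSwitchError, match="run"):
            single_task_reference(ds, "b001", "letter")

    def test_matches_linear_quantile_oracle(self):
        rng = np.random.default_rng(2)
        rts = list(rng.lognormal(6.4, 0.3, 37))
        ds = _prepped(
            switching_run_rows([500] * 6, block_id="b001")
            + single_block_rows(rts, block_id="b002")
            + single_block_rows([500] * 4, task="digit", block_id="b003")
        )
        ref = single_task_reference(ds, "b001", "letter")
        assert ref.threshold_ms == pytest.approx(naive_quantile25(rts))


def _comp_scenario(candidate_interval_rts, switch_rt, single_rts):
    """Block: non-candidate run with interval fixing the baseline at 2000,
    then a candidate switch preceded by the given three-trial run."""
    rts = (
        [2000 / 3] * 3             # letter run; next switch's interval = 2000
        + [2000 / 3] * 3           # digit run; interval 2000
        + [900, 550, 550]          # letter run; interval 2000
        + list(candidate_interval_rts)  # digit run preceding the candidate
        + [switch_rt, 600, 600]    # letter candidate switch
    )
    rows = switching_run_rows(rts, block_id="b001")
    rows += single_block_rows(single_rts, block_id="b002")
    rows += single_block_rows(single_rts, task="digit", block_id="b003")
    return _prepped(rows)


class TestCompensationCorrection:
    def test_candidate_rule_is_inclusive(self):
        ds = _prepped(
            switching_run_rows([475, 500, 500, 600, 600, 600], block_id="b001")
            + single_block_rows([400, 500, 600, 700], block_id="b002")
            + single_block_rows([400, 500, 600, 700], task="digit", block_id="b003")
        )
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        first = ann.iloc[0]
        assert first["threshold_ms"] == pytest.approx(475.0)
        assert bool(first["candidate"])

    def test_prolongation_exceeding_benefit_declassifies(self):
        # interval 2500 vs baseline 2000, benefit 600 - 450 = 150 < 500
        ds = _comp_scenario([2500 / 3] * 3, 450.0, [600] * 8)
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        cand = ann[ann["candidate"] & ann["comp_checked"]]
        assert len(cand) == 1
        row = cand.iloc[0]
        assert row["prolongation_ms"] == pytest.approx(500.0)
        assert row["benefit_ms"] == pytest.approx(150.0)
        assert not row["is_fast"]

    def test_prolongation_within_benefit_keeps_fast(self):
        # interval 2100 vs baseline 2000: prolongation 100 <= benefit 150
        ds = _comp_scenario([700, 700, 700], 450.0, [600] * 8)
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        cand = ann[ann["candidate"] & ann["comp_checked"]]
        row = cand.iloc[0]
        assert row["prolongation_ms"] == pytest.approx(100.0)
        assert bool(row["is_fast"])

    def test_error_switch_never_fast(self):
        rts = [475, 500, 500, 475, 600, 600]
        correct = [True, True, True, False, True, True]
        ds = _prepped(
            switching_run_rows(rts, block_id="b001", correct=correct)
            + single_block_rows([400, 500, 600, 700], block_id="b002")
            + single_block_rows([400, 500, 600, 700], task="digit", block_id="b003")
        )
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        err = ann[~ann["correct"]].iloc[0]
        assert not err["candidate"] and not err["is_fast"]

    def test_truncated_first_run_skips_compensation(self):
        ds = _prepped(
            switching_run_rows([450, 500, 500, 900, 900, 900], block_id="b001")
            + single_block_rows([600] * 8, block_id="b002")
            + single_block_rows([600] * 8, task="digit", block_id="b003")
        )
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        first = ann.iloc[0]
        assert bool(first["candidate"]) and not first["comp_checked"]
        assert bool(first["is_fast"])

    def test_too_long_in_preceding_run_nullifies_interval(self):
        ds = flag_outliers(
            flag_long_rts(
                make_dataset(
                    switching_run_rows([500, 500, 500, 5500, 700, 700, 450, 600, 600],
                                       block_id="b001")
                    + single_block_rows([600] * 8, block_id="b002")
                    + single_block_rows([600] * 8, task="digit", block_id="b003")
                )
            ),
            k=100.0,
        )
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        third_switch = ann[ann["trial_index"] == 6].iloc[0]
        assert np.isnan(third_switch["interval_ms"])
        assert bool(third_switch["is_fast"]) == bool(third_switch["candidate"])


class TestFSR:
    def test_exact_ratio(self, exp2_scored):
        _, fsrs, anns = exp2_scored
        ds_id = sorted(anns)[0]
        ann = anns[ds_id]
        f = compute_fsr(ann, ds_id, "full")
        assert f.fsr == pytest.approx(f.n_fast / f.n_correct_switches)
        assert 0 <= f.fsr <= 1

    def test_zero_fast(self):
        ds = _prepped(
            switching_run_rows([900] * 12, block_id="b001")
            + single_block_rows([600] * 8, block_id="b002")
            + single_block_rows([600] * 8, task="digit", block_id="b003")
        )
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        assert compute_fsr(ann, "p0", "full").fsr == 0.0

    def test_no_correct_switches_is_explicit_null(self):
        rts = [900, 500, 500, 900, 600, 600]
        correct = [False, True, True, False, True, True]
        ds = _prepped(
            switching_run_rows(rts, block_id="b001", correct=correct)
            + single_block_rows([600] * 8, block_id="b002")
            + single_block_rows([600] * 8, task="digit", block_id="b003")
        )
        ann = annotate_fast_switches(ds, "full", references_for_dataset(ds))
        f = compute_fsr(ann, "p0", "full")
        assert f.fsr is None and f.reason == "no correct switch trials"


class TestProperties:
    def test_threshold_monotonicity_of_candidates(self, exp2_scored):
        """Raising the threshold never removes a candidate."""
        flagged, _, _ = exp2_scored
        ds = flagged[40]
        refs = references_for_dataset(ds)
        ann = annotate_fast_switches(ds, "full", refs)
        from dataclasses import replace

        refs_hi = {k: replace(v, threshold_ms=v.threshold_ms + 50) for k, v in refs.items()}
        ann_hi = annotate_fast_switches(ds, "full", refs_hi)
        assert not (ann["candidate"] & ~ann_hi["candidate"]).any()
        # without the compensation check the fast count is monotone too
        ann_nc = annotate_fast_switches(ds, "full", refs, compensation=False)
        ann_hi_nc = annotate_fast_switches(ds, "full", refs_hi, compensation=False)
        assert ann_hi_nc["is_fast"].sum() >= ann_nc["is_fast"].sum()

    def test_uniform_preswitch_slowing_is_caught(self, exp2_scored):
        """Adding a constant to all three trials preceding every candidate
        (and nothing else) preserves or reduces the number of fast switches,
        and removes them all once the constant exceeds every benefit."""
        flagged, _, _ = exp2_scored
        ds = flagged[40]  # an overlapper: plenty of candidates
        refs = references_for_dataset(ds)
        base_ann = annotate_fast_switches(ds, "full", refs)
        cand = base_ann[base_ann["candidate"]]
        n_prev = base_ann["is_fast"].sum()
        assert n_prev > 0
        for c in (200.0, 600.0, 1500.0):
            trials = ds.trials.copy()
            for r in cand.itertuples():
                blk = trials["block_id"] == r.block_id
                prev = trials["trial_index"].between(r.trial_index - 3, r.trial_index - 1)
                trials.loc[blk & prev, "rt_ms"] += c
            bumped = ds.with_trials(trials)
            ann = annotate_fast_switches(bumped, "full", refs)
            n_now = ann["is_fast"].sum()
            assert n_now <= n_prev
            n_prev = n_now
        # once the slowing exceeds every benefit, only candidates exempt
        # from the compensation check can remain fast
        assert n_now <= (~cand["comp_checked"]).sum()

    def test_bruteforce_oracle_equivalence_small_datasets(self):
        """On small cohorts the vectorized scoring agrees exactly with a
        naive loop re-implementation (thresholds, candidacy, compensation,
        FSR)."""
        plan = (
            ("warmup_switching", 30.0),
            ("task_switching", 45.0),
            ("task_switching", 45.0),
            ("single_task", 30.0),
            ("single_task", 30.0),
        )
        for seed, experiment in [(5, "exp1"), (9, "exp2")]:
            cfg = SimulationConfig(
                experiment=experiment, seed=seed,
                n_per_mode={"serial": 1, "semi_overlapper": 1, "overlapper": 1},
                mode_params=default_mode_params(), block_plan=plan,
            )
            cohort = simulate_cohort(cfg)
            for ds in cohort.datasets:
                d2 = flag_outliers(flag_long_rts(ds))
                refs = references_for_dataset(d2)
                for cond in cfg.conditions:
                    ann = annotate_fast_switches(d2, cond, refs)
                    verdicts, fsr = naive_fast_switch_analysis(d2, cond)
                    assert len(ann) == len(verdicts)
                    for r in ann.itertuples():
                        cand, fast = verdicts[(r.block_id, r.trial_index)]
                        assert r.candidate == cand and r.is_fast == fast
                    got = compute_fsr(ann, ds.participant_id, cond).fsr
                    assert got == pytest.approx(fsr) if fsr is not None else got is None
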