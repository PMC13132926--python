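"""Independent brute-force re-implementations used as test oracles.

Everything here is written with naive loops and no shared code with the
package's vectorized paths: interpolated quantiles, candidate flagging, the
compensatory-prolongation correction, FSR, trimmed/winsorized statistics
and the variance-weighted group separation.
"""

from __future__ import annotations

import math


def naive_quantile25(values):
    """Linear-interpolation first quartile (type-7), computed by hand."""
    xs = sorted(float(v) for v in values)
    if len(xs) == 1:
        return xs[0]
    pos = 0.25 * (len(xs) - 1)
    lo = int(math.floor(pos))
    frac = pos - lo
    if lo + 1 >= len(xs):
        return xs[lo]
    return xs[lo] + frac * (xs[lo + 1] - xs[lo])


def naive_trimmed_mean(values, trim):
    xs = sorted(float(v) for v in values)
    g = int(math.floor(len(xs) * trim))
    core = xs[g : len(xs) - g]
    return sum(core) / len(core)


def naive_winsorized_variance(values, trim):
    xs = sorted(float(v) for v in values)
    g = int(math.floor(len(xs) * trim))
    w = list(xs)
    for i in range(g):
        w[i] = xs[g]
        w[len(xs) - 1 - i] = xs[len(xs) - 1 - g]
    m = sum(w) / len(w)
    return sum((v - m) ** 2 for v in w) / (len(w) - 1)


def naive_kms_two_groups(a, b):
    """Classical (untrimmed) variance-weighted standardized separation,
    doubled to the Cohen's-d scale, written directly from the formula."""
    def mean(x):
        return sum(x) / len(x)

    def var(x):
        m = mean(x)
        return sum((v - m) ** 2 for v in x) / (len(x) - 1)

    n1, n2 = len(a), len(b)
    m1, m2, v1, v2 = mean(a), mean(b), var(a), var(b)
    n = n1 + n2
    w1, w2 = n1 / v1, n2 / v2
    mbar = (w1 * m1 + w2 * m2) / (w1 + w2)
    delta2 = (n1 / n) * (m1 - mbar) ** 2 / v1 + (n2 / n) * (m2 - mbar) ** 2 / v2
    return 2.0 * math.sqrt(delta2)


def naive_fast_switch_analysis(dataset, condition):
    """Loop-based fast-switch scoring for one participant and condition.

    Returns (verdicts, fsr) where verdicts maps (block_id, trial_index) ->
    (candidate, is_fast). Mirrors the documented rules: task-matched
    quartile thresholds from the run's later single-task blocks, inclusive
    candidate rule, intervals of the three preceding responses (null when
    truncated or containing a too-long response), baseline = mean interval
    over non-candidates of the condition, single-pass declassification.
    """
    trials = dataset.trials
    blocks = dataset.blocks.set_index("block_id")

    def block_rows(bid):
        sub = trials[trials["block_id"] == bid]
        return sub.sort_values("trial_index").to_dict("records")

    # thresholds per (switching block, task)
    refs = {}
    for bid, brow in blocks.iterrows():
        if brow["block_kind"] != "task_switching" or brow["phase"] != "experimental":
            continue
        for task in ("letter", "digit"):
            rts = []
            for sid, srow in blocks.iterrows():
                if (
                    srow["block_kind"] == "single_task"
                    and srow["phase"] == brow["phase"]
                    and srow["condition"] == brow["condition"]
                    and srow["run_index"] == brow["run_index"]
                    and sid > bid
                ):
                    for r in block_rows(sid):
                        if (
                            r["task"] == task
                            and r["correct"]
                            and not r["too_long"]
                            and not r["rt_outlier"]
                        ):
                            rts.append(r["rt_ms"])
            if rts:
                refs[(bid, task)] = (
                    naive_quantile25(rts),
                    sum(rts) / len(rts),
                )

    switch_info = []
    for bid, brow in blocks.iterrows():
        if (
            brow["block_kind"] != "task_switching"
            or brow["phase"] != "experimental"
            or brow["condition"] != condition
        ):
            continue
        rows = block_rows(bid)
        for i, r in enumerate(rows):
            if r["trial_type"] != "switch":
                continue
            thr, mean_single = refs[(bid, r["task"])]
            flagged = bool(r["too_long"] or r["rt_outlier"])
            cand = bool(r["correct"] and not flagged and r["rt_ms"] <= thr)
            if i >= 3 and not any(rows[j]["too_long"] for j in range(i - 3, i)):
                interval = sum(rows[j]["rt_ms"] for j in range(i - 3, i))
            else:
                interval = None
            switch_info.append(
                dict(block_id=bid, trial_index=r["trial_index"], correct=r["correct"],
                     flagged=flagged, cand=cand, interval=interval, thr=thr,
                     mean_single=mean_single, rt=r["rt_ms"])
            )

    base_vals = [s["interval"] for s in switch_info if not s["cand"] and s["interval"] is not None]
    baseline = sum(base_vals) / len(base_vals) if base_vals else None

    verdicts = {}
    n_fast = 0
    n_denom = 0
    for s in switch_info:
        if s["cand"] and s["interval"] is not None and baseline is not None:
            prolongation = s["interval"] - baseline
            benefit = s["mean_single"] - s["rt"]
            fast = prolongation <= benefit
        else:
            fast = s["cand"]
        verdicts[(s["block_id"], s["trial_index"])] = (s["cand"], fast)
        if s["correct"] and not s["flagged"]:
            n_denom += 1
        if fast:
            n_fast += 1
    fsr = n_fast / n_denom if n_denom else None
    return verdicts, fsr
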