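# tswp — fast-switch analysis of task switching with preview

`tswp` is an analysis pipeline for *task switching with preview* (TSWP)
experiments: alternating-runs task switching (AAABBB) in which the stimulus
of the upcoming task can be visible in advance as a preview. People differ
in whether they use that preview — some process tasks strictly serially,
others preprocess the upcoming stimulus in parallel with the current task.
The pipeline quantifies that difference from trial-level response-time
logs and is aimed at researchers analyzing such paradigms (or building
simulation studies around them).

## The statistic at its core

A **fast switch** is a correct switch response whose RT is at least as fast
as the first quartile of the eligible single-task RTs from the upcoming
single-task block of the same experimental run,

&nbsp;&nbsp;&nbsp;&nbsp;RT_switch ≤ Q₁(RT_single),

provided it does not owe its speed to **compensatory prolongation**: for
each switch the summed RT of the three preceding same-task trials (the
interval *I*) is contrasted with the mean interval *Ī* preceding
non-candidate switches, and the switch is declassified when the surplus
exceeds the benefit,

&nbsp;&nbsp;&nbsp;&nbsp;I − Ī > mean(RT_single) − RT_switch.

The **fast switch rate** (FSR) is the proportion of fast switches among
all correct switch trials, per participant × condition. Participants are
labelled **serial**, **semi-overlapper** or **overlapper** by comparing
their full-preview FSR with cutoffs at +1 and +3 SD of a reference FSR
distribution obtained without a usable preview. Group × condition FSR
inference uses a heteroscedastic between-by-within ANOVA on 20% trimmed
means (Johansen-type statistics with winsorized covariances and an
adjusted-F reference distribution) with robust AKP / KMS effect sizes;
classical repeated-measures ANOVAs use Greenhouse–Geisser correction.

The package also ships a synthetic cohort generator (fixed-duration
blocks, endogenous trial counts, mode-dependent preview use with known
ground truth) so the whole pipeline is testable and its recovery
properties measurable without any data download.

## Worked example

The numbered scripts under `analysis/` run the full study flow. After
`python analysis/01_simulate_cohorts.py` (writes trial logs under
`scratch/data/`), `python analysis/03_analyze_exp2.py` analyzes the
preview-position cohort and prints:

```
classification counts: {'overlapper': 26, 'serial': 16, 'semi_overlapper': 6}
trimmed-mean FSR (%) by assigned mode x condition:
          label condition  n  fsr_mt_pct
     overlapper     early 26    2.831681
     overlapper      full 26   31.237431
     overlapper      late 26   31.189622
     overlapper    middle 26    2.135555
...
cohort-mean FSR: early=0.024 middle=0.019 late=0.184
position-selectivity gap (late - max(early, middle)): 0.160
robust ANOVA on FSRs:
           effect  statistic  df1      df2        p epsilon  effect_size effect_size_kind
            label  68.056728    2 8.725592 0.000005    None     3.887999              KMS
        condition  37.464825    3 9.343241 0.000016    None     0.663113              AKP
label x condition  15.445878    6 8.138106 0.000480    None     2.409003              AKP
```

Reading this: participants classified as overlappers show high FSRs only
when the preview is available on the trial immediately before the switch
(late ≈ 31%, early/middle ≈ 2–3%) — preview use peaks just before the
task switch — while serial processors stay near zero everywhere. The
robust ANOVA confirms the mode, position and mode × position effects at
estimated denominator degrees of freedom.

The same pipeline is available as a CLI for external trial logs
(`tswp simulate` / `tswp analyze` / `tswp report`); foreign column names
and condition labels are absorbed by a YAML mapping config, and the
classification cutoffs are always supplied explicitly (a `c1`/`c3` pair or
a reference FSR sample) — they are never invented by the package.

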