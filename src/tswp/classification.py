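"""Processing-mode classification from full-preview fast switch rates.

Participants are labelled *serial*, *semi-overlapper* or *overlapper* by
comparing their full-preview FSR against two cutoffs anchored to a
reference distribution of FSRs obtained without a usable preview: the mean
plus one standard deviation (c1) and plus three standard deviations (c3) of
that reference sample. The numeric cutoffs are never hard-coded — callers
supply either an explicit (c1, c3) pair or a reference FSR sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ModeCutoffs", "ModeLabel", "LABELS", "derive_cutoffs", "classify_mode", "classify_cohort"]

log = logging.getLogger(__name__)

LABELS = ("serial", "semi_overlapper", "overlapper")
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ModeCutoffs:
    c1: float
    c3: float
    reference_mean: float | None = None
    reference_sd: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.c1 < self.c3):
            raise ValueError(f"require 0 <= c1 < c3, got c1={self.c1}, c3={self.c3}")


@dataclass(frozen=True)
class ModeLabel:
    participant_id: str
    label: str
    basis_fsr: float | None


def derive_cutoffs(reference_fsrs, provenance: str = "reference sample") -> ModeCutoffs:
    """Cutoffs at mean + 1 SD and mean + 3 SD of a reference FSR sample.

    Uses the sample SD (n-1). A zero-variance reference cannot anchor the
    boundaries and is rejected.
    """
    x = np.asarray(list(reference_fsrs), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 reference FSRs to derive cutoffs")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("zero-variance reference sample")
    return ModeCutoffs(
        c1=m + s, c3=m + 3 * s, reference_mean=m, reference_sd=s, provenance=provenance
    )


def classify_mode(basis_fsr: float | None, cutoffs: ModeCutoffs, participant_id: str = "") -> ModeLabel:
    """Label one participant from their full-preview FSR.

    Boundary convention: serial below c1, semi-overlapper in [c1, c3),
    overlapper at or above c3. A null FSR (no correct switches) yields the
    label "unclassifiable", to be excluded downstream with a logged reason.
    """
    if basis_fsr is None or not np.isfinite(basis_fsr):
        log.info("%s: unclassifiable (no FSR)", participant_id)
        return ModeLabel(participant_id, UNCLASSIFIABLE, None)
    if not 0 <= basis_fsr <= 1:
        raise ValueError(f"basis_fsr must be a proportion in [0, 1], got {basis_fsr}")
    if basis_fsr < cutoffs.c1:
        label = "serial"
    elif basis_fsr < cutoffs.c3:
        label = "semi_overlapper"
    else:
        label = "overlapper"
    return ModeLabel(participant_id, label, basis_fsr)


def classify_cohort(fsr_table: pd.DataFrame, cutoffs: ModeCutoffs, basis_condition: str = "full") -> pd.DataFrame:
    """Classify every participant on their FSR in the basis condition.

    ``fsr_table`` needs columns participant_id, condition, fsr (proportion).
    Returns one row per participant: participant_id, basis_fsr, label.
    """
    basis = fsr_table[fsr_table["condition"] == basis_condition]
    rows = []
    for r in basis.itertuples():
        ml = classify_mode(r.fsr, cutoffs, participant_id=r.participant_id)
        rows.append(dict(participant_id=r.participant_id, basis_fsr=ml.basis_fsr, label=ml.label))
    return pd.DataFrame(rows)
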