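"""Histology scoring, disease-activity classification and qPCR expression.

The EoE Histology Scoring System (EoEHSS) scores eight esophageal-biopsy
features — eosinophil inflammation (EI), basal zone hyperplasia (BZH),
eosinophil abscess (EA), surface layering (SL), dilated intercellular spaces
(DIS), surface epithelial alteration (SEA), dyskeratotic epithelial cells
(DEC) and lamina propria fibrosis (LPF) — each 0-3 for grade (severity) and
0-3 for stage (extent), so a feature total spans 0-6.  Features are grouped
into an eosinophilic group (EI, EA, SL, SEA) and a structural/architectural
group (BZH, DIS, DEC, LPF), each summarized as the achieved fraction of the
maximum possible score for the features actually evaluated on that biopsy.

Expression is quantified as ΔCT = CT(gene of interest) − CT(GAPDH), accepted
only when the GAPDH CT is below 30 cycles; lower ΔCT means higher expression,
and group fold changes use the 2^−ΔΔCT transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "HSS_FEATURES",
    "EOSINOPHILIC_FEATURES",
    "STRUCTURAL_FEATURES",
    "HSSRecord",
    "hss_feature_total",
    "hss_group_ratio",
    "eos_grade",
    "classify_activity",
    "delta_ct",
    "fold_change",
]

HSS_FEATURES = ("EI", "BZH", "EA", "SL", "DIS", "SEA", "DEC", "LPF")
EOSINOPHILIC_FEATURES = ("EI", "EA", "SL", "SEA")
STRUCTURAL_FEATURES = ("BZH", "DIS", "DEC", "LPF")

_MAX_FEATURE_TOTAL = 6


def hss_feature_total(grade: int, stage: int) -> int:
    """Feature total = grade + stage, each on the 0-3 scale (total 0-6)."""
    for v in (grade, stage):
        if not (isinstance(v, int) and 0 <= v <= 3):
            raise ValueError(f"grade/stage must be integers in 0..3, got {v!r}")
    return grade + stage


@dataclass(frozen=True)
class HSSRecord:
    """Per-biopsy feature totals (``None`` = feature not evaluable, e.g. LPF
    when no lamina propria is present in the biopsy) plus the peak eosinophil
    count per high-power field."""

    subject_id: str
    feature_totals: Mapping[str, int | None]
    peak_eos: int = 0

    def __post_init__(self) -> None:
        if self.peak_eos < 0:
            raise ValueError("peak_eos must be >= 0")
        for f, t in self.feature_totals.items():
            if f not in HSS_FEATURES:
                raise ValueError(f"unknown EoEHSS feature {f!r}")
            if t is not None and not 0 <= t <= _MAX_FEATURE_TOTAL:
                raise ValueError(f"feature total {t!r} outside 0..6")


def hss_group_ratio(record: HSSRecord, group: str) -> float:
    """Group score: sum of evaluated feature totals over the maximum possible
    for that biopsy (6 per evaluated feature), in [0, 1].  Unevaluated features
    leave both the numerator and the denominator."""
    try:
        features = {
            "eosinophilic": EOSINOPHILIC_FEATURES,
            "structural": STRUCTURAL_FEATURES,
        }[group]
    except KeyError:
        raise ValueError(f"group must be 'eosinophilic' or 'structural', got {group!r}")
    totals = [
        record.feature_totals[f]
        for f in features
        if record.feature_totals.get(f) is not None
    ]
    if not totals:
        raise ValueError(f"no evaluated features in group {group!r}")
    return sum(totals) / (_MAX_FEATURE_TOTAL * len(totals))


#: Default peak-eosinophil bin edges mapping counts/hpf to the EI grade 0-3.
#: The edges follow the published EoEHSS convention and are configurable.
DEFAULT_EOS_GRADE_BINS = (15, 30, 60)


def eos_grade(peak_eos: int, bins: Sequence[int] = DEFAULT_EOS_GRADE_BINS) -> int:
    """Map a peak eosinophil count to the 0-3 EI grade via bin edges."""
    if peak_eos < 0:
        raise ValueError("peak_eos must be >= 0")
    grade = 0
    for edge in bins:
        if peak_eos >= edge:
            grade += 1
    return grade


def classify_activity(peak_eos: int, has_eoe_history: bool) -> str:
    """Disease-activity class from the peak eosinophil count.

    ``active``: >= 15 eos/hpf.  ``inactive``: < 15 with a prior EoE history.
    ``control``: <= 2 without history.  3-14 eos without history fits none of
    those definitions and is labelled ``indeterminate`` rather than silently
    forced into a class.
    """
    if peak_eos < 0:
        raise ValueError("peak_eos must be >= 0")
    if peak_eos >= 15:
        return "active"
    if has_eoe_history:
        return "inactive"
    if peak_eos <= 2:
        return "control"
    return "indeterminate"


GAPDH_MAX_CT = 30.0


def delta_ct(ct_goi: float, ct_gapdh: float, gapdh_max_ct: float = GAPDH_MAX_CT) -> float | None:
    """ΔCT = CT(GOI) − CT(GAPDH), or ``None`` when the sample fails the
    housekeeping QC gate (GAPDH CT must be strictly below ``gapdh_max_ct``)."""
    if not (math.isfinite(ct_goi) and math.isfinite(ct_gapdh)):
        raise ValueError("CT values must be finite")
    if ct_gapdh >= gapdh_max_ct:
        return None
    return ct_goi - ct_gapdh


def fold_change(group_a_delta_cts: Sequence[float], group_b_delta_cts: Sequence[float]) -> float:
    """Expression of group A relative to group B: 2^(mean ΔCT_B − mean ΔCT_A).

    A fold change above 1 means group A expresses the gene more highly (its
    mean ΔCT is smaller).
    """
    if not group_a_delta_cts or not group_b_delta_cts:
        raise ValueError("both groups must be non-empty")
    mean_a = sum(group_a_delta_cts) / len(group_a_delta_cts)
    mean_b = sum(group_b_delta_cts) / len(group_b_delta_cts)
    return 2.0 ** (mean_b - mean_a)
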