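"""Total tumour volume, its percentage change, and the RECIP 1.0 rule engine.

RECIP 1.0 (Response Evaluation Criteria in PSMA PET/CT) classifies each
patient from two quantities measured between a baseline and a follow-up
scan: the percentage change in whole-body total tumour volume (dTTV) and
the appearance of new lesions.

* **CR** — no lesions identified on the follow-up scan (baseline had some);
* **PD** — tumour-burden increase past +20% together with >= 1 new lesion;
* **PR** — tumour-burden decline past -30% with no new lesions;
* **SD** — everything else (increase without new lesions, new lesions
  without sufficient increase, or change within (-30%, +20%)).

Published statements of the rule table disagree on
whether the +20% and -30% boundaries are strict; the counts reported with
the criteria correspond to inclusive boundaries (dTTV >= +20% toward PD,
dTTV <= -30% toward PR), which is the default here. Both behaviours are
available through :class:`RecipPolicy`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .delineation import Delineation
from .imaging import voxel_volume_ml

__all__ = [
    "RecipClass",
    "RecipPolicy",
    "TTVPair",
    "DeltaTTV",
    "RECIPResult",
    "total_tumour_volume",
    "delta_ttv",
    "classify_recip",
    "binarize_pd",
]


class RecipClass(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


@dataclass(frozen=True)
class RecipPolicy:
    """Boundary-inclusivity switches for the classification thresholds.

    ``pd_inclusive``: PD requires dTTV >= +20% (True, default) or > +20%.
    ``pr_inclusive``: PR requires dTTV <= -30% (True, default) or < -30%.
    """

    pd_threshold_pct: float = 20.0
    pr_threshold_pct: float = -30.0
    pd_inclusive: bool = True
    pr_inclusive: bool = True


@dataclass(frozen=True)
class TTVPair:
    """Baseline and follow-up whole-body total tumour volume (mL)."""

    baseline_ttv: float
    followup_ttv: float

    def __post_init__(self) -> None:
        if self.baseline_ttv < 0 or self.followup_ttv < 0:
            raise ValueError("tumour volumes must be non-negative")


@dataclass(frozen=True)
class DeltaTTV:
    """Signed percentage change in TTV.

    When the baseline volume is zero and the follow-up volume positive,
    the percentage is undefined (``undefined_flag`` set, ``percent`` is
    +inf); downstream dichotomisations treat this as exceeding any
    positive cutoff.
    """

    percent: float
    undefined_flag: bool = False


@dataclass(frozen=True)
class RECIPResult:
    patient_id: str
    ttv: TTVPair
    delta: DeltaTTV
    new_lesions: int
    recip_class: RecipClass

    @property
    def pd_flag(self) -> bool:
        return self.recip_class is RecipClass.PD


def total_tumour_volume(d: Delineation) -> float:
    """TTV in mL: total delineated voxel count times the voxel volume."""
    return d.total_voxels * voxel_volume_ml(d.grid)


def delta_ttv(pair: TTVPair) -> DeltaTTV:
    """Percentage change 100*(follow-up - baseline)/baseline.

    Zero baseline with zero follow-up is 0%; zero baseline with positive
    follow-up is undefined (flagged, percent +inf).
    """
    if pair.baseline_ttv == 0:
        if pair.followup_ttv == 0:
            return DeltaTTV(0.0)
        return DeltaTTV(math.inf, undefined_flag=True)
    pct = 100.0 * (pair.followup_ttv - pair.baseline_ttv) / pair.baseline_ttv
    return DeltaTTV(pct)


def classify_recip(
    delta: DeltaTTV,
    new_lesions: int,
    pair: TTVPair,
    policy: RecipPolicy = RecipPolicy(),
) -> RecipClass:
    """Apply the four-class RECIP 1.0 rule; total over consistent inputs."""
    if new_lesions < 0:
        raise ValueError("new-lesion count must be non-negative")
    if pair.followup_ttv == 0 and new_lesions > 0:
        raise ValueError("inconsistent input: new lesions with zero follow-up TTV")
    if delta.undefined_flag and new_lesions == 0:
        raise ValueError(
            "inconsistent input: positive follow-up TTV from zero baseline implies new lesions"
        )

    if pair.followup_ttv == 0 and pair.baseline_ttv > 0:
        return RecipClass.CR

    pct = delta.percent
    pd_increase = (
        delta.undefined_flag
        or (pct >= policy.pd_threshold_pct if policy.pd_inclusive else pct > policy.pd_threshold_pct)
    )
    pr_decline = (
        pct <= policy.pr_threshold_pct if policy.pr_inclusive else pct < policy.pr_threshold_pct
    )
    if pd_increase and new_lesions >= 1:
        return RecipClass.PD
    if pr_decline and new_lesions == 0:
        return RecipClass.PR
    return RecipClass.SD


def binarize_pd(result: RECIPResult) -> bool:
    """Dichotomise to progressive (True) vs non-progressive disease."""
    return result.recip_class is RecipClass.PD
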