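"""Baseline/follow-up lesion matching and new-lesion counting.

Clinically, "new lesion" means a focal uptake site on the follow-up scan
with no spatial counterpart at baseline. Readers decide this by eye; this
module encodes an explicit, deterministic rule so that the decision is
reproducible:

* A baseline lesion and a follow-up lesion are *candidates* for a match
  when the follow-up lesion overlaps the baseline lesion after dilating
  the baseline lesion by a small margin (default 1 voxel), or when their
  centroids lie within ``max_centroid_mm`` (default 10 mm).
* Candidates are assigned greedily in descending voxel overlap, ties
  broken by smaller centroid distance, then by smaller label pair.

The dilation absorbs small growth/shrinkage and sub-voxel repositioning;
the centroid gate rescues lesions that moved slightly more than one voxel
without overlap (e.g. different breath-hold). Anatomically distinct sites
— tens of millimetres away — are never matched and therefore count as new.

Timepoints are assumed rigidly co-registered in a common world frame; no
deformable registration is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .delineation import Delineation
from .imaging import GeometryError

__all__ = ["StudyPair", "MatchResult", "match_lesions", "count_new_lesions"]


@dataclass(frozen=True)
class StudyPair:
    """One patient's baseline and follow-up delineations."""

    patient_id: str
    baseline: Delineation
    followup: Delineation
    interval_months: float = 6.0

    def __post_init__(self) -> None:
        if self.interval_months <= 0:
            raise ValueError("scan interval must be positive")


@dataclass(frozen=True)
class MatchResult:
    """Lesion correspondence between the two timepoints."""

    matched: tuple[tuple[int, int], ...]  # (baseline label, follow-up label)
    disappeared: tuple[int, ...]          # baseline labels without a partner
    new: tuple[int, ...]                  # follow-up labels without a partner

    def to_dict(self) -> dict:
        return {
            "matched": [list(p) for p in self.matched],
            "disappeared": list(self.disappeared),
            "new": list(self.new),
        }


def _dilate(mask: np.ndarray, voxels: int) -> np.ndarray:
    if voxels <= 0:
        return mask
    structure = ndimage.generate_binary_structure(3, 3)
    return ndimage.binary_dilation(mask, structure=structure, iterations=voxels)


def match_lesions(
    pair: StudyPair,
    max_centroid_mm: float = 10.0,
    dilation_voxels: int = 1,
) -> MatchResult:
    """Match lesions across timepoints; see the module docstring for the rule."""
    base, foll = pair.baseline, pair.followup
    if not base.grid.same_grid(foll.grid):
        raise GeometryError(
            "baseline and follow-up delineations must share a co-registered grid"
        )

    b_labels = base.labelmap.values
    f_labels = foll.labelmap.values
    candidates = []  # (-overlap, centroid_dist, b, f)
    for bl in base.lesions:
        b_mask = _dilate(b_labels == bl.label, dilation_voxels)
        overlaps = np.bincount(
            f_labels[b_mask].ravel(), minlength=foll.n_lesions + 1
        )
        for fl in foll.lesions:
            overlap = int(overlaps[fl.label])
            dist = float(
                np.linalg.norm(np.subtract(bl.centroid_mm, fl.centroid_mm))
            )
            if overlap > 0 or dist <= max_centroid_mm:
                candidates.append((-overlap, dist, bl.label, fl.label))

    candidates.sort()
    used_b: set[int] = set()
    used_f: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _neg_overlap, _dist, b, f in candidates:
        if b in used_b or f in used_f:
            continue
        matched.append((b, f))
        used_b.add(b)
        used_f.add(f)

    disappeared = tuple(l.label for l in base.lesions if l.label not in used_b)
    new = tuple(l.label for l in foll.lesions if l.label not in used_f)
    return MatchResult(tuple(matched), disappeared, new)


def count_new_lesions(result: MatchResult) -> int:
    """Number of follow-up lesions with no baseline counterpart."""
    return len(result.new)
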