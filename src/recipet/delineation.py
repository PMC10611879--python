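"""SUV-threshold lesion delineation with emulated manual editing.

The semi-automated reading procedure this module reproduces is: apply a
fixed SUV_bw threshold (clinically, 3.0) to the whole-body PET volume,
split the thresholded foreground into connected components, remove
components that correspond to physiologic tracer uptake (kidneys,
bladder, salivary glands), and insert lesions whose uptake never reaches
the threshold. The removals and insertions are expressed as an
:class:`EditScript`, the package's stand-in for the reader's manual
contouring work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, GeometryError, PetVolume, voxel_volume_ml

__all__ = [
    "LabelMap",
    "Lesion",
    "EditScript",
    "Delineation",
    "DelineationSource",
    "EditConflictError",
    "threshold_segment",
    "connected_components",
    "apply_edits",
    "lesion_stats",
    "delineate",
]

DEFAULT_SUV_THRESHOLD = 3.0


class EditConflictError(ValueError):
    """An added lesion overlaps a region flagged as physiologic."""


class DelineationSource(str, Enum):
    MANUAL_EMULATED = "manual_emulated"
    TRUTH = "truth"
    DEGRADED_OBSERVER = "degraded_observer"


@dataclass(frozen=True)
class LabelMap:
    """Integer lesion labels (0 = background, 1..K) on a PET grid."""

    values: np.ndarray
    grid: PetVolume

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.issubdtype(values.dtype, np.integer):
            values = np.rint(values).astype(np.int32)
        if values.shape != self.grid.shape:
            raise GeometryError(
                f"label map shape {values.shape} does not match grid {self.grid.shape}"
            )
        labels = np.unique(values)
        labels = labels[labels != 0]
        if labels.size and (labels.min() < 1 or not np.array_equal(labels, np.arange(1, labels.size + 1))):
            raise ValueError("labels must be consecutive integers 1..K")
        object.__setattr__(self, "values", values.astype(np.int32))

    @property
    def n_labels(self) -> int:
        return int(self.values.max(initial=0))


@dataclass(frozen=True)
class Lesion:
    """Per-lesion summary statistics on the PET grid."""

    label: int
    voxel_count: int
    volume_ml: float
    suv_max: float
    suv_mean: float
    centroid_mm: tuple[float, float, float]


@dataclass
class EditScript:
    """Manual adjustments: physiologic exclusions and inserted lesions."""

    exclusions: list[BinaryMask] = field(default_factory=list)
    additions: list[BinaryMask] = field(default_factory=list)

    def save(self, path, grid: PetVolume, mask_dir=None) -> None:
        """Serialise to JSON as a list of mask files with roles.

        Masks are written as NIfTI next to ``path`` (or in ``mask_dir``)
        and referenced by relative path with role "exclude" or "add".
        """
        import json
        from pathlib import Path

        from .imaging import write_mask

        path = Path(path)
        mask_dir = Path(mask_dir) if mask_dir is not None else path.parent
        mask_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for role, masks in (("exclude", self.exclusions), ("add", self.additions)):
            for i, mask in enumerate(masks):
                name = f"{path.stem}_{role}_{i}.nii.gz"
                write_mask(mask, mask_dir / name)
                entries.append({"role": role, "path": str((mask_dir / name).relative_to(path.parent))})
        path.write_text(json.dumps(entries, indent=2))

    @classmethod
    def load(cls, path, grid: PetVolume) -> "EditScript":
        """Read an edit script written by :meth:`save`, binding all masks
        to ``grid``."""
        import json
        from pathlib import Path

        from .imaging import read_mask

        path = Path(path)
        script = cls()
        for entry in json.loads(path.read_text()):
            mask = read_mask(path.parent / entry["path"], grid)
            if entry["role"] == "exclude":
                script.exclusions.append(mask)
            elif entry["role"] == "add":
                script.additions.append(mask)
            else:
                raise ValueError(f"{path}: unknown edit role {entry['role']!r}")
        return script


@dataclass(frozen=True)
class Delineation:
    """A finished scan delineation: label map plus per-lesion statistics."""

    labelmap: LabelMap
    lesions: tuple[Lesion, ...]
    source: DelineationSource = DelineationSource.MANUAL_EMULATED

    @property
    def grid(self) -> PetVolume:
        return self.labelmap.grid

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def total_voxels(self) -> int:
        return int(sum(l.voxel_count for l in self.lesions))


def threshold_segment(volume: PetVolume, threshold: float = DEFAULT_SUV_THRESHOLD) -> BinaryMask:
    """Mask of voxels with SUV_bw >= ``threshold`` (inclusive comparison)."""
    if threshold <= 0:
        raise ValueError("SUV threshold must be positive")
    return BinaryMask(volume.values >= threshold, volume)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _relabel_deterministic(labels: np.ndarray, n: int) -> np.ndarray:
    """Relabel 1..K by descending voxel count; ties broken by the smallest
    flat (C-order) voxel index, i.e. the lexicographically smallest voxel."""
    if n == 0:
        return labels.astype(np.int32)
    flat = labels.ravel(order="C")
    counts = np.bincount(flat, minlength=n + 1)
    present, first = np.unique(flat, return_index=True)
    first_index = {int(lab): int(idx) for lab, idx in zip(present, first)}
    order = sorted(
        (lab for lab in range(1, n + 1) if counts[lab] > 0),
        key=lambda lab: (-counts[lab], first_index[lab]),
    )
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels]


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabelMap:
    """Label maximal connected foreground regions.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full 3D
    neighbourhood). Label order is deterministic: descending voxel count,
    ties by the lexicographically smallest member voxel index.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    raw, n = ndimage.label(mask.values, structure=_STRUCTURES[connectivity])
    return LabelMap(_relabel_deterministic(raw, n), mask.grid)


def apply_edits(
    labelmap: LabelMap,
    edits: EditScript,
    exclusion_fraction: float = 0.5,
    connectivity: int = 26,
) -> LabelMap:
    """Apply an edit script to a thresholded label map.

    A component is removed when at least ``exclusion_fraction`` of its
    voxels fall inside the union of exclusion regions. Each addition is
    inserted as a lesion of its own, merging with any surviving component
    it overlaps. Labels are recompacted deterministically.
    """
    grid = labelmap.grid
    for region in list(edits.exclusions) + list(edits.additions):
        if not region.grid.same_grid(grid):
            raise GeometryError("edit region is not on the delineation grid")

    values = labelmap.values
    n = labelmap.n_labels
    keep = np.ones(n + 1, dtype=bool)
    if edits.exclusions and n:
        excl_union = np.zeros(grid.shape, dtype=bool)
        for region in edits.exclusions:
            excl_union |= region.values
        counts = np.bincount(values.ravel(), minlength=n + 1)
        inside = np.bincount(values[excl_union].ravel(), minlength=n + 1)
        with np.errstate(invalid="ignore"):
            frac = np.where(counts > 0, inside / np.maximum(counts, 1), 0.0)
        keep[1:] = frac[1:] < exclusion_fraction
    surviving = np.where(keep[values], values, 0) > 0

    if edits.additions:
        if edits.exclusions:
            excl_union = np.zeros(grid.shape, dtype=bool)
            for region in edits.exclusions:
                excl_union |= region.values
            for addition in edits.additions:
                if np.any(addition.values & excl_union):
                    raise EditConflictError(
                        "an added lesion overlaps a physiologic exclusion region"
                    )
        combined = surviving.copy()
        for addition in edits.additions:
            combined |= addition.values
        surviving = combined

    # Relabelling the surviving foreground also realises the merge rule:
    # an addition touching an existing component becomes one component.
    return connected_components(BinaryMask(surviving, grid), connectivity=connectivity)


def lesion_stats(labelmap: LabelMap, volume: PetVolume) -> tuple[Lesion, ...]:
    """Summarise each labelled lesion against the SUV volume.

    Volume is voxel count times the voxel volume; the centroid is the
    unweighted mean of member-voxel world coordinates (mm).
    """
    if not labelmap.grid.same_grid(volume):
        raise GeometryError("label map and SUV volume are on different grids")
    n = labelmap.n_labels
    if n == 0:
        return ()
    vv = voxel_volume_ml(volume)
    labels = labelmap.values
    index = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    suv_max = ndimage.labeled_comprehension(volume.values, labels, index, np.max, float, 0.0)
    suv_mean = ndimage.labeled_comprehension(volume.values, labels, index, np.mean, float, 0.0)
    centroids_idx = ndimage.center_of_mass(np.ones(labels.shape), labels, index)
    out = []
    for k, (count, smax, smean, cidx) in enumerate(
        zip(counts, suv_max, suv_mean, centroids_idx), start=1
    ):
        world = volume.index_to_world(np.asarray(cidx))
        out.append(
            Lesion(
                label=k,
                voxel_count=int(count),
                volume_ml=float(count) * vv,
                suv_max=float(smax),
                suv_mean=float(smean),
                centroid_mm=tuple(float(w) for w in world),
            )
        )
    return tuple(out)


def delineate(
    volume: PetVolume,
    threshold: float = DEFAULT_SUV_THRESHOLD,
    edits: EditScript | None = None,
    connectivity: int = 26,
    min_voxels: int = 0,
    source: DelineationSource = DelineationSource.MANUAL_EMULATED,
) -> Delineation:
    """Full delineation: threshold, components, edits, statistics.

    ``min_voxels`` optionally drops components smaller than the floor
    (off by default; no minimum-size criterion is part of the clinical
    procedure being emulated).
    """
    mask = threshold_segment(volume, threshold)
    labelmap = connected_components(mask, connectivity=connectivity)
    if edits is not None:
        labelmap = apply_edits(labelmap, edits, connectivity=connectivity)
    if min_voxels > 1 and labelmap.n_labels:
        counts = np.bincount(labelmap.values.ravel(), minlength=labelmap.n_labels + 1)
        small = counts < min_voxels
        small[0] = False
        if small.any():
            fg = labelmap.values > 0
            fg &= ~small[labelmap.values]
            labelmap = connected_components(BinaryMask(fg, volume), connectivity=connectivity)
    return Delineation(labelmap, lesion_stats(labelmap, volume), source=source)
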