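"""Synthetic phantom cohort: paired PET volumes, imperfect observers, survival.

The clinical data this package is designed for (paired whole-body PSMA
PET scans with expert delineations and overall-survival follow-up) are
not publicly distributable, so this module generates a stand-in cohort
with the same statistical anatomy:

* paired baseline/follow-up volumes on a PET-like grid (default
  96 x 96 x 128 voxels at 4.07 x 4.07 x 3.0 mm) with Gaussian background
  noise, high-uptake physiologic "organ" blobs (bladder, kidneys), and
  focal lesions rendered as smooth isotropic peaks;
* lesion evolution between timepoints (growth, shrinkage, disappearance,
  newly appearing lesions), including sub-threshold lesions whose peak
  uptake never reaches the SUV-3 delineation threshold and which can
  therefore only enter a delineation through manual insertion;
* an observer model that degrades the reference delineation — missing
  sub-threshold lesions with some probability, jittering boundaries,
  adding small false-positive foci — emulating the failure mode in which
  an automated reader misses a faint new lesion and flips a progression
  call;
* overall-survival times from an exponential proportional-hazards model
  keyed to the intended progression status, with uniform-entry
  administrative censoring producing the heavy censoring typical of a
  biochemical-recurrence population.

Lesion profiles are clipped Gaussians calibrated so that the SUV-3
isocontour sits exactly at the specified lesion radius; composition with
the background uses a voxelwise maximum, so the thresholded voxel set of
a supra-threshold lesion equals its geometric sphere on the grid. That
makes phantom tumour volumes constructible to a target mL by direct
voxel counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Literal, Sequence

import numpy as np

from .delineation import (
    BinaryMask,
    Delineation,
    DelineationSource,
    EditScript,
    LabelMap,
    connected_components,
    lesion_stats,
)
from .imaging import PetVolume
from .recip import RecipClass
from .survival import SurvivalRecord

__all__ = [
    "LesionSpec",
    "OrganSpec",
    "PhantomSpec",
    "ObserverModel",
    "CohortSpec",
    "SyntheticPatient",
    "PhantomSpecError",
    "generate_phantom",
    "evolve_phantom",
    "truth_delineation",
    "observe",
    "simulate_survival",
    "simulate_cohort",
    "generate_cohort",
    "radius_for_volume",
    "snap_to_voxel_center",
]

SUV_THRESHOLD = 3.0
DEFAULT_SPACING = (4.07, 4.07, 3.0)
DEFAULT_SHAPE = (96, 96, 128)


class PhantomSpecError(ValueError):
    """A phantom specification is geometrically or physically inconsistent."""


@dataclass(frozen=True)
class LesionSpec:
    """One focal lesion: the SUV-3 isocontour sphere and its evolution.

    ``radius_mm`` is the radius at which the rendered profile crosses
    SUV 3 (for ``peak_suv`` > 3) or the half-maximum radius (for
    sub-threshold peaks). ``growth_factor`` scales the lesion *volume*
    between baseline and follow-up; 0 removes the lesion at follow-up.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float
    growth_factor: float = 1.0
    appears_at: Literal["baseline", "followup"] = "baseline"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.peak_suv <= 0:
            raise PhantomSpecError("lesion radius and peak SUV must be positive")
        if self.growth_factor < 0:
            raise PhantomSpecError("growth factor must be non-negative")


@dataclass(frozen=True)
class OrganSpec:
    """A physiologic-uptake distractor (bladder, kidney, gland)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    background_mean: float = 0.4
    background_sd: float = 0.12
    organs: tuple[OrganSpec, ...] = ()
    lesions: tuple[LesionSpec, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class ObserverModel:
    """Imperfect reader: step miss probability, jitter, false positives.

    ``p_miss_subthreshold`` applies to lesions whose peak SUV is below
    the delineation threshold (supra-threshold lesions are never missed);
    ``boundary_jitter`` dilates or erodes each kept lesion by up to that
    many voxels; ``false_positive_rate`` is the expected number of small
    spurious foci added per scan.
    """

    p_miss_subthreshold: float = 0.0
    boundary_jitter: int = 0
    false_positive_rate: float = 0.0

    def miss_probability(self, peak_suv: float) -> float:
        return 0.0 if peak_suv >= SUV_THRESHOLD else self.p_miss_subthreshold

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_miss_subthreshold <= 1.0:
            raise ValueError("miss probability must be in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false-positive rate must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generator settings.

    Defaults emulate a biochemical-recurrence population: 199 patients
    scanned twice ~6 months apart, ~13.1% progressing by RECIP, a true
    hazard ratio of 3.78 for progressors, and administrative censoring
    at a 75.4-month horizon giving a median follow-up near 67 months.
    ``nonpd_median_os_months`` is set so the progressor group's marginal
    median overall survival lands near 62.5 months (236.3 / 3.78).
    """

    n_patients: int = 199
    pd_fraction: float = 0.131
    hr_pd: float = 3.78
    nonpd_median_os_months: float = 236.3
    censor_min_months: float = 58.0
    censor_max_months: float = 75.4
    interval_months: float = 6.0
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    pr_fraction: float = 0.15
    cr_fraction: float = 0.05
    subthreshold_fraction: float = 0.35
    degraded_observer: ObserverModel = ObserverModel(
        p_miss_subthreshold=0.85, boundary_jitter=0, false_positive_rate=0.15
    )

    def __post_init__(self) -> None:
        if not 0 < self.pd_fraction < 1:
            raise ValueError("PD fraction must be in (0, 1)")
        if self.hr_pd <= 0 or self.n_patients < 2:
            raise ValueError("hazard ratio must be positive and n >= 2")

    def to_json(self) -> str:
        import dataclasses
        import json

        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        import json

        data = json.loads(text)
        data["degraded_observer"] = ObserverModel(**data["degraded_observer"])
        for key in ("shape", "spacing"):
            data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# phantom rendering


def _profile_sigma(radius_mm: float, peak_suv: float) -> float:
    """Gaussian sigma putting the SUV-3 isocontour (or half-maximum for
    sub-threshold peaks) at ``radius_mm``."""
    if peak_suv > SUV_THRESHOLD:
        return radius_mm / math.sqrt(2.0 * math.log(peak_suv / SUV_THRESHOLD))
    return radius_mm / math.sqrt(2.0 * math.log(2.0))


def _render_blob(
    values: np.ndarray,
    spacing: Sequence[float],
    center_mm: Sequence[float],
    radius_mm: float,
    peak_suv: float,
) -> None:
    """Composite a clipped Gaussian peak into ``values`` via voxel max."""
    sigma = _profile_sigma(radius_mm, peak_suv)
    support = max(radius_mm, 3.5 * sigma)
    lo = [max(0, int(math.floor((c - support) / s))) for c, s in zip(center_mm, spacing)]
    hi = [
        min(n, int(math.ceil((c + support) / s)) + 1)
        for c, s, n in zip(center_mm, spacing, values.shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    coords = [
        (np.arange(l, h) * s - c) for l, h, s, c in zip(lo, hi, spacing, center_mm)
    ]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    blob = peak_suv * np.exp(-d2 / (2.0 * sigma * sigma))
    blob[d2 > support * support] = 0.0
    region = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(region, blob, out=region)


def _sphere_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    center_mm: Sequence[float],
    radius_mm: float,
) -> np.ndarray:
    out = np.zeros(tuple(shape), dtype=bool)
    lo = [max(0, int(math.floor((c - radius_mm) / s))) for c, s in zip(center_mm, spacing)]
    hi = [
        min(n, int(math.ceil((c + radius_mm) / s)) + 1)
        for c, s, n in zip(center_mm, spacing, shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return out
    coords = [
        (np.arange(l, h) * s - c) for l, h, s, c in zip(lo, hi, spacing, center_mm)
    ]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= radius_mm * radius_mm
    return out


def _check_overlaps(spec: PhantomSpec, lesions: Sequence[LesionSpec]) -> None:
    centers = [l.center_mm for l in lesions] + [o.center_mm for o in spec.organs]
    radii = [l.radius_mm for l in lesions] + [o.radius_mm for o in spec.organs]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dist = math.dist(centers[i], centers[j])
            if dist < radii[i] + radii[j]:
                raise PhantomSpecError(
                    f"blobs {i} and {j} overlap (centres {dist:.1f} mm apart)"
                )


def _lesions_at(spec: PhantomSpec, timepoint: str) -> list[LesionSpec]:
    out: list[LesionSpec] = []
    for lesion in spec.lesions:
        if timepoint == "baseline":
            if lesion.appears_at == "baseline":
                out.append(lesion)
        else:
            if lesion.appears_at == "followup":
                out.append(lesion)
            elif lesion.growth_factor > 0:
                out.append(
                    replace(lesion, radius_mm=lesion.radius_mm * lesion.growth_factor ** (1 / 3))
                )
    return out


def _render(spec: PhantomSpec, lesions: Sequence[LesionSpec], rng: np.random.Generator):
    _check_overlaps(spec, lesions)
    values = rng.normal(spec.background_mean, spec.background_sd, size=spec.shape)
    np.clip(values, 0.0, None, out=values)
    for organ in spec.organs:
        _render_blob(values, spec.spacing, organ.center_mm, organ.radius_mm, organ.peak_suv)
    for lesion in lesions:
        _render_blob(values, spec.spacing, lesion.center_mm, lesion.radius_mm, lesion.peak_suv)
    volume = PetVolume(values, spec.spacing)
    truth = np.zeros(spec.shape, dtype=np.int32)
    for k, lesion in enumerate(lesions, start=1):
        truth[_sphere_mask(spec.shape, spec.spacing, lesion.center_mm, lesion.radius_mm)] = k
    return volume, LabelMap(truth, volume)


def generate_phantom(spec: PhantomSpec) -> tuple[PetVolume, LabelMap]:
    """Render the baseline volume and its full-truth lesion label map.

    The label map marks *all* lesion voxels (the geometric spheres), in
    spec order; sub-threshold lesions are present in the truth even
    though SUV thresholding cannot see them. Deterministic given the
    spec seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return _render(spec, _lesions_at(spec, "baseline"), rng)


def evolve_phantom(spec: PhantomSpec) -> tuple[PetVolume, LabelMap]:
    """Render the follow-up volume: lesion volumes scaled by their growth
    factors (radius scaled by the cube root), follow-up-only lesions
    added, factor-zero lesions removed. Background noise is redrawn
    (independent acquisition)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed ^ 0x5EED))
    return _render(spec, _lesions_at(spec, "followup"), rng)


def snap_to_voxel_center(
    center_mm: Sequence[float], spacing: Sequence[float]
) -> tuple[float, float, float]:
    """Snap a world coordinate to the nearest voxel center (origin 0)."""
    return tuple(round(c / s) * s for c, s in zip(center_mm, spacing))


def radius_for_volume(
    target_ml: float,
    spacing: Sequence[float] = DEFAULT_SPACING,
    center_mm: Sequence[float] | None = None,
    max_radius_mm: float = 40.0,
) -> float:
    """Sphere radius whose voxelised volume on the grid (voxel centers
    inside the sphere) is as close as possible to ``target_ml``.

    Computed by brute-force voxel counting: sort voxel-center distances
    from the sphere center, take the count matching the target volume,
    and place the radius between the last included and first excluded
    distance. ``center_mm`` is the intended lesion position; a center
    that is not voxel-aligned breaks distance-shell degeneracy, letting
    the count hit the target exactly. With no center given, a generic
    symmetry-breaking sub-voxel offset is used.
    """
    vv = math.prod(spacing) / 1000.0
    if center_mm is None:
        center_mm = [0.31 * s for s in spacing]
    axes = []
    for c, s in zip(center_mm, spacing):
        k_lo = int(math.floor((c - max_radius_mm) / s))
        k_hi = int(math.ceil((c + max_radius_mm) / s))
        axes.append(np.arange(k_lo, k_hi + 1) * s - c)
    d = np.sqrt(
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    ).ravel()
    d = np.sort(d[d <= max_radius_mm])
    k = int(round(target_ml / vv))
    if k < 1 or k >= d.size:
        raise ValueError("target volume out of range for the given max radius")
    # skip over any residual exactly-tied distances around the cut
    while k < d.size and d[k] == d[k - 1]:
        k += 1
    return float((d[k - 1] + d[k]) / 2.0)


# ---------------------------------------------------------------------------
# observers


def truth_delineation(volume: PetVolume, truth: LabelMap) -> Delineation:
    """Delineation straight from the generator's truth label map."""
    return Delineation(truth, lesion_stats(truth, volume), source=DelineationSource.TRUTH)


def observe(
    volume: PetVolume,
    truth: Delineation,
    model: ObserverModel,
    seed: int,
) -> Delineation:
    """Apply an imperfect observer to a reference delineation.

    Each lesion is dropped with the model's miss probability for its
    peak SUV; kept lesions are dilated or eroded by up to the boundary
    jitter; Poisson-many small false-positive foci are added away from
    existing lesions. Deterministic given the seed. A null model (all
    zero) reproduces the reference delineation exactly.
    """
    from scipy import ndimage

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = truth.labelmap.values
    kept = np.zeros(volume.shape, dtype=bool)
    structure = ndimage.generate_binary_structure(3, 3)
    for lesion in truth.lesions:
        if rng.random() < model.miss_probability(lesion.suv_max):
            continue
        mask = labels == lesion.label
        if model.boundary_jitter > 0:
            amount = int(rng.integers(0, model.boundary_jitter + 1))
            if amount:
                if rng.random() < 0.5:
                    mask = ndimage.binary_dilation(mask, structure, iterations=amount)
                else:
                    eroded = ndimage.binary_erosion(mask, structure, iterations=amount)
                    if eroded.any():
                        mask = eroded
        kept |= mask
    n_fp = int(rng.poisson(model.false_positive_rate))
    for _ in range(n_fp):
        for _attempt in range(20):
            center = [
                float(rng.uniform(0.15, 0.85) * (n - 1) * s)
                for n, s in zip(volume.shape, volume.spacing)
            ]
            radius = float(rng.uniform(4.0, 6.5))
            blob = _sphere_mask(volume.shape, volume.spacing, center, radius)
            if blob.any() and not (blob & (kept | (labels > 0))).any():
                kept |= blob
                break
    labelmap = connected_components(BinaryMask(kept, volume))
    return Delineation(
        labelmap, lesion_stats(labelmap, volume), source=DelineationSource.DEGRADED_OBSERVER
    )


# ---------------------------------------------------------------------------
# outcomes


def simulate_survival(
    pd_flags: Sequence[bool],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Exponential proportional-hazards overall survival.

    Hazard is lambda0 = ln 2 / (non-PD median OS) for non-progressors and
    lambda0 x HR for progressors; censoring times are uniform on the
    administrative window, so no observed time exceeds the horizon.
    """
    flags = np.asarray(pd_flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("degenerate cohort: need both PD and non-PD patients")
    lam0 = math.log(2.0) / spec.nonpd_median_os_months
    lam = np.where(flags, lam0 * spec.hr_pd, lam0)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(spec.censor_min_months, spec.censor_max_months, size=flags.size)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    time = np.maximum(time, 1e-6)
    return [
        SurvivalRecord(float(t), int(e), float(f))
        for t, e, f in zip(time, event, flags)
    ]


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SyntheticPatient:
    """Everything generated for one patient (volumes held in memory)."""

    patient_id: str
    phantom: PhantomSpec
    baseline_volume: PetVolume
    followup_volume: PetVolume
    baseline_truth: LabelMap
    followup_truth: LabelMap
    edits_baseline: EditScript
    edits_followup: EditScript
    intended_class: RecipClass
    survival: SurvivalRecord
    interval_months: float


def _default_organs(shape, spacing, rng: np.random.Generator) -> tuple[OrganSpec, ...]:
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    bladder = OrganSpec(
        center_mm=(0.50 * extent[0], 0.50 * extent[1], 0.22 * extent[2]),
        radius_mm=float(rng.uniform(18.0, 24.0)),
        peak_suv=float(rng.uniform(12.0, 25.0)),
    )
    kidney_z = 0.52 * extent[2]
    kidneys = [
        OrganSpec(
            center_mm=(fx * extent[0], 0.60 * extent[1], kidney_z),
            radius_mm=float(rng.uniform(14.0, 18.0)),
            peak_suv=float(rng.uniform(8.0, 16.0)),
        )
        for fx in (0.28, 0.72)
    ]
    return (bladder, *kidneys)


def _place_lesion(
    rng: np.random.Generator,
    shape,
    spacing,
    radius: float,
    existing: list[tuple[tuple[float, float, float], float]],
    margin: float = 6.0,
) -> tuple[float, float, float]:
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    for _ in range(200):
        center = snap_to_voxel_center(
            [float(rng.uniform(0.15, 0.85) * e) for e in extent], spacing
        )
        if all(
            math.dist(center, c) >= radius + r + margin for c, r in existing
        ):
            return center
    raise PhantomSpecError("could not place a lesion without overlap")


def _patient_phantom_spec(
    spec: CohortSpec, rng: np.random.Generator, seed: int
) -> tuple[PhantomSpec, RecipClass]:
    organs = _default_organs(spec.shape, spec.spacing, rng)
    # keep lesions clear of the enlarged physiologic exclusion spheres so
    # that manual edit scripts never conflict with inserted lesions
    occupied: list[tuple[tuple[float, float, float], float]] = [
        (o.center_mm, o.radius_mm * 1.6) for o in organs
    ]

    u = rng.random()
    if u < spec.pd_fraction:
        intended = RecipClass.PD
    else:
        v = rng.random()
        if v < spec.cr_fraction:
            intended = RecipClass.CR
        elif v < spec.cr_fraction + spec.pr_fraction:
            intended = RecipClass.PR
        else:
            intended = RecipClass.SD

    n_lesions = int(rng.integers(1, 4))
    lesions: list[LesionSpec] = []
    for _ in range(n_lesions):
        radius = float(rng.uniform(8.0, 14.0))
        # growth factor scales each lesion's volume between the scans
        if intended is RecipClass.PD:
            growth = float(rng.uniform(1.5, 3.0))
        elif intended is RecipClass.PR:
            growth = float(rng.uniform(0.35, 0.55))
        elif intended is RecipClass.CR:
            growth = 0.0
        else:
            growth = float(rng.uniform(0.80, 1.10))
        grown_radius = radius * max(growth, 1.0) ** (1 / 3)
        center = _place_lesion(rng, spec.shape, spec.spacing, grown_radius, occupied)
        occupied.append((center, grown_radius))
        lesions.append(
            LesionSpec(
                center_mm=center,
                radius_mm=radius,
                peak_suv=float(rng.uniform(4.0, 12.0)),
                growth_factor=growth,
            )
        )

    if intended is RecipClass.PD:
        # the progression-defining new lesion, sometimes sub-threshold
        # (only a human reader inserts it; a degraded observer may miss it)
        radius = float(rng.uniform(7.0, 11.0))
        center = _place_lesion(rng, spec.shape, spec.spacing, radius, occupied)
        occupied.append((center, radius))
        subthreshold = rng.random() < spec.subthreshold_fraction
        lesions.append(
            LesionSpec(
                center_mm=center,
                radius_mm=radius,
                peak_suv=float(rng.uniform(2.2, 2.9)) if subthreshold else float(rng.uniform(4.0, 9.0)),
                appears_at="followup",
            )
        )
    elif intended is RecipClass.SD and rng.random() < spec.subthreshold_fraction:
        # a faint lesion present at both timepoints, visible only to a
        # reader who contours below the threshold
        radius = float(rng.uniform(6.0, 9.0))
        center = _place_lesion(rng, spec.shape, spec.spacing, radius, occupied)
        occupied.append((center, radius))
        lesions.append(
            LesionSpec(
                center_mm=center,
                radius_mm=radius,
                peak_suv=float(rng.uniform(2.2, 2.9)),
                growth_factor=1.0,
            )
        )

    phantom = PhantomSpec(
        shape=spec.shape,
        spacing=spec.spacing,
        organs=organs,
        lesions=tuple(lesions),
        seed=seed,
    )
    return phantom, intended


def _edit_script(
    phantom: PhantomSpec, volume: PetVolume, truth: LabelMap, timepoint: str
) -> EditScript:
    """The emulated manual edits: exclude organ spheres, insert the truth
    masks of sub-threshold lesions (which thresholding cannot find)."""
    exclusions = [
        BinaryMask(
            _sphere_mask(volume.shape, volume.spacing, o.center_mm, o.radius_mm * 1.6),
            volume,
        )
        for o in phantom.organs
    ]
    additions = []
    for k, lesion in enumerate(_lesions_at(phantom, timepoint), start=1):
        if lesion.peak_suv < SUV_THRESHOLD:
            additions.append(BinaryMask(truth.values == k, volume))
    return EditScript(exclusions=exclusions, additions=additions)


def simulate_cohort(spec: CohortSpec, seed: int) -> Iterator[SyntheticPatient]:
    """Yield synthetic patients one at a time (volumes are large; stream).

    All randomness derives from ``seed`` via spawned child sequences, so
    a given (spec, seed) reproduces the cohort exactly, patient by
    patient, regardless of how many patients the consumer draws.
    """
    root = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(root.spawn(1)[0])
    phantoms: list[tuple[PhantomSpec, RecipClass]] = []
    for i in range(spec.n_patients):
        child_seed = int(np.random.SeedSequence((seed, 1000 + i)).generate_state(1)[0] % (2**31))
        phantoms.append(_patient_phantom_spec(spec, design_rng, child_seed))

    pd_flags = [intended is RecipClass.PD for _, intended in phantoms]
    if all(pd_flags) or not any(pd_flags):
        raise ValueError(
            "degenerate cohort draw (all or no progressors); choose a larger n or another seed"
        )
    survival_rng = np.random.default_rng(root.spawn(2)[1])
    records = simulate_survival(pd_flags, spec, survival_rng)

    for i, ((phantom, intended), record) in enumerate(zip(phantoms, records)):
        base_vol, base_truth = generate_phantom(phantom)
        foll_vol, foll_truth = evolve_phantom(phantom)
        yield SyntheticPatient(
            patient_id=f"P{i+1:03d}",
            phantom=phantom,
            baseline_volume=base_vol,
            followup_volume=foll_vol,
            baseline_truth=base_truth,
            followup_truth=foll_truth,
            edits_baseline=_edit_script(phantom, base_vol, base_truth, "baseline"),
            edits_followup=_edit_script(phantom, foll_vol, foll_truth, "followup"),
            intended_class=intended,
            survival=record,
            interval_months=spec.interval_months,
        )


def generate_cohort(spec: CohortSpec, out_dir, seed: int) -> "pd.DataFrame":
    """Write a cohort to disk as NIfTI volumes plus a manifest CSV.

    Per patient: baseline/follow-up SUV volumes, truth label maps, and
    organ-exclusion masks; the manifest links files to survival records.
    Returns the manifest frame (also written to ``out_dir/manifest.csv``).
    """
    import pandas as pd
    from pathlib import Path

    from .imaging import write_labelmap_nifti, write_mask, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in simulate_cohort(spec, seed):
        pid = patient.patient_id
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        paths = {
            "baseline_pet": pdir / "baseline_pet.nii.gz",
            "followup_pet": pdir / "followup_pet.nii.gz",
            "baseline_truth": pdir / "baseline_truth.nii.gz",
            "followup_truth": pdir / "followup_truth.nii.gz",
        }
        write_volume(patient.baseline_volume, paths["baseline_pet"])
        write_volume(patient.followup_volume, paths["followup_pet"])
        write_labelmap_nifti(
            patient.baseline_truth.values, patient.baseline_volume, paths["baseline_truth"]
        )
        write_labelmap_nifti(
            patient.followup_truth.values, patient.followup_volume, paths["followup_truth"]
        )
        excl = np.zeros(patient.baseline_volume.shape, dtype=bool)
        for region in patient.edits_baseline.exclusions:
            excl |= region.values
        excl_path = pdir / "physiologic_mask.nii.gz"
        write_mask(BinaryMask(excl, patient.baseline_volume), excl_path)
        rows.append(
            {
                "patient_id": pid,
                **{k: str(v.relative_to(out)) for k, v in paths.items()},
                "physiologic_mask": str(excl_path.relative_to(out)),
                "interval_months": patient.interval_months,
                "time_months": patient.survival.time,
                "event": patient.survival.event,
                "intended_class": patient.intended_class.value,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
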