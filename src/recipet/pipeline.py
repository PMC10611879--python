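"""End-to-end orchestration: delineate, match, classify, and report.

The pipeline mirrors the clinical workflow: for each patient, delineate
both timepoints (SUV threshold + physiologic exclusions + manual
insertions, or an observer model applied to the reference), match lesions
across timepoints, compute total tumour volume and its change, apply the
RECIP 1.0 rules, then pool patients for survival and agreement
statistics. Patients lacking a usable follow-up scan are excluded with a
logged reason rather than dropped silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import (
    DEFAULT_CUTOFFS,
    ConfusionMatrix2x2,
    cohens_kappa,
    percent_agreement,
    spearman_corr,
    threshold_sweep,
)
from .delineation import (
    BinaryMask,
    Delineation,
    EditScript,
    LabelMap,
    delineate,
    lesion_stats,
)
from .imaging import PetVolume, read_labelmap_nifti, read_mask, read_volume
from .longitudinal import MatchResult, StudyPair, count_new_lesions, match_lesions
from .recip import (
    RecipClass,
    RecipPolicy,
    RECIPResult,
    TTVPair,
    classify_recip,
    delta_ttv,
    total_tumour_volume,
)
from .survival import (
    CoxDiagnosticError,
    SurvivalRecord,
    UndefinedStatisticError,
    cox_univariate,
    km_estimate,
    logrank_test,
)
from .synthetic import (
    SUV_THRESHOLD,
    CohortSpec,
    SyntheticPatient,
    observe,
    simulate_cohort,
    truth_delineation,
)

logger = logging.getLogger("recipet")

__all__ = [
    "RunConfig",
    "PatientOutcome",
    "classify_pair",
    "classify_synthetic_cohort",
    "classify_manifest_cohort",
    "results_table",
    "run_statistics",
    "format_summary",
]


@dataclass(frozen=True)
class RunConfig:
    """Tunable analysis parameters, with the clinical defaults."""

    threshold: float = SUV_THRESHOLD
    connectivity: int = 26
    max_centroid_mm: float = 10.0
    dilation_voxels: int = 1
    min_voxels: int = 0
    policy: RecipPolicy = RecipPolicy()
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS


@dataclass
class PatientOutcome:
    """Classification plus audit trail for one patient under one rater."""

    result: RECIPResult
    match: MatchResult
    baseline_lesions: int
    followup_lesions: int

    def audit_dict(self) -> dict:
        return {
            "patient_id": self.result.patient_id,
            "baseline_lesions": self.baseline_lesions,
            "followup_lesions": self.followup_lesions,
            "match": self.match.to_dict(),
        }


def classify_pair(
    patient_id: str,
    baseline: Delineation,
    followup: Delineation,
    interval_months: float = 6.0,
    config: RunConfig = RunConfig(),
) -> PatientOutcome:
    """Match lesions, measure TTV change, and classify one patient."""
    pair = StudyPair(patient_id, baseline, followup, interval_months)
    match = match_lesions(
        pair,
        max_centroid_mm=config.max_centroid_mm,
        dilation_voxels=config.dilation_voxels,
    )
    ttv = TTVPair(total_tumour_volume(baseline), total_tumour_volume(followup))
    delta = delta_ttv(ttv)
    new = count_new_lesions(match) if ttv.followup_ttv > 0 else 0
    recip_class = classify_recip(delta, new, ttv, policy=config.policy)
    result = RECIPResult(patient_id, ttv, delta, new, recip_class)
    return PatientOutcome(result, match, baseline.n_lesions, followup.n_lesions)


def _classify_patient_raters(
    patient: SyntheticPatient,
    config: RunConfig,
    raters: Sequence[str],
    degraded_model,
    seed: int,
) -> dict[str, PatientOutcome]:
    out: dict[str, PatientOutcome] = {}
    base_truth_d = truth_delineation(patient.baseline_volume, patient.baseline_truth)
    foll_truth_d = truth_delineation(patient.followup_volume, patient.followup_truth)
    for rater in raters:
        if rater == "truth":
            base, foll = base_truth_d, foll_truth_d
        elif rater == "manual":
            base = delineate(
                patient.baseline_volume,
                threshold=config.threshold,
                edits=patient.edits_baseline,
                connectivity=config.connectivity,
                min_voxels=config.min_voxels,
            )
            foll = delineate(
                patient.followup_volume,
                threshold=config.threshold,
                edits=patient.edits_followup,
                connectivity=config.connectivity,
                min_voxels=config.min_voxels,
            )
        elif rater == "degraded":
            pid_num = int(patient.patient_id.lstrip("P"))
            base = observe(
                patient.baseline_volume, base_truth_d, degraded_model, seed=seed * 100003 + pid_num * 2
            )
            foll = observe(
                patient.followup_volume, foll_truth_d, degraded_model, seed=seed * 100003 + pid_num * 2 + 1
            )
        else:
            raise ValueError(f"unknown rater {rater!r}")
        out[rater] = classify_pair(
            patient.patient_id, base, foll, patient.interval_months, config
        )
    return out


@dataclass
class CohortClassification:
    """Per-rater classification results plus the shared survival records."""

    outcomes: dict[str, list[PatientOutcome]]
    survival: list[SurvivalRecord]
    intended_classes: list[RecipClass] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)


def classify_synthetic_cohort(
    spec: CohortSpec,
    seed: int,
    config: RunConfig = RunConfig(),
    raters: Sequence[str] = ("manual", "degraded"),
) -> CohortClassification:
    """Generate and classify a synthetic cohort patient-by-patient.

    Volumes are streamed: each phantom is rendered, delineated by every
    requested rater ("manual", "degraded", "truth"), classified, and
    discarded before the next patient is generated.
    """
    outcomes: dict[str, list[PatientOutcome]] = {r: [] for r in raters}
    survival: list[SurvivalRecord] = []
    intended: list[RecipClass] = []
    for patient in simulate_cohort(spec, seed):
        per_rater = _classify_patient_raters(
            patient, config, raters, spec.degraded_observer, seed
        )
        for rater, outcome in per_rater.items():
            outcomes[rater].append(outcome)
        survival.append(patient.survival)
        intended.append(patient.intended_class)
    return CohortClassification(outcomes, survival, intended)


def _edits_from_truth(
    volume: PetVolume, truth: LabelMap, physiologic: BinaryMask, threshold: float
) -> EditScript:
    """Reconstruct the manual edit script from on-disk truth artefacts:
    exclusions from the physiologic mask, additions from truth lesions
    whose peak SUV never reaches the threshold."""
    additions = []
    for lesion in lesion_stats(truth, volume):
        if lesion.suv_max < threshold:
            additions.append(BinaryMask(truth.values == lesion.label, volume))
    return EditScript(exclusions=[physiologic], additions=additions)


def classify_manifest_cohort(
    manifest_path,
    config: RunConfig = RunConfig(),
) -> CohortClassification:
    """Classify a cohort stored on disk (manifest CSV + NIfTI files).

    Expects the manifest schema written by
    :func:`recipet.synthetic.generate_cohort`. Patients with missing or
    unreadable scans are excluded with a logged reason.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError(f"{manifest_path}: manifest lists no patients")
    outcomes: dict[str, list[PatientOutcome]] = {"manual": []}
    survival: list[SurvivalRecord] = []
    excluded: list[dict] = []
    for row in manifest.itertuples(index=False):
        try:
            base_vol = read_volume(root / row.baseline_pet)
            foll_vol = read_volume(root / row.followup_pet)
            base_truth = LabelMap(read_labelmap_nifti(root / row.baseline_truth, base_vol), base_vol)
            foll_truth = LabelMap(read_labelmap_nifti(root / row.followup_truth, foll_vol), foll_vol)
            physio = read_mask(root / row.physiologic_mask, base_vol)
        except Exception as err:  # missing scan, bad geometry, bad format
            logger.warning("excluding %s: %s", row.patient_id, err)
            excluded.append({"patient_id": row.patient_id, "reason": str(err)})
            continue
        base = delineate(
            base_vol,
            threshold=config.threshold,
            edits=_edits_from_truth(base_vol, base_truth, physio, config.threshold),
            connectivity=config.connectivity,
            min_voxels=config.min_voxels,
        )
        foll = delineate(
            foll_vol,
            threshold=config.threshold,
            edits=_edits_from_truth(foll_vol, foll_truth, BinaryMask(physio.values, foll_vol), config.threshold),
            connectivity=config.connectivity,
            min_voxels=config.min_voxels,
        )
        outcomes["manual"].append(
            classify_pair(str(row.patient_id), base, foll, float(row.interval_months), config)
        )
        survival.append(
            SurvivalRecord(float(row.time_months), int(row.event), 0.0)
        )
    result = CohortClassification(outcomes, survival, excluded=excluded)
    return result


def results_table(outcomes: Sequence[PatientOutcome]) -> pd.DataFrame:
    """Per-patient RECIP results as a tidy frame (presentation rounding:
    volumes to 2 dp, percentages to 1 dp; classification itself always
    uses unrounded values)."""
    rows = []
    for o in outcomes:
        r = o.result
        rows.append(
            {
                "patient_id": r.patient_id,
                "baseline_ttv_ml": round(r.ttv.baseline_ttv, 2),
                "followup_ttv_ml": round(r.ttv.followup_ttv, 2),
                "delta_ttv_pct": (
                    math.inf if r.delta.undefined_flag else round(r.delta.percent, 1)
                ),
                "new_lesions": r.new_lesions,
                "recip_class": r.recip_class.value,
                "pd_flag": r.pd_flag,
            }
        )
    return pd.DataFrame(rows)


def _km_summary(records: list[SurvivalRecord]) -> dict:
    curve = km_estimate(records)
    return {
        "n": len(records),
        "events": int(sum(r.event for r in records)),
        "median_os_months": None if not curve.median_reached else round(curve.median, 1),
    }


def run_statistics(
    classification: CohortClassification,
    primary_rater: str = "manual",
    second_rater: str | None = None,
    config: RunConfig = RunConfig(),
) -> dict:
    """The cohort-level statistical battery.

    Produces, for the primary rater: PD prevalence, Kaplan-Meier
    summaries per PD group, the log-rank test, the univariate Cox fit of
    the PD flag (HR, 95% CI, Wald p, Harrell C), and the dTTV cutoff
    sweep. With a second rater: the 2x2 confusion matrix, Cohen's kappa
    with its band, percent agreement, per-cutoff kappas, and Spearman
    correlation of the two raters' TTVs at both timepoints. Individual
    statistical failures are reported in place without aborting the
    bundle.
    """
    outcomes = classification.outcomes[primary_rater]
    survival = classification.survival
    results = [o.result for o in outcomes]
    pd_flags = [r.pd_flag for r in results]
    n = len(results)
    n_pd = sum(pd_flags)
    deltas = [r.delta for r in results]

    bundle: dict = {
        "n": n,
        "n_pd": n_pd,
        "pd_prevalence_pct": round(100.0 * n_pd / n, 1) if n else None,
        "n_delta_ge_20": sum(
            1 for d in deltas if d.undefined_flag or d.percent >= 20.0
        ),
        "class_counts": {
            c.value: sum(1 for r in results if r.recip_class is c) for c in RecipClass
        },
    }

    records_pd = [
        SurvivalRecord(s.time, s.event, 1.0)
        for s, f in zip(survival, pd_flags) if f
    ]
    records_nonpd = [
        SurvivalRecord(s.time, s.event, 0.0)
        for s, f in zip(survival, pd_flags) if not f
    ]
    if records_pd and records_nonpd:
        bundle["km"] = {
            "pd": _km_summary(records_pd),
            "non_pd": _km_summary(records_nonpd),
        }
        try:
            chi2, p = logrank_test(records_pd, records_nonpd)
            bundle["logrank"] = {"chi2": round(chi2, 3), "p": p}
        except UndefinedStatisticError as err:
            bundle["logrank"] = {"error": str(err)}
        try:
            fit = cox_univariate(records_pd + records_nonpd)
            bundle["cox_pd"] = {
                "hr": round(fit.hr, 2),
                "ci95": (round(fit.ci95[0], 2), round(fit.ci95[1], 2)),
                "p": fit.wald_p,
                "c_index": round(fit.c_index, 2),
                "n_events": fit.n_events,
            }
        except CoxDiagnosticError as err:
            bundle["cox_pd"] = {"error": str(err)}
    else:
        bundle["km"] = {"error": "cohort has a single PD group; no comparison possible"}

    second_deltas = None
    if second_rater is not None:
        second_results = [o.result for o in classification.outcomes[second_rater]]
        second_deltas = [r.delta for r in second_results]

    sweep = threshold_sweep(
        deltas, survival, cutoffs=config.cutoffs, second_rater_deltas=second_deltas
    )
    bundle["sweep"] = [
        {
            "cutoff_pct": row.cutoff_pct,
            "n_exposed": row.n_exposed,
            **(
                {
                    "hr": round(row.fit.hr, 2),
                    "ci95": (round(row.fit.ci95[0], 2), round(row.fit.ci95[1], 2)),
                    "p": row.fit.wald_p,
                    "c_index": round(row.fit.c_index, 2),
                }
                if row.fit
                else {"error": row.error}
            ),
            **({"kappa": round(row.kappa, 2)} if row.kappa is not None else {}),
        }
        for row in sweep
    ]

    if second_rater is not None:
        second_results = [o.result for o in classification.outcomes[second_rater]]
        matrix = ConfusionMatrix2x2.from_flags(
            pd_flags, [r.pd_flag for r in second_results]
        )
        overall, row_nonpd, row_pd = percent_agreement(matrix)
        agreement: dict = {
            "confusion": {"a": matrix.a, "b": matrix.b, "c": matrix.c, "d": matrix.d},
            "percent_agreement": round(overall, 1),
            "agreement_nonpd_row": None if row_nonpd is None else round(row_nonpd, 1),
            "agreement_pd_row": None if row_pd is None else round(row_pd, 1),
        }
        try:
            kap = cohens_kappa(matrix)
            agreement["kappa"] = round(kap.kappa, 2)
            agreement["kappa_band"] = kap.band
        except UndefinedStatisticError as err:
            agreement["kappa_error"] = str(err)
        for label, attr in (("baseline", "baseline_ttv"), ("followup", "followup_ttv")):
            try:
                agreement[f"spearman_ttv_{label}"] = round(
                    spearman_corr(
                        [getattr(r.ttv, attr) for r in results],
                        [getattr(r.ttv, attr) for r in second_results],
                    ),
                    2,
                )
            except (ValueError, UndefinedStatisticError):
                agreement[f"spearman_ttv_{label}"] = None
        bundle["agreement"] = agreement

    return bundle


def format_summary(bundle: dict) -> str:
    """Plain-text report of the statistics bundle."""
    lines = [
        f"Patients analysed: {bundle['n']}",
        f"RECIP-PD: {bundle['n_pd']} ({bundle['pd_prevalence_pct']}%)",
        f"dTTV >= 20%: {bundle['n_delta_ge_20']}",
        "Class counts: "
        + ", ".join(f"{k}={v}" for k, v in bundle["class_counts"].items()),
    ]
    if "logrank" in bundle and "p" in bundle.get("logrank", {}):
        lines.append(f"Log-rank: chi2={bundle['logrank']['chi2']}, p={bundle['logrank']['p']:.4g}")
    cox = bundle.get("cox_pd", {})
    if "hr" in cox:
        lines.append(
            f"Cox (RECIP-PD): HR={cox['hr']} (95% CI {cox['ci95'][0]}-{cox['ci95'][1]}), "
            f"p={cox['p']:.4g}, C-index={cox['c_index']}"
        )
    agr = bundle.get("agreement")
    if agr:
        lines.append(
            f"Agreement: {agr['percent_agreement']}% overall; "
            f"kappa={agr.get('kappa')} ({agr.get('kappa_band')})"
        )
    lines.append("dTTV cutoff sweep:")
    for row in bundle.get("sweep", []):
        if "hr" in row:
            extra = f", kappa={row['kappa']}" if "kappa" in row else ""
            lines.append(
                f"  cutoff {row['cutoff_pct']:>4.0f}%: HR={row['hr']} "
                f"(95% CI {row['ci95'][0]}-{row['ci95'][1]}), p={row['p']:.3g}, "
                f"C-index={row['c_index']}{extra}"
            )
        else:
            lines.append(f"  cutoff {row['cutoff_pct']:>4.0f}%: {row.get('error')}")
    return "\n".join(lines)
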