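import math

import numpy as np
import pytest

from recipet.delineation import EditScript, delineate, threshold_segment
from recipet.imaging import voxel_volume_ml
from recipet.pipeline import classify_pair
from recipet.recip import RecipClass
from recipet.synthetic import (
    CohortSpec,
    LesionSpec,
    ObserverModel,
    PhantomSpec,
    PhantomSpecError,
    evolve_phantom,
    generate_cohort,
    generate_phantom,
    observe,
    radius_for_volume,
    simulate_cohort,
    simulate_survival,
    snap_to_voxel_center,
    truth_delineation,
)

SPACING = (4.07, 4.07, 3.0)
SHAPE = (48, 48, 48)
CENTER = snap_to_voxel_center((95.0, 95.0, 70.0), SPACING)
FAR = snap_to_voxel_center((40.0, 40.0, 30.0), SPACING)


def spec_with(lesions, seed=0, shape=SHAPE):
    return PhantomSpec(shape=shape, spacing=SPACING, lesions=tuple(lesions), seed=seed)


class TestGeneratePhantom:
    def test_deterministic_given_seed(self):
        spec = spec_with([LesionSpec(CENTER, 10.0, 8.0)])
        vol1, truth1 = generate_phantom(spec)
        vol2, truth2 = generate_phantom(spec)
        assert np.array_equal(vol1.values, vol2.values)
        assert np.array_equal(truth1.values, truth2.values)

    def test_zero_lesions_empty_truth(self):
        vol, truth = generate_phantom(spec_with([]))
        assert truth.n_labels == 0
        assert vol.values.max() < 3.0  # background never crosses the threshold

    def test_target_volume_constructed_by_voxel_counting(self):
        """A phantom constructed for a 7.86 mL supra-threshold lesion
        yields that thresholded volume to within one voxel."""
        center = (95.7, 94.3, 69.8)  # off voxel centers: no degenerate shells
        radius = radius_for_volume(7.86, SPACING, center_mm=center)
        spec = spec_with([LesionSpec(center, radius, 8.0)])
        vol, _ = generate_phantom(spec)
        ttv = threshold_segment(vol, 3.0).voxel_count * voxel_volume_ml(vol)
        assert abs(ttv - 7.86) <= voxel_volume_ml(vol)

    def test_subthreshold_lesion_in_truth_but_not_threshold(self):
        spec = spec_with([LesionSpec(CENTER, 8.0, 2.8)])
        vol, truth = generate_phantom(spec)
        assert truth.n_labels == 1
        assert threshold_segment(vol, 3.0).voxel_count == 0

    def test_overlapping_blobs_rejected(self):
        with pytest.raises(PhantomSpecError):
            generate_phantom(
                spec_with(
                    [LesionSpec(CENTER, 12.0, 8.0), LesionSpec(CENTER, 10.0, 6.0)]
                )
            )

    def test_truth_volume_close_to_analytic_sphere(self):
        radius = 12.0
        spec = spec_with([LesionSpec(CENTER, radius, 8.0)])
        vol, truth = generate_phantom(spec)
        voxels = int((truth.values == 1).sum())
        analytic_ml = 4.0 / 3.0 * math.pi * radius**3 / 1000.0
        assert voxels * voxel_volume_ml(vol) == pytest.approx(analytic_ml, rel=0.1)


class TestEvolvePhantom:
    def test_unit_growth_preserves_thresholded_volume(self):
        spec = spec_with([LesionSpec(CENTER, 10.0, 8.0, growth_factor=1.0)])
        base, _ = generate_phantom(spec)
        foll, _ = evolve_phantom(spec)
        assert (
            threshold_segment(base).voxel_count == threshold_segment(foll).voxel_count
        )

    def test_growth_scales_volume(self):
        spec = spec_with([LesionSpec(CENTER, 10.0, 8.0, growth_factor=2.0)])
        base, _ = generate_phantom(spec)
        foll, _ = evolve_phantom(spec)
        ratio = threshold_segment(foll).voxel_count / threshold_segment(base).voxel_count
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_followup_only_lesion_appears(self):
        spec = spec_with(
            [
                LesionSpec(CENTER, 10.0, 8.0),
                LesionSpec(FAR, 8.0, 6.0, appears_at="followup"),
            ]
        )
        _, base_truth = generate_phantom(spec)
        _, foll_truth = evolve_phantom(spec)
        assert base_truth.n_labels == 1
        assert foll_truth.n_labels == 2

    def test_progression_pair_classifies_pd(self):
        """A progression pair — TTV growing
        from ~7.86 to ~13.60 mL plus one new lesion — comes out PD."""
        r_base = radius_for_volume(7.86, SPACING)
        growth = 13.60 / 7.86 - 0.3  # remaining increase comes from the new lesion
        new_radius = radius_for_volume(7.86 * 0.3, SPACING)
        spec = spec_with(
            [
                LesionSpec(CENTER, r_base, 9.0, growth_factor=growth),
                LesionSpec(FAR, new_radius, 6.0, appears_at="followup"),
            ]
        )
        base_vol, base_truth = generate_phantom(spec)
        foll_vol, foll_truth = evolve_phantom(spec)
        outcome = classify_pair(
            "worked-example",
            truth_delineation(base_vol, base_truth),
            truth_delineation(foll_vol, foll_truth),
        )
        assert outcome.result.recip_class is RecipClass.PD
        assert outcome.result.new_lesions == 1
        assert outcome.result.delta.percent > 20.0

    def test_shrinkage_classifies_pr(self):
        spec = spec_with([LesionSpec(CENTER, 10.0, 8.0, growth_factor=0.5)])
        base_vol, base_truth = generate_phantom(spec)
        foll_vol, foll_truth = evolve_phantom(spec)
        outcome = classify_pair(
            "pr",
            truth_delineation(base_vol, base_truth),
            truth_delineation(foll_vol, foll_truth),
        )
        assert outcome.result.recip_class is RecipClass.PR


class TestObserve:
    def _truth(self, lesions):
        spec = spec_with(lesions)
        vol, truth = generate_phantom(spec)
        return vol, truth_delineation(vol, truth)

    def test_null_observer_is_identity(self):
        vol, truth = self._truth([LesionSpec(CENTER, 10.0, 8.0), LesionSpec(FAR, 8.0, 2.5)])
        observed = observe(vol, truth, ObserverModel(), seed=5)
        assert np.array_equal(observed.labelmap.values > 0, truth.labelmap.values > 0)
        assert observed.n_lesions == truth.n_lesions

    def test_subthreshold_lesion_always_missed_at_pmiss_one(self):
        vol, truth = self._truth([LesionSpec(CENTER, 10.0, 8.0), LesionSpec(FAR, 8.0, 2.8)])
        observed = observe(
            vol, truth, ObserverModel(p_miss_subthreshold=1.0), seed=6
        )
        assert observed.n_lesions == 1
        assert all(l.suv_max >= 3.0 for l in observed.lesions)

    def test_suprathreshold_never_missed(self):
        vol, truth = self._truth([LesionSpec(CENTER, 10.0, 8.0)])
        for seed in range(5):
            observed = observe(
                vol, truth, ObserverModel(p_miss_subthreshold=1.0), seed=seed
            )
            assert observed.n_lesions == 1

    def test_false_positives_add_components(self):
        vol, truth = self._truth([LesionSpec(CENTER, 10.0, 8.0)])
        model = ObserverModel(false_positive_rate=3.0)
        observed = observe(vol, truth, model, seed=7)
        assert observed.n_lesions >= truth.n_lesions

    def test_deterministic_given_seed(self):
        vol, truth = self._truth([LesionSpec(CENTER, 10.0, 8.0), LesionSpec(FAR, 8.0, 2.5)])
        model = ObserverModel(p_miss_subthreshold=0.5, false_positive_rate=1.0)
        a = observe(vol, truth, model, seed=8)
        b = observe(vol, truth, model, seed=8)
        assert np.array_equal(a.labelmap.values, b.labelmap.values)


class TestSimulateSurvival:
    def test_no_time_exceeds_censoring_horizon(self):
        spec = CohortSpec(n_patients=100)
        rng = np.random.default_rng(20)
        recs = simulate_survival([True] * 20 + [False] * 80, spec, rng)
        assert max(r.time for r in recs) <= spec.censor_max_months

    def test_degenerate_cohort_rejected(self):
        spec = CohortSpec(n_patients=10)
        rng = np.random.default_rng(21)
        with pytest.raises(ValueError):
            simulate_survival([True] * 10, spec, rng)

    def test_pd_group_has_higher_event_rate(self):
        spec = CohortSpec(n_patients=400)
        rng = np.random.default_rng(22)
        recs = simulate_survival([True] * 200 + [False] * 200, spec, rng)
        rate_pd = np.mean([r.event for r in recs[:200]])
        rate_nonpd = np.mean([r.event for r in recs[200:]])
        assert rate_pd > rate_nonpd

    def test_heavy_censoring_in_nonpd_group(self):
        """With a long baseline median OS and a ~6-year horizon, most
        non-progressors are censored, as in the target population."""
        spec = CohortSpec(n_patients=500)
        rng = np.random.default_rng(23)
        recs = simulate_survival([True] * 50 + [False] * 450, spec, rng)
        censored_nonpd = np.mean([1 - r.event for r in recs[50:]])
        assert censored_nonpd > 0.7


class TestSimulateCohort:
    def test_streaming_patients_reproducible(self):
        spec = CohortSpec(n_patients=4, shape=(32, 32, 32))
        first = [p.patient_id for p in simulate_cohort(spec, seed=0)]
        again = list(simulate_cohort(spec, seed=0))
        assert first == [p.patient_id for p in again]
        p = again[0]
        assert p.baseline_volume.shape == (32, 32, 32)

    def test_manual_edits_reconstruct_truth_ttv(self):
        """Thresholding + organ exclusion + sub-threshold insertion gives
        the same foreground as the generator truth."""
        spec = CohortSpec(n_patients=3, shape=(64, 64, 64))
        for patient in simulate_cohort(spec, seed=0):
            manual = delineate(patient.baseline_volume, edits=patient.edits_baseline)
            truth_fg = patient.baseline_truth.values > 0
            assert np.array_equal(manual.labelmap.values > 0, truth_fg)


class TestGenerateCohortFiles:
    def test_manifest_round_trip_and_determinism(self, tmp_path):
        spec = CohortSpec(n_patients=2, shape=(32, 32, 32))
        m1 = generate_cohort(spec, tmp_path / "a", seed=0)
        m2 = generate_cohort(spec, tmp_path / "b", seed=0)
        assert len(m1) == 2
        assert (
            (tmp_path / "a" / "manifest.csv").read_bytes()
            == (tmp_path / "b" / "manifest.csv").read_bytes()
        )
        for col in ("baseline_pet", "followup_pet", "baseline_truth", "followup_truth"):
            for rel in m1[col]:
                assert (tmp_path / "a" / rel).exists()
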