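from collections import deque
from itertools import product

import numpy as np
import pytest

from recipet.delineation import (
    BinaryMask,
    EditConflictError,
    EditScript,
    LabelMap,
    apply_edits,
    connected_components,
    delineate,
    lesion_stats,
    threshold_segment,
)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Brute-force BFS partition of a boolean array; returns the set of
    components as frozensets of voxel coordinates."""
    offsets = [
        off
        for off in product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0)
        and {6: 1, 18: 2, 26: 3}[connectivity] >= sum(abs(o) for o in off)
    ]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = set()
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            voxel = queue.popleft()
            comp.add(voxel)
            for off in offsets:
                nb = tuple(v + o for v, o in zip(voxel, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        comps.add(frozenset(comp))
    return comps


def labelmap_components(labelmap: LabelMap) -> set[frozenset]:
    return {
        frozenset(zip(*np.nonzero(labelmap.values == k)))
        for k in range(1, labelmap.n_labels + 1)
    }


class TestThresholdSegment:
    def test_blob_above_background(self, make_volume):
        values = np.full((8, 8, 8), 0.5)
        values[3:5, 3:5, 3:5] = 5.0
        mask = threshold_segment(make_volume(values), 3.0)
        assert mask.voxel_count == 8
        assert mask.values[3:5, 3:5, 3:5].all()

    def test_subthreshold_lesion_invisible(self, make_volume):
        values = np.full((8, 8, 8), 0.5)
        values[2:6, 2:6, 2:6] = 2.8  # faint lesion below the SUV-3 threshold
        assert threshold_segment(make_volume(values), 3.0).voxel_count == 0

    def test_low_threshold_full_mask(self, make_volume):
        mask = threshold_segment(make_volume(np.full((4, 4, 4), 0.5)), 0.1)
        assert mask.voxel_count == 64

    def test_comparison_is_inclusive(self, make_volume):
        values = np.full((3, 3, 3), 3.0)
        assert threshold_segment(make_volume(values), 3.0).voxel_count == 27

    def test_monotone_in_threshold(self, make_volume):
        rng = np.random.default_rng(6)
        vol = make_volume(rng.uniform(0, 6, (10, 10, 10)))
        low = threshold_segment(vol, 2.0).values
        high = threshold_segment(vol, 4.0).values
        assert not (high & ~low).any()

    def test_nonpositive_threshold_rejected(self, make_volume):
        with pytest.raises(ValueError):
            threshold_segment(make_volume(np.zeros((2, 2, 2))), 0.0)


class TestConnectedComponents:
    def test_two_separated_blobs(self, make_volume):
        values = np.zeros((10, 10, 10))
        values[1:3, 1:3, 1:3] = 5
        values[7:9, 7:9, 7:9] = 5
        mask = threshold_segment(make_volume(values))
        assert connected_components(mask).n_labels == 2

    def test_diagonal_touch_depends_on_connectivity(self, make_volume):
        values = np.zeros((4, 4, 4))
        values[0, 0, 0] = 5
        values[1, 1, 1] = 5
        mask = threshold_segment(make_volume(values))
        assert connected_components(mask, connectivity=26).n_labels == 1
        assert connected_components(mask, connectivity=6).n_labels == 2

    def test_empty_mask(self, make_volume):
        mask = threshold_segment(make_volume(np.zeros((4, 4, 4)) + 0.1), 3.0)
        assert connected_components(mask).n_labels == 0

    def test_label_order_descending_size(self, make_volume):
        values = np.zeros((12, 12, 12))
        values[0:2, 0:2, 0:2] = 5       # 8 voxels
        values[6:10, 6:10, 6:10] = 5    # 64 voxels
        labelmap = connected_components(threshold_segment(make_volume(values)))
        counts = np.bincount(labelmap.values.ravel())[1:]
        assert list(counts) == sorted(counts, reverse=True) == [64, 8]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_partition_matches_flood_fill_oracle(self, make_volume, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(10):
            arr = rng.random((9, 9, 9)) > 0.72
            mask = BinaryMask(arr, make_volume(np.zeros((9, 9, 9))))
            got = labelmap_components(connected_components(mask, connectivity))
            assert got == flood_fill_components(arr, connectivity)

    def test_invalid_connectivity_rejected(self, make_volume):
        mask = BinaryMask(np.zeros((3, 3, 3), dtype=bool), make_volume(np.zeros((3, 3, 3))))
        with pytest.raises(ValueError):
            connected_components(mask, connectivity=4)


def _two_blob_volume(make_volume):
    values = np.full((12, 12, 12), 0.3)
    values[1:4, 1:4, 1:4] = 8.0    # "bladder"
    values[8:11, 8:11, 8:11] = 5.0  # lesion
    return make_volume(values)


class TestApplyEdits:
    def test_physiologic_component_removed(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        excl = np.zeros(vol.shape, dtype=bool)
        excl[0:5, 0:5, 0:5] = True
        edited = apply_edits(labelmap, EditScript(exclusions=[BinaryMask(excl, vol)]))
        assert edited.n_labels == 1
        assert not edited.values[2, 2, 2]
        assert edited.values[9, 9, 9]

    def test_empty_script_identity(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        edited = apply_edits(labelmap, EditScript())
        assert np.array_equal(edited.values, labelmap.values)

    def test_disjoint_addition_adds_one_component(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        add = np.zeros(vol.shape, dtype=bool)
        add[5:7, 1:3, 8:10] = True
        edited = apply_edits(labelmap, EditScript(additions=[BinaryMask(add, vol)]))
        assert edited.n_labels == labelmap.n_labels + 1

    def test_overlapping_addition_merges(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        add = np.zeros(vol.shape, dtype=bool)
        add[9:12, 9:12, 9:12] = True  # overlaps the lesion component
        edited = apply_edits(labelmap, EditScript(additions=[BinaryMask(add, vol)]))
        assert edited.n_labels == labelmap.n_labels

    def test_addition_inside_exclusion_conflicts(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        region = np.zeros(vol.shape, dtype=bool)
        region[0:4, 0:4, 0:4] = True
        with pytest.raises(EditConflictError):
            apply_edits(
                labelmap,
                EditScript(
                    exclusions=[BinaryMask(region, vol)],
                    additions=[BinaryMask(region.copy(), vol)],
                ),
            )

    def test_remove_then_readd_restores_voxels(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        bladder = np.array(labelmap.values == labelmap.values[2, 2, 2])
        removed = apply_edits(labelmap, EditScript(exclusions=[BinaryMask(bladder, vol)]))
        restored = apply_edits(removed, EditScript(additions=[BinaryMask(bladder, vol)]))
        assert np.array_equal(restored.values > 0, labelmap.values > 0)

    def test_partial_overlap_below_half_is_kept(self, make_volume):
        vol = _two_blob_volume(make_volume)
        labelmap = connected_components(threshold_segment(vol))
        excl = np.zeros(vol.shape, dtype=bool)
        excl[1:2, 1:4, 1:4] = True  # 9 of 27 bladder voxels: below the 50% rule
        edited = apply_edits(labelmap, EditScript(exclusions=[BinaryMask(excl, vol)]))
        assert edited.n_labels == 2


class TestLesionStats:
    def test_volume_from_voxel_count(self, make_volume):
        values = np.full((10, 10, 10), 0.2)
        values[0:10, 0:5, 0:4] = 5.0  # 10*5*4 = 200 voxels
        vol = make_volume(values)  # 2 mm isotropic, 0.008 mL/voxel
        labelmap = connected_components(threshold_segment(vol))
        (lesion,) = lesion_stats(labelmap, vol)
        assert lesion.voxel_count == 200
        assert lesion.volume_ml == pytest.approx(1.6)

    def test_suv_max_and_mean(self, make_volume):
        values = np.full((5, 5, 5), 0.1)
        values[1, 1, 1], values[1, 1, 2], values[1, 1, 3] = 2.0, 4.0, 9.0
        vol = make_volume(values)
        labelmap = connected_components(threshold_segment(vol, threshold=1.0))
        (lesion,) = lesion_stats(labelmap, vol)
        assert lesion.suv_max == pytest.approx(9.0)
        assert lesion.suv_mean == pytest.approx(5.0)
        assert lesion.suv_max >= lesion.suv_mean >= 0

    def test_single_voxel_centroid_is_world_coordinate(self, make_volume):
        values = np.full((6, 6, 6), 0.1)
        values[2, 3, 4] = 7.0
        vol = make_volume(values, spacing=(4.07, 4.07, 3.0), origin=(1.0, 2.0, 3.0))
        labelmap = connected_components(threshold_segment(vol))
        (lesion,) = lesion_stats(labelmap, vol)
        expected = (1.0 + 2 * 4.07, 2.0 + 3 * 4.07, 3.0 + 4 * 3.0)
        assert lesion.centroid_mm == pytest.approx(expected)

    def test_grid_mismatch_rejected(self, make_volume):
        vol_a = make_volume(np.zeros((4, 4, 4)))
        vol_b = make_volume(np.zeros((4, 4, 4)), spacing=(3.0, 3.0, 3.0))
        labelmap = LabelMap(np.zeros((4, 4, 4), dtype=np.int32), vol_a)
        from recipet.imaging import GeometryError

        with pytest.raises(GeometryError):
            lesion_stats(labelmap, vol_b)


class TestDelineate:
    def test_min_voxel_floor_drops_specks(self, make_volume):
        values = np.full((10, 10, 10), 0.2)
        values[1, 1, 1] = 5.0                 # single-voxel speck
        values[5:8, 5:8, 5:8] = 5.0           # 27-voxel lesion
        vol = make_volume(values)
        assert delineate(vol).n_lesions == 2
        assert delineate(vol, min_voxels=5).n_lesions == 1


class TestEditScriptSerialisation:
    def test_json_round_trip(self, tmp_path, make_volume):
        vol = _two_blob_volume(make_volume)
        excl = np.zeros(vol.shape, dtype=bool)
        excl[0:5, 0:5, 0:5] = True
        add = np.zeros(vol.shape, dtype=bool)
        add[5:7, 1:3, 8:10] = True
        script = EditScript(
            exclusions=[BinaryMask(excl, vol)], additions=[BinaryMask(add, vol)]
        )
        path = tmp_path / "edits.json"
        script.save(path, vol)
        back = EditScript.load(path, vol)
        assert np.array_equal(back.exclusions[0].values, excl)
        assert np.array_equal(back.additions[0].values, add)
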