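"""3D connected components and the case-level two-lung filter."""

import numpy as np
import pytest

from ctlungseg import (
    MaskVolume,
    case_filter,
    inject_edge_blobs,
    label_components_3d,
)


def brute_force_components(voxels, connectivity):
    """Independent flood-fill labeling for the oracle comparison."""
    offsets = []
    for dz in (-1, 0, 1):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dz, dr, dc) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dr) + abs(dc) != 1:
                    continue
                offsets.append((dz, dr, dc))
    seen = np.zeros_like(voxels, dtype=bool)
    sizes = []
    for start in zip(*np.nonzero(voxels)):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            z, r, c = stack.pop()
            size += 1
            for dz, dr, dc in offsets:
                nz, nr, nc = z + dz, r + dr, c + dc
                if (
                    0 <= nz < voxels.shape[0]
                    and 0 <= nr < voxels.shape[1]
                    and 0 <= nc < voxels.shape[2]
                    and voxels[nz, nr, nc]
                    and not seen[nz, nr, nc]
                ):
                    seen[nz, nr, nc] = True
                    stack.append((nz, nr, nc))
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestLabelComponents:
    def test_empty_mask_yields_empty_list(self):
        assert label_components_3d(MaskVolume(np.zeros((3, 8, 8), dtype=np.uint8))) == []

    def test_three_boxes_sorted_by_volume(self):
        vox = np.zeros((6, 20, 20), dtype=np.uint8)
        vox[0:1, 0:10, 0:10] = 1  # 100
        vox[2:3, 12:20, 10:20] = 1  # 80
        vox[4:5, 0:1, 15:20] = 1  # 5
        comps = label_components_3d(MaskVolume(vox))
        assert [c.volume for c in comps] == [100, 80, 5]

    def test_corner_touch_merges_under_26_but_not_6(self):
        vox = np.zeros((4, 6, 6), dtype=np.uint8)
        vox[0:2, 0:2, 0:2] = 1
        vox[2:4, 2:4, 2:4] = 1  # touches only at voxel corner (1,1,1)-(2,2,2)
        assert len(label_components_3d(MaskVolume(vox), connectivity=26)) == 1
        assert len(label_components_3d(MaskVolume(vox), connectivity=6)) == 2

    def test_matches_brute_force_flood_fill(self, rng):
        vox = (rng.random((6, 12, 12)) > 0.7).astype(np.uint8)
        for conn in (6, 26):
            got = [c.volume for c in label_components_3d(MaskVolume(vox), conn)]
            assert got == brute_force_components(vox, conn)

    def test_component_geometry_fields(self):
        vox = np.zeros((3, 10, 10), dtype=np.uint8)
        vox[1, 2:5, 3:7] = 1
        (comp,) = label_components_3d(MaskVolume(vox))
        assert comp.volume == 12
        assert comp.bbox == (1, 2, 2, 5, 3, 7)
        z, r, c = comp.centroid
        assert (z, r, c) == (1.0, 3.0, 4.5)

    def test_non_binary_mask_rejected(self):
        arr = np.zeros((2, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="binary"):
            label_components_3d(arr + 2)


class TestCaseFilter:
    def test_keeps_exactly_the_two_true_lungs(self, clean_phantom):
        corrupted, centres = inject_edge_blobs(clean_phantom.mask, n_blobs=5, seed=21)
        filtered, report = case_filter(corrupted)
        comps = label_components_3d(filtered)
        assert len(comps) == 2
        # every injected blob voxel is gone
        for z, r, c in centres:
            assert filtered.voxels[z, r, c] == 0
        # and the true lungs survive untouched
        assert np.array_equal(
            filtered.voxels & clean_phantom.mask.voxels, clean_phantom.mask.voxels
        )
        assert len(report.kept) == 2
        assert report.removed  # the injected blobs were explicitly rejected

    def test_never_adds_voxels(self, clean_phantom):
        corrupted, _ = inject_edge_blobs(clean_phantom.mask, n_blobs=3, seed=4)
        filtered, _ = case_filter(corrupted)
        assert np.all(filtered.voxels <= corrupted.voxels)

    def test_idempotent(self, clean_phantom):
        corrupted, _ = inject_edge_blobs(clean_phantom.mask, n_blobs=4, seed=8)
        once, _ = case_filter(corrupted)
        twice, _ = case_filter(once)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_single_central_component_is_retained(self):
        vox = np.zeros((4, 32, 32), dtype=np.uint8)
        vox[1:3, 12:20, 12:20] = 1
        filtered, report = case_filter(MaskVolume(vox))
        assert np.array_equal(filtered.voxels, vox)
        assert len(report.kept) == 1 and not report.warnings

    def test_empty_mask_warns_and_stays_empty(self):
        filtered, report = case_filter(MaskVolume(np.zeros((2, 16, 16), dtype=np.uint8)))
        assert filtered.voxels.sum() == 0
        assert report.warnings

    def test_peripheral_only_mask_warns(self):
        vox = np.zeros((2, 64, 64), dtype=np.uint8)
        vox[:, 0:2, 0:2] = 1  # centroid far outside the central window
        filtered, report = case_filter(MaskVolume(vox), location_prior=0.8)
        assert filtered.voxels.sum() == 0
        assert any("location prior" in w for w in report.warnings)

    def test_third_largest_central_component_is_dropped(self):
        vox = np.zeros((3, 40, 40), dtype=np.uint8)
        vox[:, 10:20, 8:14] = 1  # lung 1 (big)
        vox[:, 10:20, 24:30] = 1  # lung 2 (big)
        vox[1, 30:32, 18:20] = 1  # small central junk
        filtered, report = case_filter(MaskVolume(vox))
        assert len(report.kept) == 2
        assert filtered.voxels[1, 30:32, 18:20].sum() == 0

    def test_invalid_location_prior_rejected(self, clean_phantom):
        with pytest.raises(ValueError, match="location_prior"):
            case_filter(clean_phantom.mask, location_prior=0.0)


def test_filter_bridges_dropout_slices(noisy_phantom):
    """Dropout removes lung voxels on some slices; the pristine lungs must
    still form exactly two 3D components so the filter keeps both."""
    filtered, _ = case_filter(noisy_phantom.degraded_mask)
    comps = label_components_3d(filtered)
    assert 1 <= len(comps) <= 2
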