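"""ROI geometry: subtraction, distance bands, NAWM mirror, set identities."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from periprog.roi import (
    build_roi_set,
    nawm_mask,
    progression_roi,
    roi_label_volume,
    shell_masks,
)


def sphere(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                        indexing="ij")
    return sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2


def brute_force_distance(mask, spacing=(1.0, 1.0, 1.0)):
    """Distance to the nearest mask voxel via a KD-tree (independent of EDT)."""
    pts = np.argwhere(mask) * np.asarray(spacing)
    tree = cKDTree(pts)
    all_pts = np.argwhere(np.ones(mask.shape, bool)) * np.asarray(spacing)
    d, _ = tree.query(all_pts)
    return d.reshape(mask.shape)


class TestProgressionRoi:
    def test_full_overlap_gives_empty_mask(self):
        ce = np.zeros((5, 5, 5), bool)
        ce[1:4, 1:4, 1:4] = True
        prog = np.zeros_like(ce)
        prog[2, 2, 2] = True
        assert not progression_roi(prog, ce).any()

    def test_disjoint_masks_unchanged(self):
        ce = np.zeros((5, 5, 5), bool)
        ce[0, 0, 0] = True
        prog = np.zeros_like(ce)
        prog[4, 4, 4] = True
        assert np.array_equal(progression_roi(prog, ce), prog)

    def test_partial_overlap_by_set_enumeration(self):
        rng = np.random.default_rng(0)
        ce = np.zeros((5, 5, 5), bool)
        prog = np.zeros((5, 5, 5), bool)
        flat = rng.choice(125, size=40, replace=False)
        prog.ravel()[flat[:30]] = True  # 30 progression voxels
        ce.ravel()[flat[18:40]] = True  # overlap of exactly 12
        assert (prog & ce).sum() == 12
        result = progression_roi(prog, ce)
        expected = {tuple(v) for v in np.argwhere(prog)} - {
            tuple(v) for v in np.argwhere(ce)
        }
        assert {tuple(v) for v in np.argwhere(result)} == expected
        assert result.sum() == 18

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            progression_roi(np.zeros((4, 4, 4), bool), np.zeros((5, 5, 5), bool))


class TestShells:
    def test_single_voxel_ce_matches_brute_force_distances(self):
        shape = (25, 25, 25)
        ce = np.zeros(shape, bool)
        ce[12, 12, 12] = True
        brain = np.ones(shape, bool)
        prog = np.zeros(shape, bool)
        shells = shell_masks(ce, prog, brain)
        dist = brute_force_distance(ce)
        lo = 0.0
        for hi in (5.0, 10.0):
            expected = (dist > lo) & (dist <= hi)
            assert np.array_equal(shells[hi], expected)
            lo = hi

    def test_band_covered_by_progression_is_empty(self):
        shape = (30, 30, 30)
        ce = sphere(shape, (14.5, 14.5, 14.5), 4.0)
        dist = brute_force_distance(ce)
        prog = (dist > 0) & (dist <= 5.0)
        shells = shell_masks(ce, prog, np.ones(shape, bool))
        assert not shells[5.0].any()
        assert shells[10.0].any()

    def test_default_call_yields_four_labeled_bands(self):
        ce = np.zeros((10, 10, 10), bool)
        ce[5, 5, 5] = True
        shells = shell_masks(ce, np.zeros_like(ce), np.ones_like(ce))
        assert sorted(shells) == [5.0, 10.0, 15.0, 20.0]

    def test_empty_ce_rejected(self):
        with pytest.raises(ValueError):
            shell_masks(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5), bool),
                        np.ones((5, 5, 5), bool))

    def test_anisotropic_spacing_honored(self):
        shape = (9, 9, 9)
        ce = np.zeros(shape, bool)
        ce[4, 4, 4] = True
        spacing = (3.0, 1.0, 1.0)
        shells = shell_masks(ce, np.zeros(shape, bool), np.ones(shape, bool),
                             spacing=spacing)
        dist = brute_force_distance(ce, spacing)
        assert np.array_equal(shells[5.0], (dist > 0) & (dist <= 5.0))

    def test_dilation_monotonicity(self):
        from scipy import ndimage

        shape = (24, 24, 24)
        ce = sphere(shape, (11.5, 11.5, 11.5), 3.0)
        ce_big = ndimage.binary_dilation(ce)
        d_small = brute_force_distance(ce)
        d_big = brute_force_distance(ce_big)
        assert np.all(d_big <= d_small + 1e-12)


class TestNawm:
    def test_symmetric_brain_lateral_lesion_mirror_count(self):
        shape = (40, 40, 40)
        brain = np.ones(shape, bool)
        ce = sphere(shape, (29.5, 19.5, 19.5), 3.0)
        prog = np.zeros(shape, bool)
        nawm = nawm_mask(ce, prog, brain, midline_axis=0, envelope_mm=4.0)
        dist = brute_force_distance(ce)
        region = ce | (dist <= 4.0)
        assert nawm.sum() == region.sum()
        assert not (nawm & ce).any()

    def test_midline_straddling_lesion_by_set_enumeration(self):
        shape = (20, 20, 20)
        brain = np.ones(shape, bool)
        ce = sphere(shape, (9.5, 9.5, 9.5), 2.5)  # straddles the midline
        prog = np.zeros(shape, bool)
        nawm = nawm_mask(ce, prog, brain, midline_axis=0, envelope_mm=2.0)
        dist = brute_force_distance(ce)
        region = ce | (dist <= 2.0)
        mirrored = {
            (shape[0] - 1 - i, j, k) for i, j, k in map(tuple, np.argwhere(region))
        }
        abnormal = {tuple(v) for v in np.argwhere(ce)}
        assert {tuple(v) for v in np.argwhere(nawm)} == mirrored - abnormal

    def test_empty_ce_rejected(self):
        with pytest.raises(ValueError):
            nawm_mask(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5), bool),
                      np.ones((5, 5, 5), bool))

    def test_asymmetric_brain_warns_and_intersects(self):
        shape = (30, 30, 30)
        brain = np.zeros(shape, bool)
        brain[8:] = True  # asymmetric along the midline axis
        ce = sphere(shape, (25.5, 14.5, 14.5), 2.5)
        with pytest.warns(UserWarning, match="outside the brain"):
            nawm = nawm_mask(ce, np.zeros(shape, bool), brain, envelope_mm=2.0)
        assert not (nawm & ~brain).any()


def test_band_partition_property_exhaustive():
    """Bands partition {0 < d <= 20} ∩ brain \\ (CE ∪ progression)."""
    shape = (40, 40, 40)
    brain = sphere(shape, (19.5, 19.5, 19.5), 18.0)
    ce = sphere(shape, (23.5, 19.5, 19.5), 5.0)
    dist = brute_force_distance(ce)
    prog = (dist > 0) & (dist <= 6.0) & sphere(shape, (31.5, 19.5, 19.5), 8.0) & brain
    roi_set = build_roi_set(ce, prog | ce, brain)
    shells = roi_set.shells
    # pairwise disjoint, disjoint from CE and progression
    union = np.zeros(shape, int)
    for m in shells.values():
        union += m
        assert not (m & ce).any() and not (m & roi_set.progression_roi).any()
    assert union.max() <= 1
    expected = (dist > 0) & (dist <= 20.0) & brain & ~ce & ~roi_set.progression_roi
    assert np.array_equal(union.astype(bool), expected)
    labels, legend = roi_label_volume(roi_set)
    assert set(np.unique(labels)) <= {0, 1, 2, 3, 4}
    assert legend["1"] == "band <= 5.0 mm"
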