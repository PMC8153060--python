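"""Unit and property tests for the six-step segmentation pipeline."""

import numpy as np
import pytest
from scipy import ndimage

import clauseg as cs
from clauseg.errors import DegenerateIntensityError, EmptyMaskError
from clauseg.segment import _kmeans_1d_two_class

from helpers_oracles import (
    csf_exclusion_all_pairs,
    edge_by_column_scan,
    gaussian_kernel_1d,
    kmeans2_threshold_scan,
)


def mask(arr, spacing=(1.0, 1.0, 1.0)):
    return cs.BinaryMask(np.asarray(arr, bool), spacing)


class TestLateralEdge:
    def test_single_voxel_is_its_own_edge(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 3, 1] = True
        edge = cs.putamen_lateral_edge(mask(m), cs.RIGHT)
        assert np.array_equal(edge.data, m)

    def test_cube_edge_is_lateral_face(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        edge_r = cs.putamen_lateral_edge(mask(m), cs.RIGHT)
        assert edge_r.count == 9
        assert edge_r.data[4, 2:5, 2:5].all()
        edge_l = cs.putamen_lateral_edge(mask(m), cs.LEFT)
        assert edge_l.data[2, 2:5, 2:5].all()

    @pytest.mark.parametrize("hemi", [cs.LEFT, cs.RIGHT])
    def test_random_blobs_match_column_scan_oracle(self, rng, hemi):
        for _ in range(20):
            m = rng.random((10, 11, 9)) < 0.15
            if not m.any():
                m[0, 0, 0] = True
            edge = cs.putamen_lateral_edge(mask(m), hemi)
            oracle = edge_by_column_scan(m, hemi.lateral_sign)
            assert np.array_equal(edge.data, oracle)
            assert (edge.data & ~m).sum() == 0  # edge subset of putamen

    def test_empty_putamen_rejected(self):
        with pytest.raises(EmptyMaskError):
            cs.putamen_lateral_edge(mask(np.zeros((3, 3, 3))), cs.RIGHT)


class TestExpandLateral:
    def test_offsets_follow_rounding_rule(self):
        """5 mm at 0.7 mm spacing expands by round(5/0.7) = 7 voxels."""
        m = np.zeros((20, 5, 5), bool)
        m[10, 2, 2] = True
        roi = cs.expand_lateral(mask(m, (0.7, 0.7, 0.7)), cs.RIGHT, 5.0)
        expected = np.zeros_like(m)
        expected[11:18, 2, 2] = True
        assert np.array_equal(roi.data, expected)

    def test_left_hemisphere_expands_medially_to_laterally(self):
        m = np.zeros((20, 5, 5), bool)
        m[10, 2, 2] = True
        roi = cs.expand_lateral(mask(m, (0.7, 0.7, 0.7)), cs.LEFT, 5.0)
        assert roi.data[3:10, 2, 2].all() and roi.count == 7

    def test_truncated_at_grid_boundary(self):
        m = np.zeros((5, 3, 3), bool)
        m[3, 1, 1] = True
        roi = cs.expand_lateral(mask(m), cs.RIGHT, 5.0)
        assert roi.count == 1 and roi.data[4, 1, 1]

    def test_face_becomes_slab(self):
        m = np.zeros((20, 7, 7), bool)
        m[5, 2:5, 2:5] = True
        roi = cs.expand_lateral(mask(m, (0.7, 0.7, 0.7)), cs.RIGHT, 5.0)
        assert roi.count == 9 * 7
        assert roi.data[6:13, 2:5, 2:5].all()

    def test_excludes_the_edge_itself(self):
        m = np.zeros((20, 5, 5), bool)
        m[10, 2, 2] = True
        roi = cs.expand_lateral(mask(m), cs.RIGHT, 3.0)
        assert not roi.data[10, 2, 2]

    def test_minimum_one_voxel(self):
        m = np.zeros((5, 3, 3), bool)
        m[1, 1, 1] = True
        roi = cs.expand_lateral(mask(m, (10.0, 10.0, 10.0)), cs.RIGHT, 0.5)
        assert roi.count == 1 and roi.data[2, 1, 1]


class TestExcludeNearCSF:
    def test_inclusive_distance_rule_on_plane(self):
        """Distance exactly 5 is removed, 6 is kept."""
        csf = np.zeros((30, 5, 5), bool)
        csf[20, :, :] = True
        roi = np.zeros_like(csf)
        roi[25, 2, 2] = roi[26, 2, 2] = True
        kept = cs.exclude_near_csf(mask(roi), mask(csf), 5.0)
        assert not kept.data[25, 2, 2]
        assert kept.data[26, 2, 2]

    def test_random_grids_match_all_pairs_oracle(self, rng):
        for _ in range(20):
            roi = rng.random((9, 9, 9)) < 0.3
            csf = rng.random((9, 9, 9)) < 0.1
            kept = cs.exclude_near_csf(mask(roi), mask(csf), 2.5)
            oracle = csf_exclusion_all_pairs(roi, csf, 2.5)
            assert np.array_equal(kept.data, oracle)

    def test_empty_csf_returns_roi_unchanged(self, rng):
        roi = mask(rng.random((6, 6, 6)) < 0.4)
        kept = cs.exclude_near_csf(roi, mask(np.zeros((6, 6, 6))), 5.0)
        assert np.array_equal(kept.data, roi.data)

    def test_result_is_subset_of_roi(self, rng):
        roi = rng.random((8, 8, 8)) < 0.5
        csf = rng.random((8, 8, 8)) < 0.05
        kept = cs.exclude_near_csf(mask(roi), mask(csf), 1.5)
        assert not (kept.data & ~roi).any()


class TestClusterT1w:
    @staticmethod
    def _roi_and_volume(values):
        n = len(values)
        roi = np.zeros((n, 1, 1), bool)
        roi[:, 0, 0] = True
        vol = np.zeros((n, 1, 1))
        vol[:, 0, 0] = values
        return mask(roi), cs.ScalarVolume(vol, (1, 1, 1))

    def test_perfectly_separated_values(self):
        roi, vol = self._roi_and_volume([1, 1, 1, 10, 10, 10])
        lower, report = cs.cluster_t1w(roi, vol)
        assert np.array_equal(np.nonzero(lower.data)[0], [0, 1, 2])
        assert report.centroid_lower == pytest.approx(1.0)
        assert report.centroid_upper == pytest.approx(10.0)

    def test_matches_exhaustive_threshold_oracle(self, rng):
        """Two-component draws: partition equals the global SSE optimum."""
        for _ in range(25):
            n_lo = int(rng.integers(20, 180))
            vals = np.concatenate([
                rng.normal(70, 5, n_lo), rng.normal(110, 5, 200 - n_lo)
            ])
            rng.shuffle(vals)
            lower_impl, c_lo, c_hi, _ = _kmeans_1d_two_class(vals)
            lower_orc, o_lo, o_hi = kmeans2_threshold_scan(vals)
            assert np.array_equal(lower_impl, lower_orc)
            assert c_lo == pytest.approx(o_lo) and c_hi == pytest.approx(o_hi)

    def test_lower_centroid_below_upper(self, rng):
        vals = rng.random(300) * 50
        _, c_lo, c_hi, _ = _kmeans_1d_two_class(vals)
        assert c_lo < c_hi

    def test_constant_intensities_rejected(self):
        roi, vol = self._roi_and_volume([7.0] * 10)
        with pytest.raises(DegenerateIntensityError, match="degenerate"):
            cs.cluster_t1w(roi, vol)

    def test_empty_roi_rejected(self):
        roi, vol = self._roi_and_volume([1.0, 2.0])
        empty = mask(np.zeros_like(roi.data))
        with pytest.raises(EmptyMaskError):
            cs.cluster_t1w(empty, vol)

    def test_nonfinite_roi_rejected(self):
        roi, vol = self._roi_and_volume([1.0, np.nan, 3.0])
        with pytest.raises(DegenerateIntensityError):
            cs.cluster_t1w(roi, vol)


class TestSagittalSmoothing:
    def test_solid_slab_interior_unchanged(self):
        m = np.zeros((5, 20, 20), bool)
        m[2, 4:16, 4:16] = True
        sm = cs.smooth_in_sagittal_plane(mask(m))
        assert sm.data[2, 8:12, 8:12].all()

    def test_isolated_voxel_removed(self):
        """Central response of a lone voxel is w0^2 ~ 0.16 < 0.25."""
        w = gaussian_kernel_1d(1.0)
        assert w.max() ** 2 < 0.25  # the derivation the default relies on
        m = np.zeros((5, 15, 15), bool)
        m[2, 7, 7] = True
        assert cs.smooth_in_sagittal_plane(mask(m)).is_empty()

    def test_thin_line_preserved(self):
        """A 1-voxel line sums the 1-D kernel along itself: ~0.40 >= 0.25."""
        w = gaussian_kernel_1d(1.0)
        assert w.max() >= 0.25
        m = np.zeros((5, 31, 15), bool)
        m[2, :, 7] = True
        sm = cs.smooth_in_sagittal_plane(mask(m))
        assert sm.data[2, 10:21, 7].all()

    def test_slices_are_independent(self, rng):
        """No leakage across the left-right axis."""
        m = rng.random((6, 12, 12)) < 0.3
        sm_full = cs.smooth_in_sagittal_plane(mask(m))
        for i in range(6):
            one = np.zeros_like(m)
            one[i] = m[i]
            sm_one = cs.smooth_in_sagittal_plane(mask(one))
            assert np.array_equal(sm_full.data[i], sm_one.data[i])


class TestFullPipeline:
    def test_subset_chain_and_disjointness(self, bundle, segmented):
        final, report = segmented
        params = cs.SegmentationParams()
        edge = cs.putamen_lateral_edge(bundle.putamen, cs.RIGHT)
        roi = cs.expand_lateral(edge, cs.RIGHT, params.expansion_mm)
        roi_csf = cs.exclude_near_csf(roi, bundle.csf, params.csf_margin_voxels)
        assert not (roi_csf.data & ~roi.data).any()
        assert not (final.data & ~roi_csf.data).any()
        assert not (final.data & bundle.putamen.data).any()
        dist = ndimage.distance_transform_edt(~bundle.csf.data)
        assert dist[final.data].min() > params.csf_margin_voxels

    def test_report_counts_consistent(self, segmented):
        _, report = segmented
        assert report.n_roi_expanded >= report.n_roi_after_csf >= report.n_cluster
        assert report.n_final <= report.n_roi_after_csf
        assert report.centroid_lower < report.centroid_upper

    def test_recovers_phantom_truth(self, bundle, segmented):
        final, _ = segmented
        assert cs.dice(final, bundle.truth_claustrum) >= 0.7

    def test_deterministic(self, bundle, segmented):
        final, _ = segmented
        again, _ = cs.segment_claustrum(
            bundle.t1w, bundle.putamen, bundle.csf, cs.RIGHT
        )
        assert np.array_equal(final.data, again.data)

    def test_mirror_symmetry_exact(self, bundle, segmented):
        final, _ = segmented
        flip = lambda m: np.flip(m, axis=0).copy()
        mirrored, _ = cs.segment_claustrum(
            cs.ScalarVolume(flip(bundle.t1w.data), bundle.t1w.spacing),
            cs.BinaryMask(flip(bundle.putamen.data), bundle.putamen.spacing),
            cs.BinaryMask(flip(bundle.csf.data), bundle.csf.spacing),
            cs.LEFT,
        )
        assert np.array_equal(mirrored.data, flip(final.data))

    def test_no_sheet_ablation_yields_almost_nothing(self, bundle):
        """Without a claustrum the unimodal ROI must not produce one."""
        ablated = cs.generate_phantom(
            cs.PhantomSpec(seed=1, sheet_thickness_voxels=(0, 0))
        )
        assert ablated.truth_claustrum.is_empty()
        final, report = cs.segment_claustrum(
            ablated.t1w, ablated.putamen, ablated.csf, cs.RIGHT
        )
        assert report.centroid_lower < report.centroid_upper  # split still happened
        assert final.count < 0.1 * bundle.truth_claustrum.count

    def test_empty_putamen_rejected(self, bundle):
        empty = cs.BinaryMask(
            np.zeros_like(bundle.putamen.data), bundle.putamen.spacing
        )
        with pytest.raises(EmptyMaskError):
            cs.segment_claustrum(bundle.t1w, empty, bundle.csf, cs.RIGHT)


class TestBilateralSplit:
    def test_components_assigned_by_centroid(self, small_bundle):
        bilateral = cs.compose_bilateral(small_bundle)
        sides = cs.split_bilateral_putamen(bilateral.putamen)
        assert set(sides) == {"left", "right"}
        mid = (bilateral.putamen.shape[0] - 1) / 2
        assert np.nonzero(sides["left"].data)[0].max() < mid
        assert np.nonzero(sides["right"].data)[0].min() > mid

    def test_params_validation(self):
        with pytest.raises(ValueError):
            cs.SegmentationParams(expansion_mm=0)
        with pytest.raises(ValueError):
            cs.SegmentationParams(k=3)
        with pytest.raises(ValueError):
            cs.SegmentationParams(smooth_threshold=1.5)
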