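"""Vertical-center measurement: segmentation, midpoints, distances, pad estimate."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctcenter import (
    CTVolume,
    binarize,
    body_metrics,
    distance_ratio,
    grand_center,
    isocenter_distance,
    measure,
    pad_thickness_estimate,
    render_volume,
    slice_center,
)
from conftest import PITCH, make_box_volume, make_patient


class TestBinarize:
    def test_pure_air_volume_all_slices_empty(self):
        vol = make_box_volume()
        mask = binarize(vol, threshold=-250.0)
        assert mask.empty_slices.all()
        with pytest.raises(ValueError, match="empty"):
            measure(vol)

    def test_rendered_ellipse_matches_analytic_membership(self, noise_free_spec):
        p = make_patient(scan_length=20.0)
        vol = render_volume(p, spec=noise_free_spec)
        mask = binarize(vol, threshold=-250.0)
        got = mask.mask[0]
        # analytic: compare against HU>=threshold membership minus pad/aorta;
        # body and aorta are the only tissues above -250
        expected = vol.hu[0] >= -250.0
        assert np.array_equal(got, expected)

    def test_pad_voxels_below_threshold_excluded(self, noise_free_spec):
        p = make_patient(scan_length=20.0)
        vol = render_volume(p, spec=noise_free_spec)
        mask = binarize(vol, threshold=-250.0)
        assert not mask.mask[vol.hu == -900.0].any()

    def test_bottom_border_component_discarded(self):
        vol = make_box_volume(n_slices=1, body_rows=(10, 20), body_cols=(10, 20))
        # add a larger table-like component touching the bottom border
        vol.hu[0, 55:64, :] = 100.0
        mask = binarize(vol, threshold=-250.0)
        rows = np.flatnonzero(mask.mask[0].any(axis=1))
        assert rows.min() == 10 and rows.max() == 20


class TestSliceAndGrandCenter:
    def test_contiguous_rows_midpoint(self):
        s = np.zeros((300, 40), dtype=bool)
        s[100:200] = True  # rows 100..199
        assert slice_center(s) == 149.5

    def test_single_row(self):
        s = np.zeros((300, 40), dtype=bool)
        s[255, 3] = True
        assert slice_center(s) == 255.0

    def test_empty_slice_is_nan(self):
        assert np.isnan(slice_center(np.zeros((8, 8), dtype=bool)))

    @given(st.integers(0, 290), st.integers(0, 290))
    def test_midpoint_between_extremes(self, a, b):
        lo, hi = min(a, b), max(a, b)
        s = np.zeros((300, 4), dtype=bool)
        s[lo, 0] = True
        s[hi, 2] = True
        assert slice_center(s) == (lo + hi) / 2.0

    def test_grand_center_mean(self):
        assert grand_center([250.0, 252.0, 254.0]) == 252.0

    def test_grand_center_single_slice(self):
        assert grand_center([241.5]) == 241.5

    def test_grand_center_excludes_empty(self):
        assert grand_center([250.0, float("nan"), 254.0]) == 252.0

    def test_grand_center_all_empty_raises(self):
        with pytest.raises(ValueError):
            grand_center([float("nan")] * 3)


class TestIsocenterDistance:
    def test_coincident_centers(self):
        vol = make_box_volume(rows=512, cols=512)
        assert isocenter_distance(vol.isocenter_rc[0], vol) == 0.0

    def test_known_pixel_offset(self):
        """14.464 px below the isocenter at 354/512 mm/px is -10.0 mm."""
        vol = CTVolume(hu=np.zeros((1, 512, 512), dtype=np.float32), dfov=354.0)
        d = isocenter_distance(vol.isocenter_rc[0] + 14.464, vol)
        assert d == pytest.approx(-10.0, abs=1e-3)

    def test_manual_group_mean_offset_recovered(self, noise_free_spec):
        p = make_patient(offset=-8.3)
        d = measure(render_volume(p, spec=noise_free_spec)).isocenter_distance
        assert d == pytest.approx(-8.3, abs=0.70)

    def test_translation_equivariance_row_shift(self, noise_free_spec):
        """Shifting content up k rows changes d by exactly +k*pitch."""
        p = make_patient(offset=0.0, scan_length=30.0)
        vol = render_volume(p, spec=noise_free_spec)
        d0 = measure(vol).isocenter_distance
        for k in (3, 17):
            shifted = CTVolume(
                hu=np.roll(vol.hu, -k, axis=1),
                dfov=vol.dfov,
                slice_spacing=vol.slice_spacing,
            )
            dk = measure(shifted).isocenter_distance
            assert dk - d0 == pytest.approx(k * PITCH, abs=1e-6)

    def test_distance_independent_of_noise(self):
        from ctcenter import CohortSpec

        p = make_patient(offset=-6.0, scan_length=40.0)
        d_clean = measure(
            render_volume(p, spec=CohortSpec(noise_sd=0.0))
        ).isocenter_distance
        d_noisy = measure(
            render_volume(p, spec=CohortSpec(noise_sd=10.0, seed=4))
        ).isocenter_distance
        assert abs(d_noisy - d_clean) < PITCH


class TestBodyMetrics:
    def test_constant_slab_thickness(self):
        vol = make_box_volume(
            n_slices=4, rows=512, cols=512, body_rows=(100, 249), body_cols=(50, 100)
        )
        mask = binarize(vol)
        t, w = body_metrics(mask, vol)
        assert t == pytest.approx(150 * PITCH)  # 103.7 mm
        assert w == pytest.approx(51 * PITCH)

    def test_rendered_ellipse_extents(self, noise_free_spec):
        p = make_patient(chest=104.0, width=152.0, scan_length=20.0)
        vol = render_volume(p, spec=noise_free_spec)
        mask = binarize(vol)
        t, w = body_metrics(mask, vol)
        ap_mean = vol.meta["mean_ap_diameter"]
        assert t == pytest.approx(ap_mean, abs=PITCH)
        assert w == pytest.approx(152.0, abs=PITCH)

    def test_single_voxel_body(self):
        vol = make_box_volume(n_slices=1, body_rows=(30, 30), body_cols=(30, 30))
        mask = binarize(vol)
        t, w = body_metrics(mask, vol)
        assert t == pytest.approx(PITCH)
        assert w == pytest.approx(PITCH)


class TestRatiosAndPad:
    def test_distance_ratio_zero(self):
        assert distance_ratio(0.0, 104.0) == 0.0

    def test_distance_ratio_reported_means(self):
        assert distance_ratio(-8.3, 104.0) == pytest.approx(-7.98, abs=0.01)
        assert distance_ratio(-8.3, 104.0, absolute=True) == pytest.approx(7.98, abs=0.01)

    def test_distance_ratio_scale(self):
        assert distance_ratio(104.0, 104.0) == pytest.approx(100.0)

    def test_distance_ratio_zero_thickness_error(self):
        with pytest.raises(ValueError):
            distance_ratio(5.0, 0.0)

    def test_pad_estimate_algebraic_identity(self):
        """Table 129.35 mm, d -7.0 mm, T 101.5 mm -> 71.6 mm pad."""
        assert pad_thickness_estimate(129.35, -7.0, 101.5) == pytest.approx(71.6)

    def test_pad_estimate_zero_thickness_limit(self):
        assert pad_thickness_estimate(75.0, 0.0, 0.0) == 75.0

    def test_pad_estimate_nonpositive_warns(self):
        with pytest.warns(UserWarning):
            pad_thickness_estimate(10.0, -5.0, 100.0)

    def test_rendered_pad_recovered(self, noise_free_spec):
        """End-to-end: the estimate returns the rendered pad within a pixel."""
        p = make_patient(pad_nominal=75.0, pad_dent=3.4, offset=-7.0)
        vol = render_volume(p, spec=noise_free_spec)
        res = measure(vol)
        assert res.pad_thickness_estimate == pytest.approx(71.6, abs=PITCH)

    def test_offset_flag_and_abs(self, noise_free_spec):
        p = make_patient(offset=-25.0)
        res = measure(render_volume(p, spec=noise_free_spec))
        assert res.offset_gt_20
        assert res.abs_distance == pytest.approx(abs(res.isocenter_distance))

    def test_missing_table_height_disables_pad_estimate(self, noise_free_spec):
        p = make_patient()
        vol = render_volume(p, spec=noise_free_spec)
        vol.table_height = None
        assert measure(vol).pad_thickness_estimate is None
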