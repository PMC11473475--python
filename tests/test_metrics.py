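"""ROI statistics, CNR, plug localization and linearity QC.

The disk/ring statistics are checked against a naive per-pixel loop oracle
for exact agreement, and the CNR against its affine-invariance property.
"""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cemqa import (
    ROIConfig,
    ROIStatistics,
    cnr,
    locate_plugs,
    measure_study,
    residual_cnr,
    roi_stats,
    signal_difference_linearity,
    simulate_acquisition,
)
from cemqa.errors import (
    DegenerateNoiseError,
    InsufficientDataError,
    LocalizationWarning,
    MeasurementError,
)
from cemqa.metrics import CNRMeasurement
from cemqa.phantom import FrameMap
from cemqa.recombine import RecombinationParams, estimate_weight, recombine


def brute_force_roi_stats(image, center_px, roi_r, ring_in, ring_out, frame):
    """Independent per-pixel loop implementation of the disk/ring statistics."""
    sr, sc = frame.pixel_spacing_mm
    disk_vals, ring_vals = [], []
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            d = np.hypot((r - center_px[0]) * sr, (c - center_px[1]) * sc)
            if d <= roi_r:
                disk_vals.append(image[r, c])
            if ring_in <= d <= ring_out:
                ring_vals.append(image[r, c])
    return (
        float(np.mean(disk_vals)),
        float(np.mean(ring_vals)),
        float(np.std(ring_vals)),
        len(disk_vals),
        len(ring_vals),
    )


SMALL_FRAME = FrameMap(pixel_spacing_mm=(0.25, 0.25), shape=(64, 64))


class TestROIStats:
    def test_constant_image(self):
        img = np.full((64, 64), 7.5)
        st_ = roi_stats(img, (32, 32), 2.0, 3.0, 5.0, SMALL_FRAME, min_n_bkg=50)
        assert st_.mpv_target == st_.mpv_bkg == 7.5
        assert st_.sd_bkg == 0.0
        with pytest.raises(DegenerateNoiseError):
            cnr(st_)

    def test_piecewise_constant_disk(self):
        img = np.full((64, 64), 100.0)
        sr = SMALL_FRAME.pixel_spacing_mm[0]
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img[np.hypot((rr - 32) * sr, (cc - 32) * sr) <= 2.5] = 90.0
        st_ = roi_stats(img, (32, 32), 1.5, 3.0, 5.0, SMALL_FRAME, min_n_bkg=50)
        assert st_.mpv_target == 90.0
        assert st_.mpv_bkg == 100.0

    def test_checkerboard_ring_matches_oracle(self):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img = 2.0 * ((rr + cc) % 2)
        st_ = roi_stats(img, (32, 32), 2.0, 3.0, 5.0, SMALL_FRAME, min_n_bkg=50)
        mt, mb, sb, nt, nb = brute_force_roi_stats(img, (32, 32), 2.0, 3.0, 5.0, SMALL_FRAME)
        assert (st_.mpv_target, st_.mpv_bkg, st_.sd_bkg) == (mt, mb, sb)
        assert st_.mpv_bkg == pytest.approx(1.0, abs=0.05)
        assert st_.sd_bkg == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_brute_force_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1000, size=(64, 64))
        center = (32 + rng.uniform(-2, 2), 32 + rng.uniform(-2, 2))
        st_ = roi_stats(img, center, 2.0, 3.0, 5.0, SMALL_FRAME, min_n_bkg=50)
        mt, mb, sb, nt, nb = brute_force_roi_stats(img, center, 2.0, 3.0, 5.0, SMALL_FRAME)
        assert (st_.mpv_target, st_.mpv_bkg, st_.sd_bkg) == (mt, mb, sb)
        assert (st_.n_target, st_.n_bkg) == (nt, nb)

    def test_clipped_geometry_rejected(self):
        img = np.zeros((64, 64))
        with pytest.raises(MeasurementError):
            roi_stats(img, (3, 3), 2.0, 3.0, 5.0, SMALL_FRAME)

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            roi_stats(np.zeros((64, 64)), (32, 32), 5.0, 3.0, 2.0, SMALL_FRAME)


class TestCNR:
    def test_direct_formula(self):
        assert cnr(ROIStatistics(80.0, 100.0, 5.0, 100, 400)) == 4.0

    def test_zero_contrast(self):
        assert cnr(ROIStatistics(100.0, 100.0, 5.0, 100, 400)) == 0.0

    def test_sign_symmetry(self):
        assert cnr(ROIStatistics(120.0, 100.0, 10.0, 100, 400)) == 2.0

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**16),
        a=st.floats(0.01, 100.0),
        b=st.floats(-1000.0, 1000.0),
    )
    def test_affine_intensity_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        img = rng.normal(500, 30, size=(64, 64))
        st1 = roi_stats(img, (32, 32), 2.0, 3.0, 5.0, SMALL_FRAME, min_n_bkg=50)
        st2 = roi_stats(a * img + b, (32, 32), 2.0, 3.0, 5.0, SMALL_FRAME, min_n_bkg=50)
        assert cnr(st2) == pytest.approx(cnr(st1), rel=1e-9)


class TestLocatePlugs:
    def test_noiseless_centers_within_half_pixel_of_truth(self, spec, frame, noiseless_study):
        located = locate_plugs(noiseless_study.le_image, spec, frame, plugs=spec.iodine_plugs)
        for plug in spec.iodine_plugs:
            truth = noiseless_study.truth[plug.id].center_px
            got = located[plug.id].center_px
            assert located[plug.id].refined
            assert np.hypot(got[0] - truth[0], got[1] - truth[1]) <= 0.5

    def test_invisible_plugs_fall_back_to_nominal_with_warning(
        self, spec, frame, ge_profile_noiseless
    ):
        prof = replace(ge_profile_noiseless, alpha_le=0.0)
        study = simulate_acquisition(spec, prof, frame, seed=0)
        with pytest.warns(LocalizationWarning):
            located = locate_plugs(study.le_image, spec, frame, plugs=spec.iodine_plugs)
        for plug in spec.iodine_plugs:
            assert not located[plug.id].refined
            assert located[plug.id].center_px == frame.mm_to_px(plug.center_mm)

    def test_translated_frame_gives_identical_mm_centers(
        self, spec, frame, noiseless_study, ge_profile_noiseless
    ):
        """Shifting the whole image with a matching origin update must not move
        the refined centers in phantom coordinates."""
        shifted = FrameMap(
            pixel_spacing_mm=frame.pixel_spacing_mm,
            origin_mm=(-1.0, -1.0),
            shape=(frame.shape[0] + 10, frame.shape[1] + 10),
        )
        study2 = simulate_acquisition(spec, ge_profile_noiseless, shifted, seed=0)
        loc1 = locate_plugs(noiseless_study.le_image, spec, frame, plugs=spec.iodine_plugs)
        loc2 = locate_plugs(study2.le_image, spec, shifted, plugs=spec.iodine_plugs)
        for plug in spec.iodine_plugs:
            mm1 = frame.px_to_mm(loc1[plug.id].center_px)
            mm2 = shifted.px_to_mm(loc2[plug.id].center_px)
            assert mm1 == pytest.approx(mm2, abs=1e-9)


class TestMeasureStudy:
    def test_record_count_with_and_without_des(self, spec, frame, ge_study):
        params = estimate_weight(ge_study.le_image, ge_study.he_image, spec, frame)
        des = recombine(ge_study.le_image, ge_study.he_image, params)
        full = measure_study(
            {"LE": ge_study.le_image, "HE": ge_study.he_image, "DES": des.image}, spec, frame
        )
        assert len(full) == 26
        assert sum(m.residual_flag for m in full) == 2
        raw_only = measure_study({"LE": ge_study.le_image, "HE": ge_study.he_image}, spec, frame)
        assert len(raw_only) == 16
        assert not any(m.residual_flag for m in raw_only)

    def test_iodine_plugs_measured_on_all_kinds(self, spec, frame, ge_study):
        meas = measure_study({"LE": ge_study.le_image, "HE": ge_study.he_image}, spec, frame)
        kinds = {(m.plug_id, m.image_kind) for m in meas}
        for plug in spec.iodine_plugs:
            assert (plug.id, "LE") in kinds and (plug.id, "HE") in kinds


class TestResidualCNR:
    def test_perfect_cancellation_noiseless(self, spec, frame, noiseless_study):
        params = estimate_weight(noiseless_study.le_image, noiseless_study.he_image, spec, frame)
        des = recombine(noiseless_study.le_image, noiseless_study.he_image, params)
        for m in residual_cnr(des, spec, frame):
            assert abs(m.stats.mpv_bkg - m.stats.mpv_target) < 1e-9

    def test_weight_zero_recovers_he_log_cnr(self, spec, frame, ge_study, ge_profile):
        """DES = ln(HE) carries the glandular plug's HE contrast in log units."""
        des = recombine(ge_study.le_image, ge_study.he_image, RecombinationParams(0.0))
        for m in residual_cnr(des, spec, frame):
            t = ge_study.truth[m.plug_id]
            expected = abs(np.log(ge_profile.gland_plug_step("HE"))) / (
                t.sd_bkg["HE"] / t.mean_bkg["HE"]
            )
            assert m.cnr == pytest.approx(expected, rel=0.10)


class TestLinearity:
    @staticmethod
    def _meas(points, half="adipose"):
        return [
            CNRMeasurement(
                plug_id=f"p{i}",
                image_kind="DES",
                half=half,
                iodine_density=x,
                cnr=1.0,
                stats=ROIStatistics(mpv_target=y, mpv_bkg=0.0, sd_bkg=1.0, n_target=50, n_bkg=200),
            )
            for i, (x, y) in enumerate(points)
        ]

    def test_exact_line(self):
        res = signal_difference_linearity(
            self._meas([(0.2, 1.0), (0.5, 2.5), (1.0, 5.0), (2.0, 10.0)]), "adipose"
        )
        assert res.slope == pytest.approx(5.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_response(self):
        res = signal_difference_linearity(
            self._meas([(0.2, 3.0), (0.5, 3.0), (1.0, 3.0), (2.0, 3.0)]), "adipose"
        )
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            signal_difference_linearity(self._meas([(0.2, 1.0), (0.5, 2.0)]), "adipose")

    def test_small_attenuation_regime_is_linear(self, spec, frame, ge_profile_noiseless):
        """For alpha*sigma << 1 the exponential response is linear to R^2 > 0.99."""
        prof = replace(ge_profile_noiseless, alpha_le=0.02, alpha_he=0.01)
        study = simulate_acquisition(spec, prof, frame, seed=0)
        params = estimate_weight(study.le_image, study.he_image, spec, frame)
        des = recombine(study.le_image, study.he_image, params)
        meas = measure_study(
            {"LE": study.le_image, "HE": study.he_image, "DES": des.image}, spec, frame
        )
        for half in ("adipose", "glandular"):
            res = signal_difference_linearity(meas, half)
            assert res.r_squared > 0.99
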