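"""Exposure parsing and Dance-model MGD: K * g * c * s with gridded factors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cemqa import (
    BeamQualityConfig,
    DoseFactorTable,
    ExposureRecord,
    check_dose_limit,
    compute_mgd,
    he_dose_fraction,
    parse_exposure,
    total_mgd,
)
from cemqa.dosimetry import serialize_exposure
from cemqa.errors import ExposureParseError, FactorRangeError


@pytest.fixture(scope="module")
def factors():
    return DoseFactorTable.bundled()


@pytest.fixture
def beam():
    return BeamQualityConfig(hvl_mm_al=0.52, tube_output_ugy_per_mas=78.0)


LE_RECORD = ExposureRecord("Rh", "Ag", 34.0, 45.0, "LE", 55.0, aec_mode="AOP/STD")


class TestParseExposure:
    def test_ge_le_image_tags(self):
        rec = parse_exposure(
            {
                "KVP": 34,
                "Exposure": 45,
                "AnodeTargetMaterial": "Rh",
                "FilterMaterial": "Ag",
                "BodyPartThickness": 55,
            }
        )
        assert rec.energy_kind == "LE"
        assert (rec.anode, rec.filter_material) == ("Rh", "Ag")
        assert rec.tube_voltage_kvp == 34.0
        assert rec.exposure_mas == 45.0

    def test_titanium_filter_classified_high_energy(self):
        rec = parse_exposure(
            {
                "KVP": 49,
                "Exposure": 42.3,
                "AnodeTargetMaterial": "TUNGSTEN",
                "FilterMaterial": "Ti",
                "BodyPartThickness": 55,
            }
        )
        assert rec.energy_kind == "HE"
        assert rec.anode == "W"

    def test_dose_level_percentage_extracted(self):
        rec = parse_exposure(
            {
                "KVP": 29,
                "Exposure": 138.6,
                "AnodeTargetMaterial": "W",
                "FilterMaterial": "Rh",
                "BodyPartThickness": 55,
                "ExposureControlModeDescription": "OPDOSE CEM 80% TABLE",
            }
        )
        assert rec.aec_mode == "dose level 80%"

    def test_exposure_in_uas_fallback(self):
        rec = parse_exposure(
            {
                "KVP": 30,
                "ExposureInuAs": 156600,
                "AnodeTargetMaterial": "W",
                "FilterMaterial": "Ag",
                "BodyPartThickness": 55,
            }
        )
        assert rec.exposure_mas == pytest.approx(156.6)

    def test_missing_mandatory_tag_named_in_error(self):
        with pytest.raises(ExposureParseError, match="KVP"):
            parse_exposure(
                {"Exposure": 45, "AnodeTargetMaterial": "Rh", "FilterMaterial": "Ag",
                 "BodyPartThickness": 55}
            )

    @pytest.mark.parametrize(
        "record",
        [
            LE_RECORD,
            ExposureRecord("W", "Ti", 49.0, 31.7, "HE", 55.0, aec_mode="dose level 80%"),
            ExposureRecord("W", "Cu", 49.0, 97.6, "HE", 55.0, filter_thickness_um=300.0),
        ],
    )
    def test_serialize_parse_roundtrip(self, record):
        assert parse_exposure(serialize_exposure(record)) == record

    def test_unknown_anode_rejected(self):
        with pytest.raises(ExposureParseError):
            ExposureRecord("Pb", "Ag", 34.0, 45.0, "LE")


def brute_force_bilinear(axes, values, point):
    """Independent bilinear interpolation oracle on a 2-D grid."""
    (ax0, ax1) = axes
    i = np.clip(np.searchsorted(ax0, point[0]) - 1, 0, len(ax0) - 2)
    j = np.clip(np.searchsorted(ax1, point[1]) - 1, 0, len(ax1) - 2)
    tx = (point[0] - ax0[i]) / (ax0[i + 1] - ax0[i])
    ty = (point[1] - ax1[j]) / (ax1[j + 1] - ax1[j])
    return (
        values[i, j] * (1 - tx) * (1 - ty)
        + values[i + 1, j] * tx * (1 - ty)
        + values[i, j + 1] * (1 - tx) * ty
        + values[i + 1, j + 1] * tx * ty
    )


class TestFactorTable:
    def test_grid_node_identity(self, factors):
        ax_h, ax_t = factors._g_axes
        for i in (0, len(ax_h) // 2, -1):
            for j in (0, len(ax_t) // 2, -1):
                g, flags = factors.g(ax_h[i], ax_t[j])
                assert g == pytest.approx(factors._g_values[i, j], rel=1e-15)
                assert flags == []

    def test_midgrid_matches_brute_force_oracle(self, factors):
        rng = np.random.default_rng(12345)
        ax_h, ax_t = factors._g_axes
        for _ in range(1000):
            h = rng.uniform(ax_h[0], ax_h[-1])
            t = rng.uniform(ax_t[0], ax_t[-1])
            g, _ = factors.g(h, t)
            assert g == pytest.approx(
                brute_force_bilinear(factors._g_axes, factors._g_values, (h, t)), rel=1e-12
            )

    def test_g_monotone_in_hvl_and_thickness(self, factors):
        vals = factors._g_values
        assert np.all(np.diff(vals, axis=0) > 0)  # increasing with HVL
        assert np.all(np.diff(vals, axis=1) < 0)  # decreasing with thickness

    def test_c_is_unity_at_reference_glandularity(self, factors):
        c, flags = factors.c(0.52, 55.0, 0.5)
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_extrapolation_flagged_within_one_step(self, factors):
        ax_h, _ = factors._g_axes
        step = ax_h[1] - ax_h[0]
        _, flags = factors.g(ax_h[0] - 0.5 * step, 55.0)
        assert flags
        with pytest.raises(FactorRangeError):
            factors.g(ax_h[0] - 2.0 * step, 55.0)

    def test_missing_spectrum_combination_rejected(self, factors):
        with pytest.raises(FactorRangeError):
            factors.s("Mo", "Ti")


class TestComputeMGD:
    def test_result_invariant_k_g_c_s(self, factors, beam):
        res = compute_mgd(LE_RECORD, beam, factors)
        g, c, s = res.factors_used
        assert res.mgd_mgy == pytest.approx(res.incident_air_kerma_mgy * g * c * s, rel=1e-12)
        assert res.interpolation_flags == ()

    def test_linear_in_mas(self, factors, beam):
        from dataclasses import replace

        res1 = compute_mgd(LE_RECORD, beam, factors)
        res2 = compute_mgd(replace(LE_RECORD, exposure_mas=90.0), beam, factors)
        assert res2.mgd_mgy == pytest.approx(2.0 * res1.mgd_mgy, rel=1e-12)

    def test_increasing_in_tube_output(self, factors, beam):
        res1 = compute_mgd(LE_RECORD, beam, factors)
        brighter = BeamQualityConfig(beam.hvl_mm_al, beam.tube_output_ugy_per_mas * 1.3)
        res2 = compute_mgd(LE_RECORD, brighter, factors)
        assert res2.mgd_mgy == pytest.approx(1.3 * res1.mgd_mgy, rel=1e-12)

    def test_inverse_square_raises_kerma_at_surface(self, factors):
        near = BeamQualityConfig(0.52, 78.0, source_to_support_mm=600.0)
        far = BeamQualityConfig(0.52, 78.0, source_to_support_mm=700.0)
        assert (
            compute_mgd(LE_RECORD, near, factors).incident_air_kerma_mgy
            > compute_mgd(LE_RECORD, far, factors).incident_air_kerma_mgy
        )


class TestDoseSummaries:
    @pytest.mark.parametrize(
        "le, he, expected",
        [(1.64, 0.70, 2.34), (2.66, 0.84, 3.50), (1.23, 0.0, 1.23)],
    )
    def test_total_is_plain_sum(self, le, he, expected):
        assert total_mgd(le, he) == pytest.approx(expected, abs=1e-12)

    def test_he_fraction(self):
        assert he_dose_fraction(2.0, 2.0) == 100.0
        assert he_dose_fraction(2.0, 0.5) == 25.0
        # from the rounded per-image table values; source prints 42.8 from unrounded data
        assert round(he_dose_fraction(1.64, 0.70), 1) == 42.7

    def test_he_fraction_zero_le_rejected(self):
        with pytest.raises(ZeroDivisionError):
            he_dose_fraction(0.0, 0.5)

    def test_dose_limit_boundary_inclusive(self):
        assert check_dose_limit(2.34)
        assert not check_dose_limit(3.50)
        assert check_dose_limit(2.64)

    @settings(derandomize=True, max_examples=30)
    @given(mas=st.floats(1.0, 500.0), scale=st.floats(1.01, 5.0))
    def test_mgd_strictly_increasing_in_mas(self, factors, mas, scale):
        from dataclasses import replace

        beam = BeamQualityConfig(hvl_mm_al=0.52, tube_output_ugy_per_mas=78.0)
        lo = compute_mgd(replace(LE_RECORD, exposure_mas=mas), beam, factors)
        hi = compute_mgd(replace(LE_RECORD, exposure_mas=mas * scale), beam, factors)
        assert hi.mgd_mgy > lo.mgd_mgy
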