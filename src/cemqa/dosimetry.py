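"""Exposure parsing and mean glandular dose via the Dance factor model.

MGD = K * g * c * s, with K the incident air kerma at the breast top
surface, g the glandularity-50% conversion factor (a function of HVL and
breast thickness), c the correction for the actual glandularity, and s the
spectrum correction for the anode/filter combination.  The factor grids are
tabulated data loaded from CSV; the bundled defaults are synthetic
representative grids (see ``data/dose_factors``) that honor the published
factors' qualitative structure — swap in published tables with the same
schema for absolute dosimetry.

Exposure technical factors (anode/filter, kVp, mAs, thickness, AEC mode)
come from standard DICOM tags of "For Processing" images.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import ExposureParseError, FactorRangeError

ANODE_VOCAB = {"Mo", "Rh", "W"}
FILTER_VOCAB = {"Mo", "Rh", "Ag", "Cu", "Ti"}
HE_FILTERS = {"Cu", "Ti"}  # unique high-energy filters; used as LE/HE fallback

#: European guideline MGD limit for a 55-mm breast (mammography + DBT), mGy
EU_MGD_LIMIT_55MM = 2.64


@dataclass(frozen=True)
class ExposureRecord:
    """Technical factors of one acquisition, as selected by the AEC."""

    anode: str
    filter_material: str
    tube_voltage_kvp: float
    exposure_mas: float
    energy_kind: Literal["LE", "HE"]
    breast_thickness_mm: float = 55.0
    filter_thickness_um: float | None = None
    aec_mode: str = ""

    def __post_init__(self) -> None:
        if self.tube_voltage_kvp <= 0:
            raise ExposureParseError("tube voltage must be positive")
        if self.exposure_mas <= 0:
            raise ExposureParseError("exposure (mAs) must be positive")
        if self.anode not in ANODE_VOCAB:
            raise ExposureParseError(f"unknown anode material {self.anode!r}")
        if self.filter_material not in FILTER_VOCAB:
            raise ExposureParseError(f"unknown filter material {self.filter_material!r}")


@dataclass(frozen=True)
class BeamQualityConfig:
    """Measured beam data the DICOM header does not carry."""

    hvl_mm_al: float
    tube_output_ugy_per_mas: float  # at the reference (source-to-support) distance
    source_to_support_mm: float = 660.0

    def __post_init__(self) -> None:
        if min(self.hvl_mm_al, self.tube_output_ugy_per_mas, self.source_to_support_mm) <= 0:
            raise ValueError("beam quality parameters must all be positive")


@dataclass(frozen=True)
class DoseResult:
    mgd_mgy: float
    incident_air_kerma_mgy: float
    factors_used: tuple[float, float, float]  # (g, c, s)
    interpolation_flags: tuple[str, ...] = ()  # names of extrapolated factors


# ---------------------------------------------------------------------------
# DICOM tag parsing

_MANDATORY = ("KVP", "AnodeTargetMaterial", "FilterMaterial", "BodyPartThickness")

_MATERIAL_ALIASES = {
    "MOLYBDENUM": "Mo", "MO": "Mo",
    "RHODIUM": "Rh", "RH": "Rh",
    "TUNGSTEN": "W", "W": "W",
    "SILVER": "Ag", "AG": "Ag",
    "COPPER": "Cu", "CU": "Cu",
    "TITANIUM": "Ti", "TI": "Ti",
}


def _norm_material(value: str) -> str:
    key = str(value).strip().upper()
    return _MATERIAL_ALIASES.get(key, str(value).strip())


def parse_exposure(tags: Mapping[str, object]) -> ExposureRecord:
    """Build an ExposureRecord from a DICOM keyword->value map (or Dataset).

    Mandatory: KVP, Exposure (or ExposureInuAs), AnodeTargetMaterial,
    FilterMaterial, BodyPartThickness.  The Siemens-style dose-level
    percentage is extracted from ExposureControlModeDescription when
    present.  LE/HE comes from an explicit EnergyKind/ImageType hint when
    available, else from the filter material (Cu/Ti => HE).
    """
    get = tags.get if hasattr(tags, "get") else lambda k, d=None: getattr(tags, k, d)
    for key in _MANDATORY:
        if get(key) in (None, ""):
            raise ExposureParseError(f"missing mandatory tag {key}")
    mas = get("Exposure")
    if mas in (None, ""):
        uas = get("ExposureInuAs")
        if uas in (None, ""):
            raise ExposureParseError("missing mandatory tag Exposure (or ExposureInuAs)")
        mas = float(uas) / 1000.0
    anode = _norm_material(get("AnodeTargetMaterial"))
    filt = _norm_material(get("FilterMaterial"))

    energy: str | None = None
    hint = get("EnergyKind") or get("ImageType")
    if hint is not None:
        text = " ".join(hint) if isinstance(hint, (list, tuple)) else str(hint)
        up = text.upper()
        if "HIGH" in up or up == "HE":
            energy = "HE"
        elif "LOW" in up or up == "LE":
            energy = "LE"
    if energy is None:
        energy = "HE" if filt in HE_FILTERS else "LE"

    aec_mode = ""
    desc = get("ExposureControlModeDescription")
    if desc:
        m = re.search(r"(\d+(?:\.\d+)?)\s*%", str(desc))
        aec_mode = f"dose level {m.group(1)}%" if m else str(desc)

    thickness = get("BodyPartThickness")
    filt_um = get("FilterThicknessMinimum")
    return ExposureRecord(
        anode=anode,
        filter_material=filt,
        tube_voltage_kvp=float(get("KVP")),
        exposure_mas=float(mas),
        energy_kind=energy,  # type: ignore[arg-type]
        breast_thickness_mm=float(thickness),
        filter_thickness_um=None if filt_um in (None, "") else float(filt_um),
        aec_mode=aec_mode,
    )


def serialize_exposure(record: ExposureRecord) -> dict:
    """Inverse of :func:`parse_exposure`: a tag map that round-trips."""
    tags: dict[str, object] = {
        "KVP": record.tube_voltage_kvp,
        "Exposure": record.exposure_mas,
        "AnodeTargetMaterial": record.anode,
        "FilterMaterial": record.filter_material,
        "BodyPartThickness": record.breast_thickness_mm,
        "EnergyKind": record.energy_kind,
    }
    if record.filter_thickness_um is not None:
        tags["FilterThicknessMinimum"] = record.filter_thickness_um
    if record.aec_mode:
        tags["ExposureControlModeDescription"] = record.aec_mode
    return tags


# ---------------------------------------------------------------------------
# Factor tables

_DATA_PACKAGE = "cemqa.data.dose_factors"


class DoseFactorTable:
    """g/c/s conversion-factor grids with flagged linear interpolation.

    g(HVL, thickness) and c(HVL, thickness, glandularity) are gridded;
    s(anode, filter) is a lookup.  Queries inside the grid interpolate
    bi-/tri-linearly; queries outside by at most one grid step extrapolate
    linearly and are flagged; anything further raises a range error.
    """

    def __init__(self, g: pd.DataFrame, c: pd.DataFrame, s: pd.DataFrame) -> None:
        self._g_axes, self._g_values = self._pivot(g, ["hvl_mm_al", "thickness_mm"], "g")
        self._c_axes, self._c_values = self._pivot(
            c, ["hvl_mm_al", "thickness_mm", "glandularity"], "c"
        )
        if np.any(self._g_values <= 0) or np.any(self._c_values <= 0):
            raise ValueError("g and c factors must be positive everywhere")
        self._g_interp = RegularGridInterpolator(
            self._g_axes, self._g_values, bounds_error=False, fill_value=None
        )
        self._c_interp = RegularGridInterpolator(
            self._c_axes, self._c_values, bounds_error=False, fill_value=None
        )
        self._s = {
            (str(row.anode), str(row.filter)): float(row.s) for row in s.itertuples()
        }
        if any(v <= 0 for v in self._s.values()):
            raise ValueError("s factors must be positive")

    @staticmethod
    def _pivot(df: pd.DataFrame, axes: list[str], value: str):
        axis_vals = [np.array(sorted(df[a].unique()), dtype=float) for a in axes]
        for name, vals in zip(axes, axis_vals):
            if len(vals) < 2 or np.any(np.diff(vals) <= 0):
                raise ValueError(f"grid axis {name} must be strictly increasing with >= 2 nodes")
        shaped = (
            df.set_index(axes)[value]
            .sort_index()
            .to_numpy()
            .reshape([len(v) for v in axis_vals])
        )
        return tuple(axis_vals), shaped

    @classmethod
    def from_csvs(cls, g_path, c_path, s_path) -> "DoseFactorTable":
        read = lambda p: pd.read_csv(p, comment="#")
        return cls(read(g_path), read(c_path), read(s_path))

    @classmethod
    def bundled(cls) -> "DoseFactorTable":
        """The packaged synthetic representative grids."""
        base = resources.files(_DATA_PACKAGE)
        return cls.from_csvs(
            base / "g_factors_synthetic.csv",
            base / "c_factors_synthetic.csv",
            base / "s_factors_synthetic.csv",
        )

    def _check_range(self, axes, point, names) -> list[str]:
        flags = []
        for ax, x, name in zip(axes, point, names):
            if ax[0] <= x <= ax[-1]:
                continue
            step = ax[1] - ax[0] if x < ax[0] else ax[-1] - ax[-2]
            if ax[0] - step <= x <= ax[-1] + step:
                flags.append(name)
            else:
                raise FactorRangeError(
                    f"{name} = {x} outside the factor grid [{ax[0]}, {ax[-1]}] by more than one step"
                )
        return flags

    def g(self, hvl_mm_al: float, thickness_mm: float) -> tuple[float, list[str]]:
        flags = self._check_range(
            self._g_axes, (hvl_mm_al, thickness_mm), ("HVL(g)", "thickness(g)")
        )
        return float(self._g_interp((hvl_mm_al, thickness_mm))), flags

    def c(self, hvl_mm_al: float, thickness_mm: float, glandularity: float) -> tuple[float, list[str]]:
        flags = self._check_range(
            self._c_axes,
            (hvl_mm_al, thickness_mm, glandularity),
            ("HVL(c)", "thickness(c)", "glandularity(c)"),
        )
        return float(self._c_interp((hvl_mm_al, thickness_mm, glandularity))), flags

    def s(self, anode: str, filter_material: str) -> float:
        try:
            return self._s[(anode, filter_material)]
        except KeyError:
            raise FactorRangeError(f"no s factor tabulated for {anode}/{filter_material}") from None


# ---------------------------------------------------------------------------
# Dose computation


def compute_mgd(
    exposure: ExposureRecord,
    beam: BeamQualityConfig,
    factors: DoseFactorTable,
    glandularity: float = 0.5,
) -> DoseResult:
    """MGD = K * g * c * s for one acquisition.

    K is the tube output scaled by mAs and inverse-square corrected from the
    reference (source-to-support) distance to the breast top surface.
    """
    d_ref = beam.source_to_support_mm
    d_surface = d_ref - exposure.breast_thickness_mm
    if d_surface <= 0:
        raise ValueError("breast thickness exceeds the source-to-support distance")
    kerma_mgy = (
        beam.tube_output_ugy_per_mas * exposure.exposure_mas * (d_ref / d_surface) ** 2 / 1000.0
    )
    g, g_flags = factors.g(beam.hvl_mm_al, exposure.breast_thickness_mm)
    c, c_flags = factors.c(beam.hvl_mm_al, exposure.breast_thickness_mm, glandularity)
    s = factors.s(exposure.anode, exposure.filter_material)
    return DoseResult(
        mgd_mgy=kerma_mgy * g * c * s,
        incident_air_kerma_mgy=kerma_mgy,
        factors_used=(g, c, s),
        interpolation_flags=tuple(g_flags + c_flags),
    )


def total_mgd(le: DoseResult | float, he: DoseResult | float) -> float:
    """Total study dose: the sum of the LE and HE image MGDs, mGy."""
    get = lambda d: d.mgd_mgy if isinstance(d, DoseResult) else float(d)
    return get(le) + get(he)


def he_dose_fraction(le: DoseResult | float, he: DoseResult | float) -> float:
    """Dose increase attributed to HE imaging: 100 * MGD_HE / MGD_LE, percent."""
    get = lambda d: d.mgd_mgy if isinstance(d, DoseResult) else float(d)
    le_v, he_v = get(le), get(he)
    if le_v <= 0:
        raise ZeroDivisionError("LE dose must be positive")
    return 100.0 * he_v / le_v


def check_dose_limit(total: float, limit: float = EU_MGD_LIMIT_55MM) -> bool:
    """True (pass) iff total <= limit; the boundary is inclusive."""
    if total < 0:
        raise ValueError("total dose must be non-negative")
    return total <= limit
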