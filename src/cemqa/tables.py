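"""Loaders for the bundled reference measurement tables.

The package ships transcriptions of the dose and CNR tables published by a
three-vendor CEM phantom intercomparison (GE, Hologic, Siemens; CIRS Model
022-style phantom).  They drive report regeneration and profile calibration
without access to a mammography unit.  Cells flagged ``suspect`` are
verbatim transcriptions of apparent typographical errors at source and are
excluded from derived summaries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "cemqa.data.reference"

#: system/AEC labels in canonical presentation order
LABELS = (
    "GE",
    "Hologic",
    "Siemens 125%",
    "Siemens 112%",
    "Siemens 100%",
    "Siemens 89%",
    "Siemens 80%",
)

REFERENCE_LABEL = "GE"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_DATA).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_technical_factors() -> pd.DataFrame:
    """Per-image technical factors and MGD (mean, half-dispersion)."""
    return _read("technical_factors.csv")


def load_cnr_raw() -> pd.DataFrame:
    """Mean CNR on raw LE/HE images per (half, density, system label)."""
    return _read("cnr_raw.csv")


def load_cnr_des() -> pd.DataFrame:
    """Mean CNR on DES images per (half, density, system label)."""
    return _read("cnr_des.csv")


def load_printed_ratio_means() -> pd.DataFrame:
    """Mean CNR ratios as printed at source (1-decimal presentation)."""
    return _read("printed_ratio_means.csv")


def load_printed_dose_summary() -> pd.DataFrame:
    """Printed total-dose summaries used for rounding-artifact flagging."""
    return _read("printed_dose_summary.csv")


def cnr_target_table(label: str, include_suspect: bool = False) -> dict[tuple[str, str, float], float]:
    """Calibration target map (energy, half, density) -> CNR for one system."""
    df = load_cnr_raw()
    df = df[df["label"] == label]
    if not include_suspect:
        df = df[df["flag"] != "suspect"]
    if df.empty:
        raise KeyError(f"no CNR rows for label {label!r}")
    return {
        (r.image_kind, r.half, float(r.iodine_mg_cm2)): float(r.cnr_mean)
        for r in df.itertuples()
    }
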