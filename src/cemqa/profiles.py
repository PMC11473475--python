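"""Ready-made system profiles calibrated to the bundled CNR tables.

These emulate the three compared systems only in the sense that their
analytic plug CNRs on raw LE/HE images reproduce the bundled measured
table: the 2.0 mg/cm^2 adipose plug exactly, the rest through the
energy-lumped exponential model.  Absolute pixel values, spectra and AEC
behavior are not modelled.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from . import tables
from .dosimetry import ExposureRecord
from .simulate import SystemProfile, calibrate_profile_to_cnr


def base_profile(name: str = "generic", aec_mode: str = "default") -> SystemProfile:
    """Uncalibrated starting profile with desk-scale defaults.

    Background means are arbitrary linear detector units; the noise model
    defaults to pure quantum noise (variance = a * mean), leaving the
    electronic floor to explicit configuration.  The glandular-plug step is
    tied to the tissue step (same material as the glandular half; see
    :data:`cemqa.simulate.GLAND_PLUG_EXPONENT`), so the plug is clearly
    visible on LE images yet cancels under tissue-nulling recombination, as
    on the physical phantom.
    """
    from .simulate import gland_plug_step_from_tissue

    return SystemProfile(
        name=name,
        aec_mode=aec_mode,
        background_mean_le=10000.0,
        background_mean_he=4000.0,
        tissue_step_le=0.60,
        tissue_step_he=0.85,
        alpha_le=0.05,
        alpha_he=0.10,
        gland_plug_step_le=gland_plug_step_from_tissue(0.60),
        gland_plug_step_he=gland_plug_step_from_tissue(0.85),
        noise_a_le=1.0,
        noise_b_le=0.0,
        noise_a_he=1.0,
        noise_b_he=0.0,
    )


def _exposures(label: str) -> dict:
    tf = tables.load_technical_factors()
    sub = tf[tf["label"] == label]
    out = {}
    for r in sub.itertuples():
        out[r.energy] = ExposureRecord(
            anode=r.anode,
            filter_material=r.filter,
            tube_voltage_kvp=float(r.kvp),
            exposure_mas=float(r.mas_mean),
            energy_kind=r.energy,
            breast_thickness_mm=55.0,
            aec_mode=r.aec_mode,
        )
    return out


def reference_profile(label: str) -> SystemProfile:
    """One bundled-table-calibrated profile (e.g. 'GE', 'Siemens 100%')."""
    if label not in tables.LABELS:
        raise KeyError(f"unknown system label {label!r}; choose from {tables.LABELS}")
    targets = tables.cnr_target_table(label)
    exposures = _exposures(label)
    tf = tables.load_technical_factors()
    aec_mode = str(tf.loc[tf["label"] == label, "aec_mode"].iloc[0])
    base = base_profile(name=label.split()[0], aec_mode=aec_mode)
    prof = calibrate_profile_to_cnr(targets, base)
    from dataclasses import replace

    return replace(prof, exposure_le=exposures.get("LE"), exposure_he=exposures.get("HE"))


def reference_profiles(labels=("GE", "Hologic", "Siemens 100%")) -> dict[str, SystemProfile]:
    """Calibrated profiles for the default three-system comparison."""
    return {label: reference_profile(label) for label in labels}


# ---------------------------------------------------------------------------
# Profile (de)serialization — canonical format: YAML

_SCALAR_FIELDS = (
    "name", "aec_mode",
    "background_mean_le", "background_mean_he",
    "tissue_step_le", "tissue_step_he",
    "alpha_le", "alpha_he",
    "gland_plug_step_le", "gland_plug_step_he",
    "noise_a_le", "noise_b_le", "noise_a_he", "noise_b_he",
)


def profile_to_yaml(profile: SystemProfile) -> str:
    doc = {f: getattr(profile, f) for f in _SCALAR_FIELDS}
    for energy in ("le", "he"):
        rec = getattr(profile, f"exposure_{energy}")
        if rec is not None:
            doc[f"exposure_{energy}"] = asdict(rec)
    return yaml.safe_dump(doc, sort_keys=False)


def profile_from_yaml(text: str) -> SystemProfile:
    doc = yaml.safe_load(text)
    kwargs = {f: doc[f] for f in _SCALAR_FIELDS if f in doc}
    for energy in ("le", "he"):
        rec = doc.get(f"exposure_{energy}")
        if rec is not None:
            kwargs[f"exposure_{energy}"] = ExposureRecord(**rec)
    return SystemProfile(**kwargs)
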