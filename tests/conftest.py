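"""Shared fixtures: phantom geometry, calibrated profiles, replicate banks."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cemqa import (
    default_cirs022_layout,
    default_frame,
    measure_study,
    simulate_acquisition,
)
from cemqa.aggregate import measurements_to_frame
from cemqa.profiles import reference_profile, reference_profiles
from cemqa.recombine import estimate_weight, recombine

N_REPLICATES = 25
REPLICATE_SEED0 = 100


@pytest.fixture(scope="session")
def spec():
    return default_cirs022_layout()


@pytest.fixture(scope="session")
def frame():
    return default_frame()


@pytest.fixture(scope="session")
def ge_profile():
    """Profile calibrated to the bundled GE CNR column."""
    return reference_profile("GE")


@pytest.fixture(scope="session")
def ge_profile_noiseless(ge_profile):
    return replace(
        ge_profile, noise_a_le=0.0, noise_b_le=0.0, noise_a_he=0.0, noise_b_he=0.0
    )


@pytest.fixture(scope="session")
def three_profiles():
    return reference_profiles(("GE", "Hologic", "Siemens 100%"))


@pytest.fixture(scope="session")
def ge_study(spec, frame, ge_profile):
    return simulate_acquisition(spec, ge_profile, frame, seed=42)


@pytest.fixture(scope="session")
def noiseless_study(spec, frame, ge_profile_noiseless):
    return simulate_acquisition(spec, ge_profile_noiseless, frame, seed=0)


def _measure_one(study, spec, frame):
    params = estimate_weight(study.le_image, study.he_image, spec, frame)
    des = recombine(study.le_image, study.he_image, params)
    return measure_study(
        {"LE": study.le_image, "HE": study.he_image, "DES": des.image}, spec, frame
    )


@pytest.fixture(scope="session")
def ge_replicate_bank(spec, frame, ge_profile):
    """25 seeded replicates of the GE-calibrated system, fully measured."""
    frames = []
    for i in range(N_REPLICATES):
        study = simulate_acquisition(spec, frame=frame, profile=ge_profile, seed=REPLICATE_SEED0 + i)
        meas = _measure_one(study, spec, frame)
        frames.append(measurements_to_frame(meas, f"rep{i:02d}", "GE", "AOP/STD"))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def three_system_measurements(spec, frame, three_profiles):
    """3 calibrated systems x 3 seeded repeats, fully measured."""
    frames = []
    for label, prof in three_profiles.items():
        for rep in range(3):
            study = simulate_acquisition(spec, prof, frame, seed=1000 + rep)
            meas = _measure_one(study, spec, frame)
            frames.append(measurements_to_frame(meas, f"rep{rep}", prof.name, prof.aec_mode))
    return pd.concat(frames, ignore_index=True)
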