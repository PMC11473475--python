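"""Synthetic dual-energy phantom acquisitions.

An energy-lumped signal model stands in for a real CEM system: each energy
(LE just below, HE just above the 33.2-keV iodine k-edge) is described by a
mean detector signal over the adipose half, a multiplicative glandular-half
step, an effective iodine attenuation coefficient alpha (cm^2/mg) so that a
plug of surface density sigma multiplies the local mean by exp(-alpha*sigma),
a multiplicative step for the 100%-glandular plug, and a quantum-plus-
electronic noise law  variance = a*mean + b.  Per-pixel noise is Gaussian,
a good approximation of Poisson statistics at mammographic signal levels.

Profiles are descriptive calibrations (typically against a measured CNR
table), not physics predictions of any vendor's pixel values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dosimetry import ExposureRecord
from .errors import CalibrationWarning, DegenerateNoiseError, GeometryError, ProfileError
from .phantom import FrameMap, PhantomSpec, PlugSpec

Energy = Literal["LE", "HE"]


@dataclass(frozen=True)
class SystemProfile:
    """Energy-lumped acquisition model of one CEM system / AEC mode."""

    name: str
    aec_mode: str
    background_mean_le: float
    background_mean_he: float
    tissue_step_le: float  # glandular-half / adipose-half signal ratio, <= 1
    tissue_step_he: float
    alpha_le: float  # cm^2/mg effective iodine attenuation
    alpha_he: float
    gland_plug_step_le: float  # 100%-glandular plug / local background ratio
    gland_plug_step_he: float
    noise_a_le: float = 0.0  # variance = a*mean + b, per energy
    noise_b_le: float = 0.0
    noise_a_he: float = 0.0
    noise_b_he: float = 0.0
    exposure_le: ExposureRecord | None = None
    exposure_he: ExposureRecord | None = None
    calibration_residuals: tuple | None = None  # per-plug (energy, half, sigma, residual)

    def __post_init__(self) -> None:
        if self.background_mean_le <= 0 or self.background_mean_he <= 0:
            raise ProfileError("background means must be positive")
        for ts in (self.tissue_step_le, self.tissue_step_he):
            if not (0 < ts <= 1):
                raise ProfileError("tissue step must lie in (0, 1]")
        for gp in (self.gland_plug_step_le, self.gland_plug_step_he):
            if gp <= 0:
                raise ProfileError("glandular-plug step must be positive")
        for v in (self.noise_a_le, self.noise_b_le, self.noise_a_he, self.noise_b_he):
            if v < 0:
                raise ProfileError("noise coefficients must be non-negative")

    # -- per-energy accessors -------------------------------------------------
    def background_mean(self, energy: Energy) -> float:
        return self.background_mean_le if energy == "LE" else self.background_mean_he

    def tissue_step(self, energy: Energy) -> float:
        return self.tissue_step_le if energy == "LE" else self.tissue_step_he

    def alpha(self, energy: Energy) -> float:
        return self.alpha_le if energy == "LE" else self.alpha_he

    def gland_plug_step(self, energy: Energy) -> float:
        return self.gland_plug_step_le if energy == "LE" else self.gland_plug_step_he

    def noise_ab(self, energy: Energy) -> tuple[float, float]:
        if energy == "LE":
            return (self.noise_a_le, self.noise_b_le)
        return (self.noise_a_he, self.noise_b_he)

    def noise_sd(self, energy: Energy, mean: float) -> float:
        a, b = self.noise_ab(energy)
        return float(np.sqrt(a * mean + b))

    def local_background_mean(self, energy: Energy, half: str) -> float:
        m = self.background_mean(energy)
        if half == "glandular":
            m *= self.tissue_step(energy)
        return m

    def plug_mean(self, energy: Energy, plug: PlugSpec) -> float:
        m = self.local_background_mean(energy, plug.half)
        if plug.kind == "iodine":
            return m * float(np.exp(-self.alpha(energy) * plug.iodine_density))
        return m * self.gland_plug_step(energy)


@dataclass(frozen=True)
class PlugTruth:
    """Analytic per-plug means and noise SDs recorded by the generator."""

    plug_id: str
    center_px: tuple[float, float]
    mean_bkg: dict  # energy -> local background mean
    mean_plug: dict  # energy -> plug mean
    sd_bkg: dict  # energy -> noise SD at the local background mean


@dataclass
class CEMStudy:
    """One synthetic acquisition: the LE/HE raw pair plus its generation truth."""

    le_image: np.ndarray
    he_image: np.ndarray
    frame: FrameMap
    spec: PhantomSpec
    profile_name: str
    aec_mode: str
    seed: int
    truth: dict  # plug_id -> PlugTruth

    def image(self, kind: str) -> np.ndarray:
        if kind == "LE":
            return self.le_image
        if kind == "HE":
            return self.he_image
        raise KeyError(kind)


def _disk_coverage(frame: FrameMap, center_mm, radius_mm: float, subsamples: int = 4) -> tuple[slice, slice, np.ndarray]:
    """Area-weighted coverage fractions of a disk, on a bounding crop.

    Interior/exterior pixels are decided by center distance; boundary pixels
    are subsampled ``subsamples x subsamples`` so plug edges are anti-aliased
    and ROI statistics are not biased by aliasing.
    """
    sr, sc = frame.pixel_spacing_mm
    row_c, col_c = frame.mm_to_px(center_mm, check=False)
    half_diag = 0.5 * float(np.hypot(sr, sc))
    r_px_r = radius_mm / sr
    r_px_c = radius_mm / sc
    r0 = max(int(np.floor(row_c - r_px_r)) - 1, 0)
    r1 = min(int(np.ceil(row_c + r_px_r)) + 2, frame.shape[0])
    c0 = max(int(np.floor(col_c - r_px_c)) - 1, 0)
    c1 = min(int(np.ceil(col_c + r_px_c)) + 2, frame.shape[1])
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    dy = (rows - row_c)[:, None] * sr
    dx = (cols - col_c)[None, :] * sc
    dist = np.hypot(dx, dy)
    cov = np.zeros(dist.shape)
    cov[dist <= radius_mm - half_diag] = 1.0
    edge = (dist > radius_mm - half_diag) & (dist < radius_mm + half_diag)
    if np.any(edge):
        er, ec = np.nonzero(edge)
        offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
        oy, ox = np.meshgrid(offs * sr, offs * sc, indexing="ij")
        sub_dy = dy[er, 0][:, None, None] + oy[None]
        sub_dx = dx[0, ec][:, None, None] + ox[None]
        cov[er, ec] = np.mean(np.hypot(sub_dx, sub_dy) <= radius_mm, axis=(1, 2))
    return slice(r0, r1), slice(c0, c1), cov


def mean_image(spec: PhantomSpec, profile: SystemProfile, frame: FrameMap, energy: Energy) -> np.ndarray:
    """Noiseless detector-signal image for one energy."""
    _, Y = frame.pixel_centers_mm()
    bkg = profile.background_mean(energy)
    ts = profile.tissue_step(energy)
    boundary = spec.contrast_plate_split
    gland_mask = np.vectorize(lambda y: boundary.half_of((0.0, y)) == "glandular")(Y[:, 0])
    img = np.full(frame.shape, bkg, dtype=float)
    img[gland_mask, :] *= ts
    for plug in spec.plugs:
        x, y = plug.center_mm
        r = plug.radius_mm
        w, h = spec.field_of_view_mm
        try:
            frame.mm_to_px(plug.center_mm)
        except GeometryError as exc:
            raise GeometryError(f"plug {plug.id} outside field of view") from exc
        if plug.kind == "iodine":
            f = float(np.exp(-profile.alpha(energy) * plug.iodine_density))
        else:
            f = profile.gland_plug_step(energy)
        rs, cs, cov = _disk_coverage(frame, plug.center_mm, r)
        img[rs, cs] *= 1.0 + cov * (f - 1.0)
    if np.any(img <= 0):
        raise ProfileError("profile produces non-positive mean signal")
    return img


def simulate_acquisition(
    spec: PhantomSpec, profile: SystemProfile, frame: FrameMap, seed: int
) -> CEMStudy:
    """Generate one seeded LE/HE raw pair with per-plug analytic truth.

    Identical (spec, profile, frame, seed) reproduce the pixel arrays
    bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    images = {}
    for energy in ("LE", "HE"):
        mean = mean_image(spec, profile, frame, energy)  # type: ignore[arg-type]
        a, b = profile.noise_ab(energy)  # type: ignore[arg-type]
        if a == 0 and b == 0:
            images[energy] = mean
        else:
            sd = np.sqrt(a * mean + b)
            images[energy] = mean + rng.standard_normal(mean.shape) * sd
    truth = {}
    for plug in spec.plugs:
        truth[plug.id] = PlugTruth(
            plug_id=plug.id,
            center_px=frame.mm_to_px(plug.center_mm),
            mean_bkg={e: profile.local_background_mean(e, plug.half) for e in ("LE", "HE")},
            mean_plug={e: profile.plug_mean(e, plug) for e in ("LE", "HE")},
            sd_bkg={
                e: profile.noise_sd(e, profile.local_background_mean(e, plug.half))
                for e in ("LE", "HE")
            },
        )
    return CEMStudy(
        le_image=images["LE"],
        he_image=images["HE"],
        frame=frame,
        spec=spec,
        profile_name=profile.name,
        aec_mode=profile.aec_mode,
        seed=seed,
        truth=truth,
    )


def analytic_cnr(profile: SystemProfile, plug: PlugSpec, energy: Energy) -> float:
    """Ground-truth CNR of a plug from the noiseless model and the noise law."""
    m_bkg = profile.local_background_mean(energy, plug.half)
    m_plug = profile.plug_mean(energy, plug)
    sd = profile.noise_sd(energy, m_bkg)
    if sd == 0:
        raise DegenerateNoiseError("zero background noise: CNR undefined")
    return abs(m_bkg - m_plug) / sd


# ---------------------------------------------------------------------------
# Calibration against a measured CNR table

ANCHOR_DENSITY = 2.0  # mg/cm^2, adipose-half anchor matched exactly

#: The 100%-glandular plug is 10 mm of pure gland replacing 50/50 plate
#: material, i.e. 5 mm of excess gland against the 25-mm adipose/gland
#: contrast plate that defines the tissue step: its lumped signal step is
#: tissue_step ** (5/25).  Because it is the same material as the glandular
#: half, a tissue-nulling recombination cancels it to the same order.
GLAND_PLUG_EXPONENT = (10.0 * 0.5) / 25.0


def gland_plug_step_from_tissue(tissue_step: float) -> float:
    """Physically consistent glandular-plug step for a given tissue step."""
    return float(tissue_step**GLAND_PLUG_EXPONENT)


def _cnr_shape(alpha: float, sigma: np.ndarray) -> np.ndarray:
    """(1 - exp(-alpha*sigma)) normalized to 1 at the anchor density."""
    return -np.expm1(-alpha * sigma) / -np.expm1(-alpha * ANCHOR_DENSITY)


def calibrate_profile_to_cnr(
    target_cnr_table: Mapping[tuple[str, str, float], float],
    base_profile: SystemProfile,
) -> SystemProfile:
    """Calibrate a profile so its analytic CNRs match a measured table.

    ``target_cnr_table`` maps (energy, half, iodine_density) -> CNR and must
    cover the four iodine densities for the adipose half at both energies.
    The 2.0 mg/cm^2 adipose plug is matched exactly by construction: the
    effective attenuation alpha is chosen by least squares over the remaining
    densities under that constraint, and the quantum-noise coefficient is
    re-solved from the anchor (noise_b is kept; default 0).  When the
    glandular 2.0 mg/cm^2 target is present the tissue step is re-solved the
    same way.  Per-plug residual mismatches are attached to the returned
    profile; an unattainable target produces a calibration warning with
    residuals, never a failure.
    """
    prof = base_profile
    residuals: list[tuple[str, str, float, float]] = []
    updates: dict = {}
    for energy in ("LE", "HE"):
        sigmas = sorted(
            {s for (e, h, s) in target_cnr_table if e == energy and h == "adipose"}
        )
        if ANCHOR_DENSITY not in sigmas:
            raise ValueError(f"target table must include the {ANCHOR_DENSITY} mg/cm^2 adipose plug for {energy}")
        anchor = float(target_cnr_table[(energy, "adipose", ANCHOR_DENSITY)])
        others = np.array([s for s in sigmas if s != ANCHOR_DENSITY])
        targets = np.array([target_cnr_table[(energy, "adipose", s)] for s in others])

        def sse(alpha: float) -> float:
            return float(np.sum((anchor * _cnr_shape(alpha, others) - targets) ** 2))

        if len(others):
            res = minimize_scalar(sse, bounds=(1e-6, 5.0), method="bounded")
            alpha = float(res.x)
        else:
            alpha = prof.alpha(energy)  # anchor alone cannot fix the shape
        # exact anchor: K = m / sqrt(a*m + b) must equal anchor / (1 - e^{-alpha*2})
        m = prof.background_mean(energy)
        K = anchor / float(-np.expm1(-alpha * ANCHOR_DENSITY))
        _, b = prof.noise_ab(energy)
        a = (m * m / (K * K) - b) / m
        if a < 0:
            warnings.warn(
                f"{energy}: electronic noise floor alone exceeds the anchor target; clamping noise_a to 0",
                CalibrationWarning,
            )
            a = 0.0
        suffix = energy.lower()
        updates[f"alpha_{suffix}"] = alpha
        updates[f"noise_a_{suffix}"] = a

        # tissue step from the glandular anchor, when provided
        key = (energy, "glandular", ANCHOR_DENSITY)
        if key in target_cnr_table:
            cg = float(target_cnr_table[key])

            def gland_cnr(ts: float) -> float:
                mg = m * ts
                sd = np.sqrt(a * mg + b)
                return float(mg * -np.expm1(-alpha * ANCHOR_DENSITY) / sd)

            lo, hi = 1e-6, 1.0
            if gland_cnr(hi) < cg:
                warnings.warn(
                    f"{energy}: glandular anchor exceeds adipose anchor; tissue step clamped to 1",
                    CalibrationWarning,
                )
                ts = 1.0
            else:
                ts = float(brentq(lambda t: gland_cnr(t) - cg, lo, hi))
            updates[f"tissue_step_{suffix}"] = ts
            updates[f"gland_plug_step_{suffix}"] = gland_plug_step_from_tissue(ts)

    prof = replace(prof, **updates)
    # residual report over every provided plug
    from .phantom import PlugSpec as _PS

    for (energy, half, sigma), target in sorted(target_cnr_table.items()):
        plug = _PS(
            id="cal", center_mm=(50.0, 50.0), diameter_mm=10.0, kind="iodine",
            iodine_density=float(sigma), half=half,  # type: ignore[arg-type]
        )
        model = analytic_cnr(prof, plug, energy)  # type: ignore[arg-type]
        residuals.append((energy, half, float(sigma), model - float(target)))
    return replace(prof, calibration_residuals=tuple(residuals))
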