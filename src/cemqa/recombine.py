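"""Dual-energy subtraction by weighted logarithmic subtraction.

Vendors' recombination algorithms are proprietary; this module implements
the literature-standard log-domain weighted subtraction

    DES = ln(max(I_HE, eps)) - w * ln(max(I_LE, eps)) + offset

with the weight w estimated per study so the adipose/glandular contrast-
plate step is nulled, which is the functional goal of any DES algorithm:
enhance iodine, cancel the tissue background.  Vendor DES images, when
available, simply bypass this module and feed the ROI metrics directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .phantom import FrameMap, PhantomSpec

#: relative floor applied before the logarithm (times the image maximum)
EPSILON_REL = 1e-6
#: |mean log step| below which the LE denominator is considered degenerate
DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class RecombinationParams:
    """Log-domain weight, display offset and the positive floor before ln."""

    weight_w: float
    offset: float = 0.0
    epsilon: float = 1e-6
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not np.isfinite(self.weight_w):
            raise ValueError("weight must be finite")


@dataclass(frozen=True)
class DESImage:
    """A recombined image (log-subtraction units) with its provenance."""

    image: np.ndarray
    params: RecombinationParams
    provenance: str = ""


@dataclass(frozen=True)
class PatchPair:
    """Plug-free rectangular patches (mm), one per contrast-plate half."""

    adipose: tuple[float, float, float, float]  # (x0, x1, y0, y1)
    glandular: tuple[float, float, float, float]


def _patch_clear_of_plugs(rect, spec: PhantomSpec, margin_mm: float) -> bool:
    x0, x1, y0, y1 = rect
    for plug in spec.plugs:
        px, py = plug.center_mm
        r = plug.radius_mm + margin_mm
        # distance from the plug center to the rectangle
        dx = max(x0 - px, 0.0, px - x1)
        dy = max(y0 - py, 0.0, py - y1)
        if np.hypot(dx, dy) < r:
            return False
    return True


def default_patches(spec: PhantomSpec, margin_mm: float = 2.0) -> PatchPair:
    """Auto-place one plug-free rectangular patch per half.

    Candidate strips (left, right, then center) within each half are tested
    against every plug circle plus a safety margin; the first clear strip
    wins.  Raises a geometry error when no candidate is plug-free.
    """
    w, h = spec.field_of_view_mm
    b = spec.contrast_plate_split.position_mm
    halves = {}
    for half in ("adipose", "glandular"):
        if spec.half_of((w / 2, b / 2)) == half:
            y0, y1 = 0.05 * b, 0.90 * b
        else:
            y0, y1 = b + 0.10 * (h - b), h - 0.05 * (h - b)
        candidates = [
            (0.03 * w, 0.22 * w, y0, y1),
            (0.78 * w, 0.97 * w, y0, y1),
            (0.40 * w, 0.60 * w, y0, y1),
        ]
        for rect in candidates:
            if _patch_clear_of_plugs(rect, spec, margin_mm):
                halves[half] = rect
                break
        else:
            raise GeometryError(f"no plug-free patch placement found in the {half} half")
    return PatchPair(adipose=halves["adipose"], glandular=halves["glandular"])


def _patch_mean_log(image: np.ndarray, rect, frame: FrameMap, epsilon: float) -> float:
    x0, x1, y0, y1 = rect
    r0, c0 = frame.mm_to_px((x0, y0))
    r1, c1 = frame.mm_to_px((x1, y1))
    rs = slice(int(np.ceil(min(r0, r1))), int(np.floor(max(r0, r1))) + 1)
    cs = slice(int(np.ceil(min(c0, c1))), int(np.floor(max(c0, c1))) + 1)
    patch = image[rs, cs]
    if patch.size == 0:
        raise GeometryError("patch contains no pixels")
    return float(np.mean(np.log(np.maximum(patch, epsilon))))


def estimate_weight(
    le_image: np.ndarray,
    he_image: np.ndarray,
    spec: PhantomSpec,
    frame: FrameMap,
    patches: PatchPair | None = None,
) -> RecombinationParams:
    """Estimate the tissue-nulling weight from plug-free patches.

    w = [mean ln I_HE (gland) - mean ln I_HE (adip)] /
        [mean ln I_LE (gland) - mean ln I_LE (adip)]

    A vanishing LE denominator (no tissue contrast to null) yields w = 0
    with the degenerate flag set.
    """
    if patches is None:
        patches = default_patches(spec)
    else:
        for name, rect in (("adipose", patches.adipose), ("glandular", patches.glandular)):
            if not _patch_clear_of_plugs(rect, spec, margin_mm=0.0):
                raise GeometryError(f"{name} patch overlaps a plug")
    eps_le = EPSILON_REL * float(np.max(le_image))
    eps_he = EPSILON_REL * float(np.max(he_image))
    num = _patch_mean_log(he_image, patches.glandular, frame, eps_he) - _patch_mean_log(
        he_image, patches.adipose, frame, eps_he
    )
    den = _patch_mean_log(le_image, patches.glandular, frame, eps_le) - _patch_mean_log(
        le_image, patches.adipose, frame, eps_le
    )
    scale = abs(_patch_mean_log(le_image, patches.adipose, frame, eps_le)) + 1.0
    if abs(den) < DEGENERATE_TOL * scale:
        return RecombinationParams(weight_w=0.0, epsilon=eps_le, degenerate=True)
    return RecombinationParams(weight_w=num / den, epsilon=min(eps_le, eps_he))


def recombine(le_image: np.ndarray, he_image: np.ndarray, params: RecombinationParams) -> DESImage:
    """Pixelwise DES = ln(max(HE, eps)) - w*ln(max(LE, eps)) + offset."""
    if le_image.shape != he_image.shape:
        raise ValueError(f"shape mismatch: LE {le_image.shape} vs HE {he_image.shape}")
    des = (
        np.log(np.maximum(he_image, params.epsilon))
        - params.weight_w * np.log(np.maximum(le_image, params.epsilon))
        + params.offset
    )
    return DESImage(image=des, params=params)
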