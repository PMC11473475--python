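"""Plug localization, ROI/annulus statistics, CNR, residual CNR and linearity.

The image-quality metric throughout is the contrast-to-noise ratio

    CNR = |MPV_bkg - MPV_target| / SD_bkg

with MPV_target the mean pixel value of a circular ROI inside the target,
and MPV_bkg / SD_bkg the mean and standard deviation of a circular ring
around it.  CNR is invariant under affine intensity rescaling, so the same
machinery applies to raw LE/HE images, internal log-domain DES images and
vendor DES images of unknown scaling.

Pixel membership in disk and ring is by pixel-center inclusion, with no
partial weighting, so a per-pixel brute-force implementation reproduces the
statistics exactly.  SD is the population (not sample) standard deviation;
the difference is negligible at ring sizes >= 100 px but is pinned for
exactness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import (
    DegenerateNoiseError,
    InsufficientDataError,
    LocalizationWarning,
    MeasurementError,
)
from .phantom import FrameMap, PhantomSpec, PlugSpec
from .recombine import DESImage


@dataclass(frozen=True)
class ROIConfig:
    """ROI geometry relative to the plug radius, plus search/count settings.

    The source study placed its ROIs manually; these factors keep the target
    disk away from the plug edge (blur, localization error) and the ring
    outside it, and are freely configurable because the original ring/ROI
    sizes are not published.
    """

    roi_radius_factor: float = 0.6
    ring_inner_factor: float = 1.2
    ring_outer_factor: float = 1.6
    min_n_target: int = 25
    min_n_bkg: int = 100
    refine_window_mm: float = 2.0
    # annulus used only by center refinement; tighter than the measurement
    # ring so the search region stays inside the image for edge-most plugs
    refine_ring_inner_factor: float = 1.05
    refine_ring_outer_factor: float = 1.35


@dataclass(frozen=True)
class ROIStatistics:
    mpv_target: float
    mpv_bkg: float
    sd_bkg: float
    n_target: int
    n_bkg: int


@dataclass(frozen=True)
class CNRMeasurement:
    plug_id: str
    image_kind: str  # LE | HE | DES
    half: str
    iodine_density: float
    cnr: float
    stats: ROIStatistics
    residual_flag: bool = False


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class LocatedPlug:
    plug_id: str
    center_px: tuple[float, float]
    displacement_mm: float
    refined: bool


# ---------------------------------------------------------------------------
# ROI statistics


def _region_masks(
    shape: tuple[int, int],
    center_px: Sequence[float],
    frame: FrameMap,
    roi_radius_mm: float,
    ring_inner_mm: float,
    ring_outer_mm: float,
) -> tuple[np.ndarray, np.ndarray, slice, slice]:
    sr, sc = frame.pixel_spacing_mm
    row_c, col_c = float(center_px[0]), float(center_px[1])
    pad_r = ring_outer_mm / sr
    pad_c = ring_outer_mm / sc
    if (
        row_c - pad_r < -0.5
        or row_c + pad_r > shape[0] - 0.5
        or col_c - pad_c < -0.5
        or col_c + pad_c > shape[1] - 0.5
    ):
        raise MeasurementError("ROI/ring geometry clipped by the image border")
    r0, r1 = int(np.floor(row_c - pad_r)), int(np.ceil(row_c + pad_r)) + 1
    c0, c1 = int(np.floor(col_c - pad_c)), int(np.ceil(col_c + pad_c)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    rows = np.arange(r0, min(r1, shape[0]))
    cols = np.arange(c0, min(c1, shape[1]))
    dist = np.hypot(
        ((rows - row_c)[:, None] * sr),
        ((cols - col_c)[None, :] * sc),
    )
    disk = dist <= roi_radius_mm
    ring = (dist >= ring_inner_mm) & (dist <= ring_outer_mm)
    return disk, ring, slice(r0, r0 + len(rows)), slice(c0, c0 + len(cols))


def roi_stats(
    image: np.ndarray,
    center_px: Sequence[float],
    roi_radius_mm: float,
    ring_inner_mm: float,
    ring_outer_mm: float,
    frame: FrameMap,
    min_n_target: int = 25,
    min_n_bkg: int = 100,
) -> ROIStatistics:
    """Disk and ring statistics around a pixel center.

    Raises a measurement error when the geometry is clipped by the image
    border (partial ROIs are never measured) or the pixel counts fall below
    the configured minima.
    """
    if not (0 < roi_radius_mm < ring_inner_mm < ring_outer_mm):
        raise ValueError("require ring_outer > ring_inner > roi_radius > 0")
    disk, ring, rs, cs = _region_masks(
        image.shape, center_px, frame, roi_radius_mm, ring_inner_mm, ring_outer_mm
    )
    crop = image[rs, cs]
    target = crop[disk]
    bkg = crop[ring]
    if target.size < min_n_target or bkg.size < min_n_bkg:
        raise MeasurementError(
            f"too few ROI pixels (target {target.size}, ring {bkg.size})"
        )
    return ROIStatistics(
        mpv_target=float(np.mean(target)),
        mpv_bkg=float(np.mean(bkg)),
        sd_bkg=float(np.std(bkg)),  # population SD, by convention
        n_target=int(target.size),
        n_bkg=int(bkg.size),
    )


def cnr(stats: ROIStatistics) -> float:
    """CNR = |MPV_bkg - MPV_target| / SD_bkg; zero noise raises, never inf."""
    if stats.sd_bkg == 0:
        raise DegenerateNoiseError("sd_bkg = 0: CNR undefined")
    return abs(stats.mpv_bkg - stats.mpv_target) / stats.sd_bkg


def _cnr_or_nan(stats: ROIStatistics) -> float:
    """Study-level records on noiseless input keep their ROI statistics and
    carry NaN where the ratio is undefined."""
    try:
        return cnr(stats)
    except DegenerateNoiseError:
        return float("nan")


# ---------------------------------------------------------------------------
# Plug localization


def _disk_kernel(radius_mm: float, frame: FrameMap) -> np.ndarray:
    sr, sc = frame.pixel_spacing_mm
    nr = int(np.floor(radius_mm / sr))
    nc = int(np.floor(radius_mm / sc))
    dy = np.arange(-nr, nr + 1)[:, None] * sr
    dx = np.arange(-nc, nc + 1)[None, :] * sc
    return (np.hypot(dx, dy) <= radius_mm).astype(float)


def _annulus_kernel(inner_mm: float, outer_mm: float, frame: FrameMap) -> np.ndarray:
    sr, sc = frame.pixel_spacing_mm
    nr = int(np.floor(outer_mm / sr))
    nc = int(np.floor(outer_mm / sc))
    dy = np.arange(-nr, nr + 1)[:, None] * sr
    dx = np.arange(-nc, nc + 1)[None, :] * sc
    d = np.hypot(dx, dy)
    return ((d >= inner_mm) & (d <= outer_mm)).astype(float)


def locate_plugs(
    image: np.ndarray,
    spec: PhantomSpec,
    frame: FrameMap,
    config: ROIConfig | None = None,
    plugs: Iterable[PlugSpec] | None = None,
) -> dict[str, LocatedPlug]:
    """Refine nominal plug centers by maximizing disk-minus-annulus contrast.

    Each nominal (mm) center is searched over a +/- ``refine_window_mm``
    window at pixel resolution; the candidate maximizing the absolute
    contrast between a plug-sized disk and its surrounding annulus wins.
    If the refinement hits the window edge, or the image carries no plug
    contrast at all (e.g. zero-attenuation plugs), a localization warning is
    emitted and the nominal center is kept.
    """
    if config is None:
        config = ROIConfig()
    if plugs is None:
        plugs = spec.plugs
    out: dict[str, LocatedPlug] = {}
    for plug in plugs:
        nominal_px = frame.mm_to_px(plug.center_mm)
        r = plug.radius_mm
        disk_k = _disk_kernel(r, frame)
        ann_k = _annulus_kernel(
            config.refine_ring_inner_factor * r, config.refine_ring_outer_factor * r, frame
        )
        sr, sc = frame.pixel_spacing_mm
        win_r = int(np.ceil(config.refine_window_mm / sr))
        win_c = int(np.ceil(config.refine_window_mm / sc))
        pad_r = ann_k.shape[0] // 2 + win_r
        pad_c = ann_k.shape[1] // 2 + win_c
        row0 = int(round(nominal_px[0]))
        col0 = int(round(nominal_px[1]))
        r0, r1 = row0 - pad_r, row0 + pad_r + 1
        c0, c1 = col0 - pad_c, col0 + pad_c + 1
        if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
            warnings.warn(
                f"plug {plug.id}: search region clipped by border; nominal center used",
                LocalizationWarning,
            )
            out[plug.id] = LocatedPlug(plug.id, nominal_px, 0.0, refined=False)
            continue
        crop = image[r0:r1, c0:c1]
        disk_mean = fftconvolve(crop, disk_k / disk_k.sum(), mode="valid")
        ann_mean = fftconvolve(crop, ann_k / ann_k.sum(), mode="valid")
        # align the two 'valid' maps on the common candidate grid
        def center_crop(m: np.ndarray, rows: int, cols: int) -> np.ndarray:
            er = (m.shape[0] - rows) // 2
            ec = (m.shape[1] - cols) // 2
            return m[er : er + rows, ec : ec + cols]

        rows, cols = 2 * win_r + 1, 2 * win_c + 1
        contrast = np.abs(center_crop(disk_mean, rows, cols) - center_crop(ann_mean, rows, cols))
        best = np.unravel_index(int(np.argmax(contrast)), contrast.shape)
        scale = max(abs(float(np.mean(crop))), 1.0)
        at_edge = best[0] in (0, rows - 1) or best[1] in (0, cols - 1)
        if contrast[best] <= 1e-9 * scale or at_edge:
            warnings.warn(
                f"plug {plug.id}: no usable contrast or refinement hit the search window; "
                "nominal center used",
                LocalizationWarning,
            )
            out[plug.id] = LocatedPlug(plug.id, nominal_px, 0.0, refined=False)
            continue
        center = (row0 + best[0] - win_r, col0 + best[1] - win_c)
        disp_mm = float(
            np.hypot((center[0] - nominal_px[0]) * sr, (center[1] - nominal_px[1]) * sc)
        )
        out[plug.id] = LocatedPlug(plug.id, (float(center[0]), float(center[1])), disp_mm, refined=True)
    return out


# ---------------------------------------------------------------------------
# Study-level measurement


def _plug_roi_stats(
    image: np.ndarray, plug: PlugSpec, center_px, frame: FrameMap, config: ROIConfig
) -> ROIStatistics:
    r = plug.radius_mm
    return roi_stats(
        image,
        center_px,
        config.roi_radius_factor * r,
        config.ring_inner_factor * r,
        config.ring_outer_factor * r,
        frame,
        min_n_target=config.min_n_target,
        min_n_bkg=config.min_n_bkg,
    )


def measure_study(
    images: Mapping[str, np.ndarray],
    spec: PhantomSpec,
    frame: FrameMap,
    roi_config: ROIConfig | None = None,
) -> list[CNRMeasurement]:
    """Measure every plug on every available image kind.

    Iodine plugs are measured on LE, HE and DES (when supplied) with
    contrast-refined centers; the 100%-glandular plugs are measured on DES
    only, at their nominal centers (they are invisible by design there), and
    flagged as residual-CNR records.
    """
    if roi_config is None:
        roi_config = ROIConfig()
    out: list[CNRMeasurement] = []
    for kind in ("LE", "HE", "DES"):
        if kind not in images:
            continue
        image = np.asarray(images[kind], dtype=float)
        located = locate_plugs(image, spec, frame, roi_config, plugs=spec.iodine_plugs)
        for plug in spec.iodine_plugs:
            stats = _plug_roi_stats(image, plug, located[plug.id].center_px, frame, roi_config)
            out.append(
                CNRMeasurement(
                    plug_id=plug.id,
                    image_kind=kind,
                    half=plug.half,
                    iodine_density=plug.iodine_density,
                    cnr=_cnr_or_nan(stats),
                    stats=stats,
                )
            )
    if "DES" in images:
        des = images["DES"]
        des_img = des.image if isinstance(des, DESImage) else np.asarray(des, dtype=float)
        out.extend(residual_cnr(des_img, spec, frame, roi_config))
    return out


def residual_cnr(
    des: DESImage | np.ndarray,
    spec: PhantomSpec,
    frame: FrameMap,
    roi_config: ROIConfig | None = None,
) -> list[CNRMeasurement]:
    """Residual CNR at the 100%-glandular plug positions on the DES image.

    Measures how much tissue signal the recombination failed to cancel.  No
    contrast-based center refinement: a well-cancelled plug is invisible, so
    the nominal center is used.
    """
    if roi_config is None:
        roi_config = ROIConfig()
    image = des.image if isinstance(des, DESImage) else np.asarray(des, dtype=float)
    out = []
    for plug in spec.glandular_plugs:
        center = frame.mm_to_px(plug.center_mm)
        stats = _plug_roi_stats(image, plug, center, frame, roi_config)
        out.append(
            CNRMeasurement(
                plug_id=plug.id,
                image_kind="DES",
                half=plug.half,
                iodine_density=0.0,
                cnr=_cnr_or_nan(stats),
                stats=stats,
                residual_flag=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Linearity QC


def signal_difference_linearity(
    des_measurements: Iterable[CNRMeasurement], half: str
) -> LinearityResult:
    """Least-squares line of DES signal difference vs iodine surface density.

    The QC criterion: (MPV_target - MPV_bkg) of the contrast-enhanced plugs
    should be linear in the nominal iodine density.  Requires measurements
    at >= 3 densities for the requested half.
    """
    pts = sorted(
        (m.iodine_density, m.stats.mpv_target - m.stats.mpv_bkg)
        for m in des_measurements
        if m.half == half and not m.residual_flag and m.image_kind == "DES"
    )
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 iodine densities for the {half} half, got {len(pts)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30 * max(1.0, float(np.max(np.abs(y))) ** 2):
        return LinearityResult(0.0, float(y.mean()), 0.0, tuple(pts))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return LinearityResult(float(slope), float(intercept), float(max(0.0, min(1.0, r2))), tuple(pts))
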