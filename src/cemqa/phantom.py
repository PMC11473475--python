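"""Dual-energy phantom geometry: plates, plugs and the mm <-> pixel frame map.

The phantom emulated by default is a CIRS Model 022-style stack: a 10-mm
target plate of 50/50 gland/adipose breast-equivalent material carrying two
mirrored sets of five plugs (four iodine surface densities 0.2/0.5/1.0/2.0
mg/cm^2 plus a central 100%-glandular plug), over a 25-mm contrast plate that
is half 100% adipose and half 100% glandular, between two 10-mm adipose
plates; 55 mm compressed thickness in total.

Coordinate conventions
----------------------
* Phantom frame: (x, y) in millimetres, origin at the chest-wall-side
  top-left corner, x running along the chest wall edge.
* Pixel frame: 0-based (row, col); row maps to y, col maps to x.
* ``FrameMap`` is an affine, invertible map between the two.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

from .errors import GeometryError

IODINE_DENSITIES = (0.2, 0.5, 1.0, 2.0)  # mg/cm^2, the clinical range spanned by the plugs


@dataclass(frozen=True)
class PlugSpec:
    """One plug of the target plate.

    ``iodine_density`` is a surface density in mg/cm^2 (0 for the glandular
    plug); ``half`` records which side of the contrast plate the plug
    overlies, which sets its local background.
    """

    id: str
    center_mm: tuple[float, float]
    diameter_mm: float
    kind: Literal["iodine", "glandular"]
    iodine_density: float
    half: Literal["adipose", "glandular"]

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise GeometryError(f"plug {self.id}: diameter must be positive")
        if self.kind == "glandular" and self.iodine_density != 0:
            raise GeometryError(f"plug {self.id}: glandular plug must have zero iodine density")
        if self.kind == "iodine" and self.iodine_density <= 0:
            raise GeometryError(f"plug {self.id}: iodine plug needs a positive surface density")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class ContrastBoundary:
    """Horizontal line y = position_mm splitting the contrast plate.

    ``adipose_below`` means the half with y < position_mm is 100% adipose.
    """

    position_mm: float
    adipose_below: bool = True

    def half_of(self, point_mm: Sequence[float]) -> str:
        below = point_mm[1] < self.position_mm
        return "adipose" if (below == self.adipose_below) else "glandular"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and compositional description of the phantom."""

    total_thickness_mm: float
    target_plate_glandularity: float
    contrast_plate_split: ContrastBoundary
    plugs: tuple[PlugSpec, ...]
    field_of_view_mm: tuple[float, float]  # (width, height) = (x extent, y extent)

    def __post_init__(self) -> None:
        w, h = self.field_of_view_mm
        for plug in self.plugs:
            x, y = plug.center_mm
            r = plug.radius_mm
            if not (r <= x <= w - r and r <= y <= h - r):
                raise GeometryError(f"plug {plug.id} at {plug.center_mm} lies outside the field of view")

    @property
    def iodine_plugs(self) -> tuple[PlugSpec, ...]:
        return tuple(p for p in self.plugs if p.kind == "iodine")

    @property
    def glandular_plugs(self) -> tuple[PlugSpec, ...]:
        return tuple(p for p in self.plugs if p.kind == "glandular")

    def half_of(self, point_mm: Sequence[float]) -> str:
        return self.contrast_plate_split.half_of(point_mm)

    def plug(self, plug_id: str) -> PlugSpec:
        for p in self.plugs:
            if p.id == plug_id:
                return p
        raise KeyError(plug_id)


@dataclass(frozen=True)
class FrameMap:
    """Affine map between phantom millimetres and pixel indices.

    mm = origin + index * spacing * orientation (per axis); pixel (0, 0) has
    its center at ``origin_mm``.  orientation entries are +1 or -1.
    """

    pixel_spacing_mm: tuple[float, float]  # (row, col)
    origin_mm: tuple[float, float] = (0.0, 0.0)  # phantom-frame (x, y) of pixel (0, 0)
    orientation: tuple[int, int] = (1, 1)  # (row->y, col->x) direction flags
    shape: tuple[int, int] = (1000, 800)  # (rows, cols)

    def __post_init__(self) -> None:
        if self.pixel_spacing_mm[0] <= 0 or self.pixel_spacing_mm[1] <= 0:
            raise GeometryError("pixel spacing must be positive in both axes")
        if abs(self.orientation[0]) != 1 or abs(self.orientation[1]) != 1:
            raise GeometryError("orientation flags must be +1 or -1")

    def mm_to_px(self, point_mm: Sequence[float], check: bool = True) -> tuple[float, float]:
        """Map a phantom-frame (x, y) mm point to a continuous (row, col)."""
        x, y = float(point_mm[0]), float(point_mm[1])
        row = (y - self.origin_mm[1]) / (self.pixel_spacing_mm[0] * self.orientation[0])
        col = (x - self.origin_mm[0]) / (self.pixel_spacing_mm[1] * self.orientation[1])
        if check and not (-0.5 <= row <= self.shape[0] - 0.5 and -0.5 <= col <= self.shape[1] - 0.5):
            raise GeometryError(f"point {point_mm} mm maps outside the image frame")
        return (row, col)

    def px_to_mm(self, point_px: Sequence[float]) -> tuple[float, float]:
        """Inverse of :meth:`mm_to_px`."""
        row, col = float(point_px[0]), float(point_px[1])
        y = self.origin_mm[1] + row * self.pixel_spacing_mm[0] * self.orientation[0]
        x = self.origin_mm[0] + col * self.pixel_spacing_mm[1] * self.orientation[1]
        return (x, y)

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) mm coordinate grids of every pixel center."""
        rows = np.arange(self.shape[0])
        cols = np.arange(self.shape[1])
        y = self.origin_mm[1] + rows * self.pixel_spacing_mm[0] * self.orientation[0]
        x = self.origin_mm[0] + cols * self.pixel_spacing_mm[1] * self.orientation[1]
        return np.meshgrid(x, y)  # X[row, col], Y[row, col]


def mm_to_px(frame: FrameMap, point_mm: Sequence[float]) -> tuple[float, float]:
    """Functional wrapper over :meth:`FrameMap.mm_to_px`."""
    return frame.mm_to_px(point_mm)


def px_to_mm(frame: FrameMap, point_px: Sequence[float]) -> tuple[float, float]:
    """Functional wrapper over :meth:`FrameMap.px_to_mm`."""
    return frame.px_to_mm(point_px)


def default_frame(pixel_spacing_mm: float = 0.1, shape: tuple[int, int] = (1000, 800)) -> FrameMap:
    """Default imaging frame: 100-um pitch, 1000x800 px => 100 x 80 mm field."""
    return FrameMap(pixel_spacing_mm=(pixel_spacing_mm, pixel_spacing_mm), shape=shape)


def default_cirs022_layout(
    field_of_view_mm: tuple[float, float] = (80.0, 100.0),
    plug_diameter_mm: float = 10.0,
    arm_span_mm: float = 30.0,
) -> PhantomSpec:
    """Packaged default phantom layout.

    Two mirrored 5-plug sets, one per contrast-plate half: four iodine plugs
    (0.2, 0.5, 1.0, 2.0 mg/cm^2) at the cardinal points of a cross whose
    opposite arms span ``arm_span_mm``, and a 100%-glandular plug at the
    cross center.  The 30-mm span keeps every plug's background ring (up to
    1.6x the plug radius) clear of its neighbours and of the contrast-plate
    boundary within the default 100 x 80 mm field.  Exact plug coordinates
    are a package choice (the physical phantom's drawing is not public);
    everything is overridable and serializable, so real images with a
    different layout stay analyzable.
    """
    w, h = field_of_view_mm
    boundary = ContrastBoundary(position_mm=h / 2.0, adipose_below=True)
    off = arm_span_mm / 2.0
    plugs: list[PlugSpec] = []
    for half, cy in (("adipose", h / 4.0), ("glandular", 3.0 * h / 4.0)):
        cx = w / 2.0
        # mirror symmetry about the boundary: the glandular set reflects the adipose set
        sgn = 1.0 if half == "adipose" else -1.0
        positions = {
            2.0: (cx, cy - sgn * off),  # arm nearest the chest wall edge for the adipose set
            1.0: (cx, cy + sgn * off),
            0.5: (cx - off, cy),
            0.2: (cx + off, cy),
        }
        for dens, center in positions.items():
            plugs.append(
                PlugSpec(
                    id=f"{half[:4]}_{dens:g}",
                    center_mm=center,
                    diameter_mm=plug_diameter_mm,
                    kind="iodine",
                    iodine_density=dens,
                    half=half,  # type: ignore[arg-type]
                )
            )
        plugs.append(
            PlugSpec(
                id=f"{half[:4]}_gland",
                center_mm=(cx, cy),
                diameter_mm=plug_diameter_mm,
                kind="glandular",
                iodine_density=0.0,
                half=half,  # type: ignore[arg-type]
            )
        )
    return PhantomSpec(
        total_thickness_mm=55.0,
        target_plate_glandularity=0.5,
        contrast_plate_split=boundary,
        plugs=tuple(plugs),
        field_of_view_mm=field_of_view_mm,
    )


# ---------------------------------------------------------------------------
# Serialization (canonical format: YAML, round-trip tested)

def spec_to_yaml(spec: PhantomSpec) -> str:
    doc = {
        "total_thickness_mm": spec.total_thickness_mm,
        "target_plate_glandularity": spec.target_plate_glandularity,
        "contrast_plate_split": {
            "position_mm": spec.contrast_plate_split.position_mm,
            "adipose_below": spec.contrast_plate_split.adipose_below,
        },
        "field_of_view_mm": list(spec.field_of_view_mm),
        "plugs": [
            {
                "id": p.id,
                "center_mm": list(p.center_mm),
                "diameter_mm": p.diameter_mm,
                "kind": p.kind,
                "iodine_density": p.iodine_density,
                "half": p.half,
            }
            for p in spec.plugs
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> PhantomSpec:
    doc = yaml.safe_load(text)
    plugs = tuple(
        PlugSpec(
            id=p["id"],
            center_mm=tuple(p["center_mm"]),
            diameter_mm=float(p["diameter_mm"]),
            kind=p["kind"],
            iodine_density=float(p["iodine_density"]),
            half=p["half"],
        )
        for p in doc["plugs"]
    )
    return PhantomSpec(
        total_thickness_mm=float(doc["total_thickness_mm"]),
        target_plate_glandularity=float(doc["target_plate_glandularity"]),
        contrast_plate_split=ContrastBoundary(
            position_mm=float(doc["contrast_plate_split"]["position_mm"]),
            adipose_below=bool(doc["contrast_plate_split"]["adipose_below"]),
        ),
        plugs=plugs,
        field_of_view_mm=tuple(doc["field_of_view_mm"]),
    )
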