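"""Readers and writers: TIFF + JSON sidecar studies, DES output, DICOM export.

A synthetic study is stored as ``<stem>_LE.tif`` / ``<stem>_HE.tif`` (16-bit,
detector-linear counts) plus ``<stem>.json`` holding the frame, phantom
layout, profile name, seed and per-plug generation truth.  DES images are
written as 32-bit float TIFF with their recombination parameters in JSON.
An optional minimal DICOM secondary-capture export carries the standard
exposure tags so the dosimetry path can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile

from .phantom import FrameMap, PhantomSpec, spec_from_yaml, spec_to_yaml
from .recombine import DESImage, RecombinationParams
from .simulate import CEMStudy, PlugTruth


def _frame_to_dict(frame: FrameMap) -> dict:
    return {
        "pixel_spacing_mm": list(frame.pixel_spacing_mm),
        "origin_mm": list(frame.origin_mm),
        "orientation": list(frame.orientation),
        "shape": list(frame.shape),
    }


def _frame_from_dict(doc: dict) -> FrameMap:
    return FrameMap(
        pixel_spacing_mm=tuple(doc["pixel_spacing_mm"]),
        origin_mm=tuple(doc["origin_mm"]),
        orientation=tuple(doc["orientation"]),
        shape=tuple(doc["shape"]),
    )


def write_study(study: CEMStudy, out_dir: str | Path, stem: str = "study") -> Path:
    """Write a synthetic study as 16-bit TIFF pair + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kind, image in (("LE", study.le_image), ("HE", study.he_image)):
        counts = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
        tifffile.imwrite(out / f"{stem}_{kind}.tif", counts)
    sidecar = {
        "frame": _frame_to_dict(study.frame),
        "phantom_yaml": spec_to_yaml(study.spec),
        "profile_name": study.profile_name,
        "aec_mode": study.aec_mode,
        "seed": study.seed,
        "truth": {pid: asdict(t) for pid, t in study.truth.items()},
    }
    path = out / f"{stem}.json"
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return path


def read_study(out_dir: str | Path, stem: str = "study") -> CEMStudy:
    """Read a study written by :func:`write_study` (pixel values as uint16)."""
    out = Path(out_dir)
    with open(out / f"{stem}.json") as fh:
        sidecar = json.load(fh)
    truth = {
        pid: PlugTruth(
            plug_id=t["plug_id"],
            center_px=tuple(t["center_px"]),
            mean_bkg=t["mean_bkg"],
            mean_plug=t["mean_plug"],
            sd_bkg=t["sd_bkg"],
        )
        for pid, t in sidecar["truth"].items()
    }
    return CEMStudy(
        le_image=tifffile.imread(out / f"{stem}_LE.tif").astype(float),
        he_image=tifffile.imread(out / f"{stem}_HE.tif").astype(float),
        frame=_frame_from_dict(sidecar["frame"]),
        spec=spec_from_yaml(sidecar["phantom_yaml"]),
        profile_name=sidecar["profile_name"],
        aec_mode=sidecar["aec_mode"],
        seed=sidecar["seed"],
        truth=truth,
    )


def write_des(des: DESImage, path: str | Path) -> None:
    """Write a DES image as 32-bit float TIFF + JSON params next to it."""
    path = Path(path)
    tifffile.imwrite(path, des.image.astype(np.float32))
    meta = {
        "weight_w": des.params.weight_w,
        "offset": des.params.offset,
        "epsilon": des.params.epsilon,
        "degenerate": des.params.degenerate,
        "provenance": des.provenance,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_des(path: str | Path) -> DESImage:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return DESImage(
        image=tifffile.imread(path).astype(float),
        params=RecombinationParams(
            weight_w=meta["weight_w"],
            offset=meta["offset"],
            epsilon=meta["epsilon"],
            degenerate=meta["degenerate"],
        ),
        provenance=meta.get("provenance", ""),
    )


def export_dicom(study: CEMStudy, energy: str, path: str | Path, exposure=None) -> None:
    """Minimal DICOM secondary-capture export with exposure tags populated."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.SeriesDescription = f"synthetic CEM {energy}"
    image = study.image(energy)
    counts = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    ds.Rows, ds.Columns = counts.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = counts.tobytes()
    ds.PixelSpacing = [str(study.frame.pixel_spacing_mm[0]), str(study.frame.pixel_spacing_mm[1])]
    ds.BodyPartThickness = str(study.spec.total_thickness_mm)
    if exposure is not None:
        ds.KVP = str(exposure.tube_voltage_kvp)
        ds.Exposure = str(int(round(exposure.exposure_mas)))
        ds.ExposureInuAs = str(int(round(exposure.exposure_mas * 1000)))
        # DICOM CS defined terms are full uppercase element names
        names = {"Mo": "MOLYBDENUM", "Rh": "RHODIUM", "W": "TUNGSTEN",
                 "Ag": "SILVER", "Cu": "COPPER", "Ti": "TITANIUM"}
        ds.AnodeTargetMaterial = names.get(exposure.anode, exposure.anode)
        ds.FilterMaterial = names.get(exposure.filter_material, exposure.filter_material)
        if exposure.aec_mode:
            ds.ExposureControlModeDescription = exposure.aec_mode
    ds.save_as(str(path), enforce_file_format=True)
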