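"""Reading and writing cine studies.

Two on-disk layouts are supported, both per study directory:

``dicom``
    One CT Image file per frame (``frame_00000.dcm``) with slice position
    (ImagePositionPatient / SliceLocation), acquisition time
    (AcquisitionTime, microsecond resolution) and PixelSpacing in their
    standard tags; AcquisitionNumber holds the frame index and
    SeriesNumber the slab.
``tiff``
    A single multi-page ``study.tif`` (int16 HU) with the same metadata
    in a JSON sidecar.

Either layout carries a ``study.json`` sidecar with the acquisition
configuration, frame geometry, scene, per-frame metadata and — iff the
study was simulated — the ground-truth waveform and true wire centres.
``read_study(write_study(s))`` round-trips pixels bit for bit and
metadata to the precision of the carrying tag (exact for the default
jitter-free timing grid).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import FrameGeometry
from .motion import MotionWaveform
from .simulator import (
    AcquisitionConfig,
    CineFrame,
    CineStudy,
    SceneConfig,
    TargetConfig,
)

__all__ = ["write_study", "read_study"]


def _seconds_to_tm(t: float) -> str:
    if t < 0 or t >= 86400:
        raise ValueError("acquisition time must map into one day")
    hh = int(t // 3600)
    mm = int((t % 3600) // 60)
    ss = t - hh * 3600 - mm * 60
    return f"{hh:02d}{mm:02d}{ss:09.6f}"


def _tm_to_seconds(tm: str) -> float:
    hh, mm = int(tm[0:2]), int(tm[2:4])
    return hh * 3600 + mm * 60 + float(tm[4:])


def _scene_to_config(scene: SceneConfig) -> dict:
    d = {
        "wire_x_mm": list(scene.wire_x_mm),
        "wire_baseline_y_mm": scene.wire_baseline_y_mm,
        "wire_diameter_mm": scene.wire_diameter_mm,
        "body_center_mm": list(scene.body_center_mm),
        "body_semiaxes_mm": list(scene.body_semiaxes_mm),
        "lung_offsets_mm": list(scene.lung_offsets_mm),
        "lung_center_y_mm": scene.lung_center_y_mm,
        "lung_semiaxes_mm": list(scene.lung_semiaxes_mm),
    }
    if scene.target is not None:
        t = scene.target
        d["target"] = {
            "diameter_mm": t.diameter_mm,
            "center_mm": list(t.center_mm),
            "z_mm": t.z_mm,
            "waveform_y": t.waveform_y.to_config() if t.waveform_y else None,
            "waveform_z": t.waveform_z.to_config() if t.waveform_z else None,
        }
    return d


def _scene_from_config(d: dict) -> SceneConfig:
    target = None
    if d.get("target") is not None:
        t = d["target"]
        target = TargetConfig(
            diameter_mm=t["diameter_mm"],
            center_mm=tuple(t["center_mm"]),
            z_mm=t["z_mm"],
            waveform_y=MotionWaveform.from_config(t["waveform_y"]) if t["waveform_y"] else None,
            waveform_z=MotionWaveform.from_config(t["waveform_z"]) if t["waveform_z"] else None,
        )
    return SceneConfig(
        wire_x_mm=tuple(d["wire_x_mm"]),
        wire_baseline_y_mm=d["wire_baseline_y_mm"],
        wire_diameter_mm=d["wire_diameter_mm"],
        body_center_mm=tuple(d["body_center_mm"]),
        body_semiaxes_mm=tuple(d["body_semiaxes_mm"]),
        lung_offsets_mm=tuple(d["lung_offsets_mm"]),
        lung_center_y_mm=d["lung_center_y_mm"],
        lung_semiaxes_mm=tuple(d["lung_semiaxes_mm"]),
        target=target,
    )


def _sidecar(study: CineStudy) -> dict:
    doc = {
        "format_version": 1,
        "acquisition": study.acquisition.to_config(),
        "geometry": study.geometry.to_config(),
        "scene": _scene_to_config(study.scene),
        "frames": [
            {
                "frame_id": f.frame_id,
                "slab": f.slab,
                "slice_idx": f.slice_idx,
                "slice_z_mm": f.slice_z_mm,
                "time_s": f.time_s,
                "pixel_spacing_mm": f.pixel_spacing_mm,
                "true_centers_px": (
                    [list(c) for c in f.true_centers_px] if f.true_centers_px else None
                ),
                "true_displacement_mm": f.true_displacement_mm,
            }
            for f in study.frames
        ],
    }
    if study.ground_truth is not None:
        doc["ground_truth"] = study.ground_truth.to_config()
    return doc


def _frame_to_dataset(frame: CineFrame, series_number: Optional[int] = None):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientName = "PHANTOM^CINE"
    ds.PatientID = "RESP4D"
    ds.SeriesNumber = series_number if series_number is not None else frame.slab + 1
    ds.InstanceNumber = frame.frame_id + 1
    ds.AcquisitionNumber = frame.frame_id
    ds.AcquisitionTime = _seconds_to_tm(frame.time_s)
    ds.SliceLocation = frame.slice_z_mm
    ds.ImagePositionPatient = [0.0, 0.0, frame.slice_z_mm]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [frame.pixel_spacing_mm, frame.pixel_spacing_mm]
    ds.SliceThickness = frame.pixel_spacing_mm  # overwritten below if known
    ds.Rows, ds.Columns = frame.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed (HU can be negative)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleIntercept = 0.0
    ds.RescaleSlope = 1.0
    ds.PixelData = np.ascontiguousarray(frame.pixels, dtype=np.int16).tobytes()
    return ds


def write_study(study: CineStudy, path, format: str = "tiff") -> Path:
    """Serialise a study to ``path`` (a directory) as DICOM or TIFF+JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "tiff":
        import tifffile

        stack = np.stack([f.pixels for f in study.frames])
        tifffile.imwrite(path / "study.tif", stack)
    elif format == "dicom":
        for f in study.frames:
            ds = _frame_to_dataset(f)
            ds.SliceThickness = study.acquisition.slice_thickness_mm
            ds.save_as(path / f"frame_{f.frame_id:05d}.dcm", enforce_file_format=True)
    else:
        raise ValueError(f"unknown format: {format!r} (expected 'dicom' or 'tiff')")
    with open(path / "study.json", "w") as fh:
        json.dump(_sidecar(study), fh, indent=1)
    return path


def read_study(path) -> CineStudy:
    """Load a study written by :func:`write_study`.

    For DICOM input the pixel data, slice position, acquisition time and
    pixel spacing come from the DICOM tags; the sidecar supplies the
    study-level configuration and any simulation ground truth.
    """
    path = Path(path)
    sidecar_path = path / "study.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no study.json sidecar in {path}")
    with open(sidecar_path) as fh:
        doc = json.load(fh)
    acq = AcquisitionConfig.from_config(doc["acquisition"])
    geom = FrameGeometry.from_config(doc["geometry"])
    scene = _scene_from_config(doc["scene"])
    gt = (
        MotionWaveform.from_config(doc["ground_truth"])
        if "ground_truth" in doc
        else None
    )

    dicom_files = sorted(path.glob("frame_*.dcm"))
    tiff_file = path / "study.tif"
    frames = []
    if dicom_files:
        import pydicom

        by_id = {}
        for p in dicom_files:
            ds = pydicom.dcmread(p)
            fid = int(ds.AcquisitionNumber)
            pixels = ds.pixel_array.astype(np.int16)
            by_id[fid] = {
                "pixels": pixels,
                "time_s": _tm_to_seconds(str(ds.AcquisitionTime)),
                "slice_z_mm": float(ds.ImagePositionPatient[2]),
                "pixel_spacing_mm": float(ds.PixelSpacing[0]),
            }
        for meta in doc["frames"]:
            d = by_id[meta["frame_id"]]
            frames.append(_frame_from_meta(meta, d["pixels"], override=d))
    elif tiff_file.exists():
        import tifffile

        stack = tifffile.imread(tiff_file)
        if stack.ndim == 2:
            stack = stack[None]
        for meta, pixels in zip(doc["frames"], stack):
            frames.append(_frame_from_meta(meta, pixels))
    else:
        raise FileNotFoundError(f"no frame data (DICOM or study.tif) in {path}")
    return CineStudy(
        frames=frames, geometry=geom, acquisition=acq, scene=scene, ground_truth=gt
    )


def _frame_from_meta(meta: dict, pixels: np.ndarray, override: Optional[dict] = None) -> CineFrame:
    src = dict(meta)
    if override:
        src.update({k: override[k] for k in ("time_s", "slice_z_mm", "pixel_spacing_mm")})
    return CineFrame(
        frame_id=meta["frame_id"],
        slab=meta["slab"],
        slice_idx=meta["slice_idx"],
        slice_z_mm=src["slice_z_mm"],
        time_s=src["time_s"],
        pixel_spacing_mm=src["pixel_spacing_mm"],
        pixels=np.asarray(pixels, dtype=np.int16),
        true_centers_px=(
            tuple(tuple(c) for c in meta["true_centers_px"])
            if meta.get("true_centers_px")
            else None
        ),
        true_displacement_mm=meta.get("true_displacement_mm"),
    )
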