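"""Reading and writing CT volumes and run configuration.

NIfTI is the interchange format for synthetic volumes (pixel pitch and
slice spacing travel in the header; table height, ground truth and
provenance in a sidecar JSON next to the image).  DICOM series are read for
real-world use, pulling pixel spacing (0028,0030), rescale slope/intercept
(0028,1053)/(0028,1052) and table height (0018,1130) from the headers.  A
minimal DICOM *writer* exists purely to build synthetic round-trip test
fixtures; it is not a clinical exporter.

Axis order on disk: NIfTI data are stored (x=column, y=row, z=slice) and
transposed to the in-memory [slice, row, column] layout on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import yaml

from .phantom import CohortSpec
from .volume import CTVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_dicom_series",
    "load_cohort_spec",
    "dump_cohort_spec",
]

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: CTVolume, path: Union[str, Path]) -> Path:
    """Write a volume as NIfTI plus a sidecar JSON with geometry/provenance."""
    path = Path(path)
    pitch = volume.pixel_pitch
    affine = np.diag([pitch, pitch, volume.slice_spacing, 1.0])
    data = np.transpose(volume.hu, (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((pitch, pitch, volume.slice_spacing))
    nib.save(img, str(path))

    sidecar = {
        "axis_order": "[slice, row, column]; row index increases downward",
        "dfov_mm": volume.dfov,
        "slice_spacing_mm": volume.slice_spacing,
        "table_height_mm": volume.table_height,
        "isocenter_rc": list(volume.isocenter_rc),
        "hu_offset_metadata": "voxels stored in HU (air = -1000)",
        "meta": volume.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    hu = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    pitch, slice_spacing = float(zooms[0]), float(zooms[2])
    cols = hu.shape[2]
    kwargs: dict = {"dfov": pitch * cols, "slice_spacing": slice_spacing}

    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        kwargs["dfov"] = side.get("dfov_mm", kwargs["dfov"])
        kwargs["slice_spacing"] = side.get("slice_spacing_mm", kwargs["slice_spacing"])
        kwargs["table_height"] = side.get("table_height_mm")
        if side.get("isocenter_rc") is not None:
            kwargs["isocenter_rc"] = tuple(side["isocenter_rc"])
        kwargs["meta"] = side.get("meta", {})
    else:
        logger.warning("no sidecar JSON for %s: table height unknown", path.name)
    return CTVolume(hu=hu, **kwargs)


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    uids = {ds.SeriesInstanceUID for ds in datasets if "SeriesInstanceUID" in ds}
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} DICOM series: {sorted(uids)}")

    def z_of(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    first = datasets[0]
    if "RescaleSlope" not in first or "RescaleIntercept" not in first:
        raise ValueError("DICOM series missing rescale slope/intercept: cannot map to HU")
    slope = float(first.RescaleSlope)
    intercept = float(first.RescaleIntercept)
    spacing = [float(v) for v in first.PixelSpacing]

    zs = np.array([z_of(ds) for ds in datasets])
    if len(zs) > 1:
        steps = np.diff(zs)
        if steps.size and not np.allclose(steps, steps[0], atol=0.01):
            raise ValueError(f"inconsistent slice spacing: steps {np.round(steps, 3)}")
        slice_spacing = float(abs(steps[0])) if steps.size else 1.0
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    hu = np.stack(
        [ds.pixel_array.astype(np.float32) * slope + intercept for ds in datasets]
    )
    table_height = None
    if "TableHeight" in first:
        table_height = float(first.TableHeight)
    else:
        logger.warning("DICOM table height (0018,1130) absent: pad estimation disabled")

    cols = hu.shape[2]
    vol = CTVolume(
        hu=hu,
        dfov=spacing[1] * cols,
        slice_spacing=slice_spacing,
        table_height=table_height,
        meta={"hu_offset_metadata": f"rescale slope {slope}, intercept {intercept}"},
    )
    # Sidecar overrides, if the acquisition shipped one.
    sc = directory / "sidecar.json"
    if sc.exists():
        side = json.loads(sc.read_text())
        if side.get("table_height_mm") is not None:
            vol.table_height = float(side["table_height_mm"])
        vol.meta.update(side.get("meta", {}))
    return vol


def read_volume(path: Union[str, Path]) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def write_dicom_series(volume: CTVolume, directory: Union[str, Path]) -> Path:
    """Write a minimal synthetic CT DICOM series (test fixture only).

    Stored pixels are uint16 with rescale intercept -1024 / slope 1, so HU
    below -1024 clip at the air floor.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    pitch = volume.pixel_pitch

    for k in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "SYNTHETIC^PHANTOM"
        ds.PatientID = "SYNTH"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * volume.slice_spacing]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [pitch, pitch]
        ds.SliceThickness = volume.slice_spacing
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        if volume.table_height is not None:
            ds.TableHeight = volume.table_height
        ds.Rows, ds.Columns = volume.hu.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.clip(np.rint(volume.hu[k] + 1024.0), 0, 65535).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        pydicom.dcmwrite(str(directory / f"slice_{k:04d}.dcm"), ds)
    return directory


def load_cohort_spec(path: Union[str, Path]) -> CohortSpec:
    """Build a CohortSpec from a YAML mapping (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tuple_fields = {
        "chest_thickness_dist", "body_width_dist", "scan_length_dist",
        "direct_offset_dist", "ruler_bias_dist", "pad_dent_dist", "ctdivol_dist",
    }
    kwargs = {}
    valid = set(CohortSpec.__dataclass_fields__)
    for key, value in raw.items():
        if key not in valid:
            raise ValueError(f"unknown cohort spec key {key!r}")
        kwargs[key] = tuple(value) if key in tuple_fields else value
    return CohortSpec(**kwargs)


def dump_cohort_spec(spec: CohortSpec, path: Union[str, Path]) -> Path:
    path = Path(path)
    d = asdict(spec)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path
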