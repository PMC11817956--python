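"""On-disk formats.

Clinical-style cases are one directory per case: numbered DICOM files
(RescaleSlope/Intercept, WindowCenter/Width, PixelSpacing,
SOPInstanceUID) plus one JSON annotation file per annotated slice,
named by SOPInstanceUID.  BraTS-style cases are NIfTI image/label
pairs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .preprocess import AnnotationSet, RawSeries, SliceMeta
from .phantom import SyntheticCase

_MR_STORAGE = "1.2.840.10008.5.1.4.1.1.4"


def _slice_to_dataset(arr: np.ndarray, meta: SliceMeta, index: int,
                      series_uid: str) -> pydicom.FileDataset:
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _MR_STORAGE
    file_meta.MediaStorageSOPInstanceUID = meta.sop_uid or generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.FileDataset(None, Dataset(), file_meta=file_meta,
                             preamble=b"\x00" * 128)
    ds.SOPClassUID = _MR_STORAGE
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "MR"
    ds.SeriesDescription = "T2-FLAIR AX"
    ds.InstanceNumber = index + 1
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f"{meta.pixel_spacing_mm:.6f}"] * 2
    ds.RescaleSlope = f"{meta.rescale_slope:.6f}"
    ds.RescaleIntercept = f"{meta.rescale_intercept:.6f}"
    ds.WindowCenter = f"{meta.window_center:.6f}"
    ds.WindowWidth = f"{meta.window_width:.6f}"
    ds.PixelData = np.clip(arr, 0, 4095).astype("<u2").tobytes()
    return ds


def write_chgh_case(case: SyntheticCase, out_dir) -> Path:
    """Write one clinical-style case directory (DICOM + JSON annotations)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[case.series.uids()[0]])
    for i, (arr, meta) in enumerate(case.series.slices):
        ds = _slice_to_dataset(np.asarray(arr), meta, i, series_uid)
        ds.save_as(out_dir / f"{i:03d}.dcm", enforce_file_format=True)
    for uid, polys in case.annotations.entries.items():
        payload = [{"points": np.asarray(p).tolist(), "width": float(w)}
                   for p, w in polys]
        (out_dir / f"{uid}.json").write_text(json.dumps(payload))
    (out_dir / "meta.json").write_text(json.dumps({"group": case.group}))
    return out_dir


def read_chgh_case(case_dir) -> tuple[RawSeries, AnnotationSet, str]:
    """Read a case directory back into (series, annotations, group)."""
    case_dir = Path(case_dir)
    datasets = [pydicom.dcmread(p) for p in sorted(case_dir.glob("*.dcm"))]
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    slices = []
    for ds in datasets:
        meta = SliceMeta(rescale_slope=float(ds.RescaleSlope),
                         rescale_intercept=float(ds.RescaleIntercept),
                         window_center=float(ds.WindowCenter),
                         window_width=float(ds.WindowWidth),
                         pixel_spacing_mm=float(ds.PixelSpacing[0]),
                         sop_uid=str(ds.SOPInstanceUID))
        slices.append((ds.pixel_array.astype(np.int32), meta))
    series = RawSeries(slices=slices)

    ann = AnnotationSet()
    for p in case_dir.glob("*.json"):
        if p.name == "meta.json":
            continue
        entries = json.loads(p.read_text())
        ann.entries[p.stem] = [(np.asarray(e["points"], dtype=float),
                                float(e["width"])) for e in entries]
    group = "unknown"
    meta_path = case_dir / "meta.json"
    if meta_path.exists():
        group = json.loads(meta_path.read_text()).get("group", "unknown")
    return series, ann, group


def write_brats_pair(image: np.ndarray, label: np.ndarray, out_dir,
                     stem: str = "case") -> tuple[Path, Path]:
    """Write a BraTS-style volume pair as .nii.gz files."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    img_path = out_dir / f"{stem}_image.nii.gz"
    lab_path = out_dir / f"{stem}_label.nii.gz"
    nib.save(nib.Nifti1Image(image.astype(np.float32), affine), str(img_path))
    nib.save(nib.Nifti1Image(label.astype(np.uint8), affine), str(lab_path))
    return img_path, lab_path


def read_brats_pair(img_path, lab_path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    image = np.asarray(nib.load(str(img_path)).dataobj, dtype=np.float32)
    label = np.asarray(nib.load(str(lab_path)).dataobj, dtype=np.uint8)
    return image, label
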