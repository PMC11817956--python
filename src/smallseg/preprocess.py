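"""Raw-series to canonical-volume preprocessing.

Two input families are converted into the canonical 128x128x64
image/label pair every model consumes:

* BraTS-style labeled volumes (240x240x155, labels in {0,1,2,4}):
  slice decimation ``u_i = s[start + 2 i]``, label merging, in-plane
  resampling.
* Clinical DICOM-style series with JSON polygon annotations: the DICOM
  grayscale chain (modality LUT -> VOI LUT -> presentation LUT),
  annotation rasterization, slice interpolation for thin stacks,
  zero-padding to 64 slices, in-plane resampling.

Tumor size class (small: largest per-slice area < 3.5 cm^2) is always
computed at the native in-plane resolution, before any resampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import binary_dilation, disk
from skimage.transform import resize

log = logging.getLogger(__name__)

SMALL_TUMOR_CM2 = 3.5          # largest-slice area threshold for "small"
CANONICAL_SHAPE = (128, 128, 64)
DISPLAY_MAX = 4095             # 12-bit grayscale


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SliceMeta:
    """DICOM-style per-slice grayscale metadata."""

    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    window_center: float = 2048.0
    window_width: float = 4096.0
    display_max: int = DISPLAY_MAX
    pixel_spacing_mm: float = 0.9
    sop_uid: str = ""

    def __post_init__(self):
        if self.rescale_slope <= 0:
            raise ValueError("rescale_slope must be positive")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.display_max < 1:
            raise ValueError("display_max must be >= 1")


@dataclass
class RawSeries:
    """Ordered axial slice stack: (2D array, SliceMeta) pairs."""

    slices: list[tuple[np.ndarray, SliceMeta]]
    modality_tag: str = "T2-FLAIR"

    def __post_init__(self):
        shapes = {s[0].shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices disagree in-plane: {shapes}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def pixel_spacing_mm(self) -> float:
        return self.slices[0][1].pixel_spacing_mm

    def uids(self) -> list[str]:
        return [m.sop_uid for _, m in self.slices]

    def volume(self) -> np.ndarray:
        """Raw pixel stack, shape (H, W, n_slices)."""
        return np.stack([a for a, _ in self.slices], axis=-1)


@dataclass
class AnnotationSet:
    """Closed polygon tumor outlines keyed by SOPInstanceUID.

    Each entry is a list of polylines; a polyline is (points, width)
    with points as an (n, 2) array of (row, col) pixel coordinates.
    """

    entries: dict[str, list[tuple[np.ndarray, float]]] = field(default_factory=dict)

    def validate_against(self, series: RawSeries):
        known = set(series.uids())
        orphans = sorted(set(self.entries) - known)
        if orphans:
            raise ValueError(f"annotation UIDs with no matching slice: {orphans}")


@dataclass
class CanonicalCase:
    """The 128x128x64 image/label pair consumed by every model."""

    image: np.ndarray
    label: np.ndarray
    source_id: str = ""
    size_class: str = "none"                # {small, large, none}
    native_max_slice_area_cm2: float = 0.0

    def __post_init__(self):
        if self.image.shape != self.label.shape:
            raise ValueError("image/label shape mismatch")
        vals = np.unique(self.label)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"label must be binary, got values {vals}")


# ---------------------------------------------------------------------------
# grayscale standardization (the DICOM LUT chain)
# ---------------------------------------------------------------------------

def modality_lut(v_org, m: float, b0: float):
    """Affine rescale of stored pixel values to physical units: v = m*v + b0."""
    return np.asarray(v_org, dtype=np.float64) * m + b0


def voi_lut(v, c: float, w: float, gm: int = DISPLAY_MAX):
    """Piecewise-linear intensity windowing.

    0 below the window, ``gm`` above it, and a linear ramp of slope
    ``gm/w`` inside: G(v) = (gm/w) * (v + w/2 - c).  Values exactly at
    the window edges fall on the ramp, so G is continuous.
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    v = np.asarray(v, dtype=np.float64)
    lo = c - w / 2.0
    hi = c + w / 2.0
    ramp = (gm / w) * (v + w / 2.0 - c)
    return np.where(v < lo, 0.0, np.where(v > hi, float(gm), ramp))


def presentation_normalize(values, gm: int = DISPLAY_MAX) -> np.ndarray:
    """Min-max rescale to integer [0, gm]; a constant input maps to 0."""
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.int32)
    scaled = (values - vmin) / (vmax - vmin) * gm
    return np.rint(scaled).astype(np.int32)


# ---------------------------------------------------------------------------
# geometry ops
# ---------------------------------------------------------------------------

def decimate_slices(volume: np.ndarray, start: int = 16, count: int = 64,
                    axis: int = -1) -> np.ndarray:
    """Take every other slice: output i is input slice ``start + 2 i``."""
    n = volume.shape[axis]
    last = start + 2 * (count - 1)
    if start < 0 or last >= n:
        raise ValueError(
            f"decimation out of range: need slice {last} but volume has {n} "
            f"(start={start}, count={count})")
    idx = start + 2 * np.arange(count)
    return np.take(volume, idx, axis=axis)


def merge_brats_labels(label: np.ndarray) -> np.ndarray:
    """Collapse the {necrotic core=1, edema=2, enhancing=4} labels to 1."""
    vals = np.unique(label)
    bad = sorted(set(vals.tolist()) - {0, 1, 2, 4})
    if bad:
        raise ValueError(f"unexpected label values: {bad}")
    return (label > 0).astype(np.uint8)


def rasterize_annotations(polylines, canvas_shape) -> np.ndarray:
    """Fill closed polygon outlines into a binary mask.

    The mask is the union of filled polygons (the fill includes the
    boundary); segment widths above one pixel add a dilated stroke
    (stroke radius from the annotation's segment width, minimum one
    pixel).  Polylines with fewer than three distinct vertices are
    skipped with a warning.
    """
    mask = np.zeros(canvas_shape, dtype=bool)
    for points, width in polylines:
        pts = np.asarray(points, dtype=float)
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(np.unique(np.round(pts, 6), axis=0)) < 3:
            warnings.warn("skipping degenerate polyline (<3 distinct vertices)")
            continue
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=canvas_shape)
        mask[rr, cc] = True
        r = max(0, int(round((width - 1) / 2)))
        if r > 0:
            stroke = np.zeros(canvas_shape, dtype=bool)
            closed = np.vstack([pts, pts[:1]])
            for a, b in zip(closed[:-1], closed[1:]):
                rr, cc = draw_line(int(round(a[0])), int(round(a[1])),
                                   int(round(b[0])), int(round(b[1])))
                keep = ((rr >= 0) & (rr < canvas_shape[0])
                        & (cc >= 0) & (cc < canvas_shape[1]))
                stroke[rr[keep], cc[keep]] = True
            mask |= binary_dilation(stroke, disk(r))
    return mask


def interpolate_slices(volume: np.ndarray, label: np.ndarray | None = None,
                       order: str = "cubic"):
    """Double the slice count of thin (24-25 slice) stacks.

    Cubic-spline interpolation along the slice axis emits 2S-1 slices
    with the originals reproduced exactly at even indices; 25-slice
    stacks are truncated to 48 so all cases land in the 47-51 range.
    Labels are interpolated the same way and re-binarized at 0.5.
    Stacks outside 24-25 slices pass through unchanged.
    """
    s = volume.shape[-1]
    if s not in (24, 25):
        return (volume, label) if label is not None else volume

    def _interp(vol, kind):
        x = np.arange(s, dtype=float)
        xq = np.arange(2 * s - 1, dtype=float) / 2.0
        if kind == "cubic":
            f = CubicSpline(x, vol.astype(np.float64), axis=-1)
            out = f(xq)
        else:  # linear fallback, pluggable
            lo = np.floor(xq).astype(int)
            hi = np.minimum(lo + 1, s - 1)
            t = xq - lo
            out = vol[..., lo] * (1 - t) + vol[..., hi] * t
        return out

    out_img = _interp(volume, order)
    out_lab = _interp(label.astype(np.float64), order) if label is not None else None
    if s == 25:  # 2*25-1 = 49 -> keep 48 to stay within the 47-51 slice range
        out_img = out_img[..., :48]
        if out_lab is not None:
            out_lab = out_lab[..., :48]
    if out_lab is not None:
        return out_img, (out_lab >= 0.5).astype(np.uint8)
    return out_img


def pad_to_depth(volume: np.ndarray, target: int = 64) -> np.ndarray:
    """Append all-zero slices at the end until the stack has ``target``."""
    d = volume.shape[-1]
    if d > target:
        raise ValueError(f"volume has {d} slices, more than target {target}")
    if d == target:
        return volume
    padw = [(0, 0)] * (volume.ndim - 1) + [(0, target - d)]
    return np.pad(volume, padw)


def resample_inplane(image: np.ndarray, label: np.ndarray | None = None,
                     target=(128, 128)):
    """Resize the first two axes: trilinear for images, nearest for labels."""
    out_shape = (target[0], target[1]) + image.shape[2:]
    img = resize(image.astype(np.float64), out_shape, order=1,
                 preserve_range=True, anti_aliasing=False)
    if label is None:
        return img
    lab = resize(label.astype(np.float64), out_shape, order=0,
                 preserve_range=True, anti_aliasing=False)
    return img, (lab > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# size classification
# ---------------------------------------------------------------------------

def max_slice_area_cm2(label: np.ndarray, pixel_spacing_mm: float) -> float:
    """Largest per-slice foreground area across the stack, in cm^2."""
    if label.ndim == 2:
        label = label[..., None]
    counts = (label > 0).sum(axis=(0, 1))
    return float(counts.max()) * pixel_spacing_mm ** 2 / 100.0


def classify_tumor_size(label: np.ndarray, pixel_spacing_mm: float) -> str:
    """'none' if empty; else 'small' iff the largest per-slice area
    is under 3.5 cm^2, 'large' otherwise."""
    if not np.any(label):
        return "none"
    area = max_slice_area_cm2(label, pixel_spacing_mm)
    return "small" if area < SMALL_TUMOR_CM2 else "large"


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def preprocess_chgh_case(series: RawSeries, annotations: AnnotationSet,
                         source_id: str = "", gm: int = DISPLAY_MAX,
                         target_depth: int = 64,
                         target_inplane=(128, 128)) -> CanonicalCase:
    """DICOM-style series + polygon annotations -> canonical case.

    Chain: modality LUT -> VOI LUT per slice -> per-case presentation
    normalization to 12 bit -> rasterize annotations -> (24-25 slices
    only) spline doubling -> zero-pad to 64 -> in-plane resample.  The
    size class is fixed from the native-resolution label beforehand.
    """
    annotations.validate_against(series)
    windowed = []
    for arr, meta in series.slices:
        v = modality_lut(arr, meta.rescale_slope, meta.rescale_intercept)
        windowed.append(voi_lut(v, meta.window_center, meta.window_width, gm))
    volume = presentation_normalize(np.stack(windowed, axis=-1), gm)

    shape2d = series.slices[0][0].shape
    label = np.zeros(volume.shape, dtype=np.uint8)
    for i, uid in enumerate(series.uids()):
        if uid in annotations.entries:
            label[..., i] = rasterize_annotations(annotations.entries[uid], shape2d)

    native_area = max_slice_area_cm2(label, series.pixel_spacing_mm)
    size_class = classify_tumor_size(label, series.pixel_spacing_mm)

    img, lab = volume.astype(np.float64), label
    if img.shape[-1] in (24, 25):
        img, lab = interpolate_slices(img, lab)
    img = pad_to_depth(img, target_depth)
    lab = pad_to_depth(lab, target_depth)
    img, lab = resample_inplane(img, lab, target_inplane)

    img = img / float(gm)  # normalized intensities in [0, 1]
    return CanonicalCase(image=img.astype(np.float32), label=lab,
                         source_id=source_id, size_class=size_class,
                         native_max_slice_area_cm2=native_area)


def preprocess_brats_case(image: np.ndarray, label: np.ndarray,
                          source_id: str = "", start: int = 16,
                          count: int = 64,
                          target_inplane=(128, 128),
                          pixel_spacing_mm: float = 1.0) -> CanonicalCase:
    """BraTS-style volume pair -> canonical case.

    Chain: slice decimation (default every other slice from index 16,
    64 slices) -> merge labels {1,2,4} to 1 -> in-plane resample.
    """
    if image.shape != label.shape:
        raise ValueError("image/label shape mismatch")
    img = decimate_slices(image.astype(np.float64), start=start, count=count)
    lab = decimate_slices(label, start=start, count=count)
    lab = merge_brats_labels(lab)
    native_area = max_slice_area_cm2(lab, pixel_spacing_mm)
    size_class = classify_tumor_size(lab, pixel_spacing_mm)
    img, lab = resample_inplane(img, lab, target_inplane)
    vmin, vmax = img.min(), img.max()
    img = (img - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(img)
    return CanonicalCase(image=img.astype(np.float32), label=lab,
                         source_id=source_id, size_class=size_class,
                         native_max_slice_area_cm2=native_area)


def save_canonical_nifti(case: CanonicalCase, image_path, label_path,
                         voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write the canonical pair as NIfTI files."""
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(case.image.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(case.label.astype(np.uint8), affine), str(label_path))


def load_canonical_nifti(image_path, label_path, source_id: str = "",
                         pixel_spacing_mm: float = 1.0) -> CanonicalCase:
    import nibabel as nib

    img = np.asarray(nib.load(str(image_path)).dataobj, dtype=np.float32)
    lab = np.asarray(nib.load(str(label_path)).dataobj, dtype=np.uint8)
    return CanonicalCase(image=img, label=lab, source_id=source_id,
                         size_class=classify_tumor_size(lab, pixel_spacing_mm),
                         native_max_slice_area_cm2=max_slice_area_cm2(
                             lab, pixel_spacing_mm))
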