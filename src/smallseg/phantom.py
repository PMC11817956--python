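"""Synthetic brain-phantom generator.

Emulates the two data families of the study so the whole pipeline runs
without any download:

* clinical-style T2-FLAIR series: 12-bit axial slice stacks (47-51
  slices, a minority at 24-25) with DICOM-style rescale/window metadata,
  polygon tumor annotations, and optional white-matter-hyperintensity
  speckles on normal cases;
* BraTS-style labeled volumes (240x240x155 by default, labels in
  {0,1,2,4}, first 15 slices blank).

Lesions are axis-aligned ellipsoids with smooth intensity falloff, so
the per-slice area at the equatorial slice is the analytic ellipse area
pi*a*b and the 3.5 cm^2 small/large class can be enforced exactly.  The
cohort defaults mirror the study composition: 18 large-tumor, 15
small-tumor and 22 normal cases (7 of them with hyperintensities), with
small-tumor areas centered near the 1.1 cm^2 median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

from .preprocess import (SMALL_TUMOR_CM2, AnnotationSet, RawSeries, SliceMeta,
                         classify_tumor_size, max_slice_area_cm2)

ALLOWED_N_SLICES = frozenset({24, 25, 47, 48, 49, 50, 51})

# analytic-area sampling bands (cm^2); kept clear of the 3.5 threshold so
# that neither pixelation nor the annotation boundary stroke can flip
# the class after the polygon round trip
_SMALL_AREA_RANGE = (0.4, 2.6)
_SMALL_AREA_MEDIAN = 1.1
_LARGE_AREA_RANGE = (4.2, 22.0)

_TISSUE = 600.0        # background tissue physical intensity
_AIR = 30.0


@dataclass
class LesionSpec:
    """One ellipsoidal lesion: center voxel, physical radii, brightness."""

    center_voxel: tuple[int, int, int]
    radii_mm: tuple[float, float, float]     # (row, col, slice) semi-axes
    intensity_boost: float = 1.9
    size_class: str = "small"

    def __post_init__(self):
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be strictly positive")
        if self.intensity_boost <= 1:
            raise ValueError("intensity_boost must exceed 1")
        if self.size_class not in ("small", "large"):
            raise ValueError("size_class must be 'small' or 'large'")

    def equatorial_area_cm2(self) -> float:
        a, b, _ = self.radii_mm
        return float(np.pi * a * b / 100.0)


@dataclass
class PhantomSpec:
    """Full description of one synthetic clinical-style case."""

    in_plane_size: int = 256
    n_slices: int = 49
    pixel_spacing_mm: float = 0.9
    slice_thickness_mm: float = 3.0
    lesions: list[LesionSpec] = field(default_factory=list)
    hyperintensity_count: int = 0
    noise_sd: float = 18.0
    rescale_slope: float = 2.0
    rescale_intercept: float = -1024.0
    window_center: float = 700.0
    window_width: float = 1400.0
    seed: int = 0

    def __post_init__(self):
        if self.n_slices not in ALLOWED_N_SLICES:
            raise ValueError(
                f"n_slices must be one of {sorted(ALLOWED_N_SLICES)}, "
                f"got {self.n_slices}")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.rescale_slope <= 0:
            raise ValueError("rescale_slope must be positive")
        if self.hyperintensity_count < 0:
            raise ValueError("hyperintensity_count must be >= 0")


@dataclass
class SyntheticCase:
    """A generated series with annotations and known ground truth."""

    series: RawSeries
    annotations: AnnotationSet
    truth_mask: np.ndarray
    group: str                      # large_tumor | small_tumor | normal_plain | normal_hyperintense
    spec: PhantomSpec | None = None

    def __post_init__(self):
        has_tumor = bool(np.any(self.truth_mask))
        tumor_group = self.group in ("large_tumor", "small_tumor")
        if has_tumor != tumor_group:
            raise ValueError(
                f"group {self.group} inconsistent with truth mask "
                f"(foreground present: {has_tumor})")
        fg_slices = {i for i in range(self.truth_mask.shape[-1])
                     if np.any(self.truth_mask[..., i])}
        ann_slices = {i for i, uid in enumerate(self.series.uids())
                      if uid in self.annotations.entries}
        if fg_slices != ann_slices:
            raise ValueError("annotations must cover exactly the slices with "
                             "truth-mask foreground")


def _ellipsoid_field(shape, center, radii_px) -> np.ndarray:
    """Normalized squared distance field: <=1 inside the ellipsoid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii_px):
        d2 = d2 + ((g - c) / max(r, 1e-9)) ** 2
    return d2


def _brain_mask_and_texture(spec: PhantomSpec, rng: np.random.Generator):
    s, n = spec.in_plane_size, spec.n_slices
    shape = (s, s, n)
    center = (s / 2.0, s / 2.0, (n - 1) / 2.0)
    radii = (0.42 * s, 0.36 * s, 0.52 * n)
    d2 = _ellipsoid_field(shape, center, radii)
    brain = d2 <= 1.0
    # low-frequency multiplicative texture so thresholding alone cannot
    # separate lesion from tissue
    tex = gaussian_filter(rng.normal(size=shape), sigma=(s / 18.0, s / 18.0, 2.0))
    tex = tex / (np.abs(tex).max() + 1e-9) * 0.15 + 1.0
    return brain, tex


def _mask_to_polylines(mask2d: np.ndarray) -> list[tuple[np.ndarray, float]]:
    """Re-encode a binary slice as closed contour polylines (width 1)."""
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    return [(c, 1.0) for c in contours if len(c) >= 4]


def generate_phantom(spec: PhantomSpec) -> SyntheticCase:
    """Render one clinical-style case from its spec. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    s, n = spec.in_plane_size, spec.n_slices
    shape = (s, s, n)
    brain, tex = _brain_mask_and_texture(spec, rng)

    physical = np.full(shape, _AIR, dtype=np.float64)
    physical[brain] = _TISSUE * tex[brain]

    truth = np.zeros(shape, dtype=np.uint8)
    for lesion in spec.lesions:
        radii_px = (lesion.radii_mm[0] / spec.pixel_spacing_mm,
                    lesion.radii_mm[1] / spec.pixel_spacing_mm,
                    lesion.radii_mm[2] / spec.slice_thickness_mm)
        d2 = _ellipsoid_field(shape, lesion.center_voxel, radii_px)
        inside = d2 <= 1.0
        truth[inside] = 1
        # smooth falloff toward the rim keeps the boundary non-trivial
        falloff = np.clip(1.0 - d2, 0.0, 1.0) ** 0.5
        physical *= 1.0 + (lesion.intensity_boost - 1.0) * falloff

    physical += rng.normal(0.0, spec.noise_sd, size=shape)
    raw = np.clip(np.rint((physical - spec.rescale_intercept) / spec.rescale_slope),
                  0, 4095).astype(np.int16)

    slices = []
    for i in range(n):
        meta = SliceMeta(rescale_slope=spec.rescale_slope,
                         rescale_intercept=spec.rescale_intercept,
                         window_center=spec.window_center,
                         window_width=spec.window_width,
                         pixel_spacing_mm=spec.pixel_spacing_mm,
                         sop_uid=f"1.2.826.0.1.{spec.seed & 0x7FFFFFFF}.{i}")
        slices.append((raw[..., i], meta))
    series = RawSeries(slices=slices)

    ann = AnnotationSet()
    for i in range(n):
        if np.any(truth[..., i]):
            polys = _mask_to_polylines(truth[..., i])
            if not polys:  # tiny cap slice: drop from the mask instead
                truth[..., i] = 0
                continue
            ann.entries[series.uids()[i]] = polys

    if spec.lesions:
        observed = classify_tumor_size(truth, spec.pixel_spacing_mm)
        declared = ("small" if all(l.size_class == "small" for l in spec.lesions)
                    else "large")
        if observed != declared:
            raise ValueError(
                f"lesion spec declared {declared} but rendered mask is "
                f"{observed} ({max_slice_area_cm2(truth, spec.pixel_spacing_mm):.2f} cm^2)")
        group = "large_tumor" if declared == "large" else "small_tumor"
    else:
        group = "normal_plain"

    case = SyntheticCase(series=series, annotations=ann, truth_mask=truth,
                         group=group, spec=spec)
    if spec.hyperintensity_count > 0:
        if spec.lesions:
            raise ValueError("hyperintensity speckles only apply to normal cases")
        case = add_hyperintensity_speckles(case, spec.hyperintensity_count,
                                           seed=spec.seed + 1)
    return case


def add_hyperintensity_speckles(case: SyntheticCase, count: int,
                                seed: int = 0) -> SyntheticCase:
    """Add small bright non-tumor blobs to a normal case.

    Each speckle stays under 0.3 cm^2 per slice; the truth mask is left
    empty (they are confounders, not tumors).  With count > 0 the case
    group becomes ``normal_hyperintense``.
    """
    if np.any(case.truth_mask):
        raise ValueError("speckles can only be added to normal (empty-mask) cases")
    if count == 0:
        return case
    rng = np.random.default_rng(seed)
    spec = case.spec or PhantomSpec()
    raw = case.series.volume().astype(np.int32).copy()
    s, _, n = raw.shape
    spacing = case.series.pixel_spacing_mm
    # bright value: physical at the window top
    bright_phys = spec.window_center + spec.window_width / 2.0
    bright_raw = int(np.clip(
        round((bright_phys - spec.rescale_intercept) / spec.rescale_slope), 0, 4095))

    max_r_mm = np.sqrt(0.3 * 100.0 / np.pi) * 0.85  # radius cap under 0.3 cm^2
    centers: list[tuple[int, int, int]] = []
    placed = 0
    attempts = 0
    while placed < count and attempts < 10000:
        attempts += 1
        cx = int(rng.integers(int(0.30 * s), int(0.70 * s)))
        cy = int(rng.integers(int(0.30 * s), int(0.70 * s)))
        cz = int(rng.integers(max(1, n // 6), max(2, 5 * n // 6)))
        r_mm = float(rng.uniform(1.2, max_r_mm))
        r_px = r_mm / spacing
        if any((cx - x) ** 2 + (cy - y) ** 2 <= (4 * r_px) ** 2 and abs(cz - z) <= 3
               for x, y, z in centers):
            continue
        zr = max(1, int(rng.integers(1, 3)))
        for dz in range(-zr + 1, zr):
            z = cz + dz
            if not 0 <= z < n:
                continue
            yy, xx = np.ogrid[0:s, 0:s]
            blob = (xx - cy) ** 2 + (yy - cx) ** 2 <= r_px ** 2
            raw[..., z][blob] = bright_raw
        centers.append((cx, cy, cz))
        placed += 1
    if placed < count:
        raise RuntimeError("could not place all requested speckles")

    slices = [(raw[..., i].astype(np.int16), m)
              for i, (_, m) in enumerate(case.series.slices)]
    return SyntheticCase(series=RawSeries(slices=slices,
                                          modality_tag=case.series.modality_tag),
                         annotations=case.annotations,
                         truth_mask=case.truth_mask,
                         group="normal_hyperintense", spec=case.spec)


# ---------------------------------------------------------------------------
# lesion sampling
# ---------------------------------------------------------------------------

def sample_lesion_spec(rng: np.random.Generator, size_class: str,
                       spec: PhantomSpec) -> LesionSpec:
    """Draw a lesion whose analytic max-slice area respects the class rule."""
    if size_class == "small":
        lo, hi = _SMALL_AREA_RANGE
        area = float(np.clip(rng.lognormal(np.log(_SMALL_AREA_MEDIAN), 0.45), lo, hi))
    elif size_class == "large":
        lo, hi = _LARGE_AREA_RANGE
        area = float(np.clip(rng.lognormal(np.log(8.0), 0.5), lo, hi))
    else:
        raise ValueError(size_class)
    # split pi*a*b = area (mm^2) with mild eccentricity
    ab = area * 100.0 / np.pi
    ecc = rng.uniform(0.7, 1.4)
    a = float(np.sqrt(ab) * ecc)
    b = float(ab / a)
    rz = float(rng.uniform(max(spec.slice_thickness_mm * 1.2, 0.5 * max(a, b)),
                           max(spec.slice_thickness_mm * 1.6, 1.2 * max(a, b))))
    # keep the lesion's z extent inside the slab
    rz = min(rz, (spec.n_slices / 2.0 - 2.0) * spec.slice_thickness_mm)
    s, n = spec.in_plane_size, spec.n_slices
    zmargin = max(2, int(rz / spec.slice_thickness_mm) + 1)
    center = (int(rng.integers(s // 2 - s // 6, s // 2 + s // 6)),
              int(rng.integers(s // 2 - s // 6, s // 2 + s // 6)),
              int(rng.integers(zmargin, max(zmargin + 1, n - zmargin))))
    return LesionSpec(center_voxel=center, radii_mm=(a, b, rz),
                      intensity_boost=float(rng.uniform(1.7, 2.2)),
                      size_class=size_class)


def generate_toy_canonical(shape=(64, 64, 32), size_class: str = "large",
                           seed: int = 0, pixel_spacing_mm: float = 1.8,
                           source_id: str = ""):
    """A desk-scale canonical case rendered directly at model resolution.

    Same structure as the full phantom (ellipsoidal brain with texture
    and noise, one ellipsoidal lesion) but emitted straight as a
    normalized CanonicalCase so scaled-down training experiments skip
    the preprocessing chain.  ``size_class='none'`` gives a normal case.
    """
    from .preprocess import CanonicalCase

    rng = np.random.default_rng(seed)
    H, W, D = shape
    d2 = _ellipsoid_field(shape, (H / 2, W / 2, (D - 1) / 2),
                          (0.44 * H, 0.40 * W, 0.55 * D))
    brain = d2 <= 1.0
    tex = gaussian_filter(rng.normal(size=shape), sigma=(H / 16.0, W / 16.0, 2.0))
    tex = tex / (np.abs(tex).max() + 1e-9) * 0.12
    image = np.full(shape, 0.03, dtype=np.float64)
    image[brain] = 0.45 * (1.0 + tex[brain])

    label = np.zeros(shape, dtype=np.uint8)
    if size_class != "none":
        # radius in pixels so that pi*r^2*spacing^2 respects the class rule
        thr_px = np.sqrt(SMALL_TUMOR_CM2 * 100.0 / np.pi) / pixel_spacing_mm
        if size_class == "small":
            r = rng.uniform(max(2.0, 0.35 * thr_px), 0.75 * thr_px)
        elif size_class == "large":
            r = rng.uniform(1.15 * thr_px, min(1.8 * thr_px, 0.3 * min(H, W)))
        else:
            raise ValueError(size_class)
        rz = min(max(2.0, r * rng.uniform(0.5, 0.9)), D / 2.0 - 1.0)
        zlo = min(max(2, int(rz)), D // 2 - 1)
        center = (int(rng.integers(H // 2 - H // 6, H // 2 + H // 6)),
                  int(rng.integers(W // 2 - W // 6, W // 2 + W // 6)),
                  int(rng.integers(zlo, max(zlo + 1, D - zlo))))
        dl = _ellipsoid_field(shape, center,
                              (r, r * rng.uniform(0.85, 1.15), rz))
        label[dl <= 1.0] = 1
        boost = np.clip(1.0 - dl, 0.0, 1.0) ** 0.5
        image *= 1.0 + 0.9 * boost
    image += rng.normal(0.0, 0.03, size=shape)
    image = np.clip(image, 0.0, 1.5) / 1.5
    return CanonicalCase(image=image.astype(np.float32), label=label,
                         source_id=source_id or f"toy-{size_class}-{seed}",
                         size_class=classify_tumor_size(label, pixel_spacing_mm),
                         native_max_slice_area_cm2=max_slice_area_cm2(
                             label, pixel_spacing_mm))


# ---------------------------------------------------------------------------
# BraTS-style volumes
# ---------------------------------------------------------------------------

def generate_brats_like_case(size: int = 240, n_slices: int = 155,
                             seed: int = 0):
    """One labeled primary-tumor-style volume.

    Returns (image, label) with label values drawn from {0, 1, 2, 4}
    (necrotic core / edema / enhancing ring).  For 155-slice volumes the
    first 15 slices are blank, mirroring the public dataset layout.
    """
    if n_slices < 33:
        raise ValueError("n_slices must be >= 33")
    rng = np.random.default_rng(seed)
    shape = (size, size, n_slices)
    blank_lo = 15 if n_slices >= 100 else 2
    zc = (blank_lo + n_slices - 3) / 2.0
    zr = (n_slices - blank_lo - 4) / 2.0
    d2 = _ellipsoid_field(shape, (size / 2, size / 2, zc),
                          (0.42 * size, 0.36 * size, zr))
    brain = d2 <= 1.0
    tex = gaussian_filter(rng.normal(size=shape), sigma=(size / 18.0, size / 18.0, 2.0))
    tex = tex / (np.abs(tex).max() + 1e-9) * 0.15 + 1.0
    image = np.zeros(shape, dtype=np.float32)
    image[brain] = (_TISSUE * tex[brain]).astype(np.float32)

    # one large multi-compartment lesion well inside the brain
    cx = int(rng.integers(size // 2 - size // 8, size // 2 + size // 8))
    cy = int(rng.integers(size // 2 - size // 8, size // 2 + size // 8))
    cz = int(rng.integers(int(zc - zr / 3), int(zc + zr / 3) + 1))
    r = float(rng.uniform(0.10, 0.16)) * size
    rz_les = max(4.0, r / 3.0)
    dl = _ellipsoid_field(shape, (cx, cy, cz), (r, r * rng.uniform(0.8, 1.1), rz_les))
    label = np.zeros(shape, dtype=np.uint8)
    label[dl <= 1.0] = 2          # peritumoral edema
    label[dl <= 0.55] = 4         # enhancing tumor
    label[dl <= 0.25] = 1         # necrotic core
    boost = np.clip(1.0 - dl, 0.0, 1.0) ** 0.5
    image *= (1.0 + 0.9 * boost).astype(np.float32)
    image += rng.normal(0.0, 12.0, size=shape).astype(np.float32)
    image[..., :blank_lo] = 0.0
    label[..., :blank_lo] = 0
    return image, label


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n_large: int, n_small: int, n_normal_plain: int,
                    n_normal_hyper: int, seed: int = 0,
                    in_plane_size: int = 256,
                    pixel_spacing_mm: float = 0.9) -> list[SyntheticCase]:
    """Generate a full clinical-style cohort with the requested group counts.

    Per-case seeds derive deterministically from the cohort seed.  Slice
    counts are mostly 47-51 with roughly one case in eight at 24-25.
    """
    for v in (n_large, n_small, n_normal_plain, n_normal_hyper):
        if v < 0:
            raise ValueError("cohort counts must be >= 0")
    groups = (["large_tumor"] * n_large + ["small_tumor"] * n_small +
              ["normal_plain"] * n_normal_plain +
              ["normal_hyperintense"] * n_normal_hyper)
    master = np.random.default_rng(seed)
    cases = []
    for idx, group in enumerate(groups):
        case_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(case_seed)
        thin = rng.random() < 0.125
        n_slices = int(rng.choice([24, 25]) if thin else rng.choice([47, 48, 49, 50, 51]))
        spec = PhantomSpec(in_plane_size=in_plane_size, n_slices=n_slices,
                           pixel_spacing_mm=pixel_spacing_mm, seed=case_seed)
        if group in ("large_tumor", "small_tumor"):
            size_class = "large" if group == "large_tumor" else "small"
            lesion = sample_lesion_spec(rng, size_class, spec)
            spec = replace(spec, lesions=[lesion])
        elif group == "normal_hyperintense":
            spec = replace(spec, hyperintensity_count=int(rng.integers(3, 9)))
        cases.append(generate_phantom(spec))
    return cases
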