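"""Geometric training-set augmentation.

Four in-plane transform kinds, applied identically to every slice of a
case: rotation by +/-(20..50) degrees, scaling by 0.6..0.9 or 1.1..1.5
(near-identity scales are deliberately outside the legal ranges),
rotation+scaling combined, and a fixed 0.4 shear.  Labels follow the
image transform with nearest-neighbor sampling and stay binary; regions
transformed in from outside the field of view are zero-filled.  The
evaluation path never augments: only training sets are expanded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .preprocess import CanonicalCase

KINDS = ("rotate", "scale", "rotate_scale", "shear")

ROTATE_RANGE_DEG = (20.0, 50.0)
SCALE_RANGES = ((0.6, 0.9), (1.1, 1.5))
SHEAR_AMOUNT = 0.4


@dataclass
class AugmentSpec:
    kind: str
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}; "
                             f"expected one of {KINDS}")


def sample_parameters(kind: str, rng: np.random.Generator) -> dict:
    """Draw transform parameters within the legal ranges."""
    params: dict = {}
    if kind in ("rotate", "rotate_scale"):
        mag = rng.uniform(*ROTATE_RANGE_DEG)
        params["angle_deg"] = float(mag if rng.random() < 0.5 else -mag)
    if kind in ("scale", "rotate_scale"):
        branch = SCALE_RANGES[int(rng.random() < 0.5)]
        params["scale"] = float(rng.uniform(*branch))
    if kind == "shear":
        params["shear"] = SHEAR_AMOUNT
    return params


def _inplane_matrix(params: dict) -> np.ndarray:
    """Forward 2x2 in-plane transform matrix from sampled parameters."""
    m = np.eye(2)
    if "angle_deg" in params:
        t = np.deg2rad(params["angle_deg"])
        m = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]]) @ m
    if "scale" in params:
        m = params["scale"] * m
    if "shear" in params:
        m = np.array([[1.0, params["shear"]], [0.0, 1.0]]) @ m
    return m


def _apply_matrix(volume: np.ndarray, m2: np.ndarray, order: int) -> np.ndarray:
    """Apply an in-plane matrix about the slice center to a 3D volume."""
    inv = np.linalg.inv(m2)
    mat = np.eye(3)
    mat[:2, :2] = inv
    center = np.array([(volume.shape[0] - 1) / 2.0,
                       (volume.shape[1] - 1) / 2.0, 0.0])
    offset = center - mat @ center
    return ndimage.affine_transform(volume, mat, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def apply_augment(case: CanonicalCase, spec: AugmentSpec) -> CanonicalCase:
    """One augmented copy of a canonical case (same transform every slice)."""
    rng = np.random.default_rng(spec.seed)
    params = sample_parameters(spec.kind, rng)
    m2 = _inplane_matrix(params)
    image = _apply_matrix(case.image.astype(np.float64), m2, order=1)
    label = _apply_matrix(case.label.astype(np.float64), m2, order=0)
    return CanonicalCase(image=image.astype(np.float32),
                         label=(label > 0.5).astype(np.uint8),
                         source_id=case.source_id,
                         size_class=case.size_class,
                         native_max_slice_area_cm2=case.native_max_slice_area_cm2)


def expand_training_set(cases: list[CanonicalCase], rate: int,
                        seed: int = 0) -> list[CanonicalCase]:
    """Grow the training set to ``rate`` times its size.

    Each original is kept once and gets ``rate - 1`` augmented variants,
    cycling uniformly over the four transform kinds.  ``rate=1`` returns
    the originals unchanged.
    """
    if rate < 1:
        raise ValueError("augmentation rate must be >= 1")
    if rate == 1:
        return list(cases)
    master = np.random.default_rng(seed)
    out: list[CanonicalCase] = []
    for case in cases:
        out.append(case)
        for j in range(rate - 1):
            kind = KINDS[j % len(KINDS)]
            out.append(apply_augment(
                case, AugmentSpec(kind=kind,
                                  seed=int(master.integers(0, 2 ** 31 - 1)))))
    return out
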