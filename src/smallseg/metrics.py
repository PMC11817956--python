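"""Segmentation and detection evaluation.

Dice overlap, case-level tumor detection via connected components, and
cohort-level sensitivity/specificity summaries, including the variant
that excludes normal cases whose FLAIR shows white-matter
hyperintensities (the dominant source of false positives).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage


@dataclass
class SegScore:
    """Voxel-wise confusion counts and the Dice coefficient.

    Dice = 2*TP / (2*TP + FP + FN).  When prediction and truth are both
    empty the score is defined as 1: a correct all-negative segmentation
    is not penalized (normal cases are scored by detection instead).
    """

    tp: int
    fp: int
    fn: int
    dice: float


@dataclass
class DetectionRule:
    """A case counts as 'tumor detected' if some 26-connected predicted
    component has at least ``min_component_voxels`` voxels."""

    min_component_voxels: int = 1

    def __post_init__(self):
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")


@dataclass
class DetectionTable:
    """Per-group (detected, not detected) case counts."""

    small_tumor: tuple[int, int] = (0, 0)
    normal_hyperintense: tuple[int, int] = (0, 0)
    normal_plain: tuple[int, int] = (0, 0)

    def add(self, group: str, detected: bool):
        cur = getattr(self, group)
        setattr(self, group, (cur[0] + int(detected), cur[1] + int(not detected)))


def dice(pred: np.ndarray, truth: np.ndarray) -> SegScore:
    """Dice overlap between two binary masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    denom = 2 * tp + fp + fn
    score = 1.0 if denom == 0 else 2.0 * tp / denom
    return SegScore(tp=tp, fp=fp, fn=fn, dice=score)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def detect(pred: np.ndarray, rule: DetectionRule | None = None) -> bool:
    """Case-level detection decision on a predicted binary volume."""
    rule = rule or DetectionRule()
    pred = np.asarray(pred).astype(bool)
    if pred.ndim == 2:
        pred = pred[..., None]
    labeled, n = ndimage.label(pred, structure=_STRUCT_26)
    if n == 0:
        return False
    sizes = np.bincount(labeled.ravel())[1:]
    return bool(sizes.max() >= rule.min_component_voxels)


def _pct(numer: int, denom: int) -> float | None:
    """Percentage rounded half-up to one decimal; None when undefined."""
    if denom == 0:
        return None
    v = Decimal(numer) / Decimal(denom) * 100
    return float(v.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def detection_metrics(table: DetectionTable) -> dict:
    """Sensitivity and the two specificities from a detection table.

    sensitivity           = detected tumor cases / all tumor cases
    specificity_all       = undetected normals / all normals
    specificity_excl_hyper= undetected plain normals / plain normals
    """
    det_s, miss_s = table.small_tumor
    det_h, ok_h = table.normal_hyperintense
    det_p, ok_p = table.normal_plain
    if det_s + miss_s == 0:
        raise ValueError("detection_metrics requires at least one tumor case")
    return {
        "sensitivity": _pct(det_s, det_s + miss_s),
        "specificity_all": _pct(ok_h + ok_p, det_h + ok_h + det_p + ok_p),
        "specificity_excl_hyper": _pct(ok_p, det_p + ok_p),
    }


def _offset_square(side: int, offset: int, canvas: int | None = None):
    canvas = canvas or side + offset + 2
    truth = np.zeros((canvas, canvas), dtype=np.uint8)
    pred = np.zeros_like(truth)
    truth[1:1 + side, 1:1 + side] = 1
    pred[1 + offset:1 + offset + side, 1 + offset:1 + offset + side] = 1
    return pred, truth


def dice_offset_study(sizes, offset: int = 1) -> list[float]:
    """Dice of an s-by-s square against itself shifted by (offset, offset).

    Quantifies the size bias of the Dice score: under a fixed boundary
    misalignment the score rises with object size, which is why few-pixel
    lesions score low even for visually acceptable segmentations.
    """
    out = []
    for side in sizes:
        if side < offset + 1:
            raise ValueError(f"square side {side} must be >= offset+1 ({offset + 1})")
        pred, truth = _offset_square(side, offset)
        out.append(dice(pred, truth).dice)
    return out


@dataclass
class CaseResult:
    case_id: str
    group: str
    dice: float | None
    detected: bool


def write_report(results: list[CaseResult], table: DetectionTable | None,
                 csv_path, json_path) -> None:
    """Per-case CSV plus a JSON summary (mean Dice, detection metrics)."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "group", "dice", "detected"])
        for r in results:
            w.writerow([r.case_id, r.group,
                        "" if r.dice is None else f"{r.dice:.4f}", int(r.detected)])
    summary = {
        "n_cases": len(results),
        "mean_dice": float(np.mean([r.dice for r in results if r.dice is not None]))
        if any(r.dice is not None for r in results) else None,
    }
    if table is not None:
        summary["detection"] = detection_metrics(table)
        summary["table"] = {
            "small_tumor": list(table.small_tumor),
            "normal_hyperintense": list(table.normal_hyperintense),
            "normal_plain": list(table.normal_plain),
        }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
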