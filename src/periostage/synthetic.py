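"""Synthetic periapical-radiograph generator with exact ground truth.

Real intraoral radiographs of periodontitis patients are private clinical
data, so every downstream stage (segmentation, apex detection, bone-loss
geometry, staging) is exercised on generated images that preserve the
geometric relations the pipeline measures:

* each tooth is a filled trapezoid silhouette (bright crown + tapering
  root) on a bone-gray background;
* the bone-loss (BL) area is a solid dark band between the CEJ line and the
  bone crest, one connected component per tooth, rendered so that the mask
  bounding box recovers the true CEJ center and BL height exactly;
* root apexes are bright Gaussian blobs (sigma = 2 px) at known integer
  coordinates, annotated with 9x9 px YOLO-style boxes;
* per case the generator records the exact CEJ/apex coordinates, BL height,
  root length, BL%, and the stage/grade implied by the staging rules.

On a noiseless rendering the measurement chain recovers BL% to floating
point precision, which is what makes end-to-end self-consistency testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.draw import polygon

from .apex_detection import APEX_BOX_SIZE, DetectionBox, write_yolo_labels
from .image_io import Point2D, write_image, write_mask
from .staging import StageGradeThresholds, DEFAULT_THRESHOLDS, classify_grade, classify_stage

__all__ = [
    "SyntheticConfig",
    "ToothTruth",
    "GroundTruth",
    "ImageCase",
    "generate_case",
    "generate_dataset",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "case_id", "tooth_id", "jaw", "age", "cej_x", "cej_y", "apex_x", "apex_y",
    "max_bl_px", "root_len_px", "bl_percent", "stage", "grade",
]

# rendering gray levels (8-bit)
_GRAY_BONE = 120
_GRAY_TOOTH = 190
_GRAY_BL = 60
_APEX_PEAK = 255.0
_APEX_SIGMA = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; identical seed means byte-identical output.

    Defaults describe a plausible periapical field of view at 0.1 mm/px:
    3 teeth with 6.5–11.5 mm roots and bone loss between 5% and 60% of root
    length, imaged with mild sensor noise (sd 8 gray levels).
    """

    image_height: int = 160
    image_width: int = 320
    teeth_per_image: int = 3
    jaw: str = "lower"
    root_length_range: Tuple[float, float] = (65.0, 115.0)
    bl_fraction_range: Tuple[float, float] = (0.05, 0.60)
    noise_sd: float = 8.0
    mm_per_px: float = 0.1
    age_range: Tuple[int, int] = (20, 70)
    seed: int = 0
    thresholds: StageGradeThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        lo, hi = self.bl_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("bl_fraction_range must be within [0, 1)")
        if self.root_length_range[0] < 20:
            raise ValueError("root_length_range minimum must be >= 20 px")
        if self.jaw not in ("upper", "lower"):
            raise ValueError("jaw must be 'upper' or 'lower'")
        if not 1 <= self.teeth_per_image <= 4:
            raise ValueError("teeth_per_image must be 1..4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ToothTruth:
    """Exact geometry of one generated tooth."""

    tooth_id: int
    cej_center: Point2D
    apex_center: Point2D
    max_bl_px: int
    root_length_px: float
    bl_percent: float


@dataclass(frozen=True)
class GroundTruth:
    """Per-case truth: tooth geometry plus the implied patient labels."""

    teeth: Tuple[ToothTruth, ...]
    age: int
    max_bl_percent: float
    stage: str
    grade: str


@dataclass(frozen=True)
class ImageCase:
    """One synthetic radiograph with mask, apex annotations and truth."""

    case_id: int
    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray  # uint8 {0,1} (H, W)
    apex_boxes: Tuple[DetectionBox, ...]
    jaw: str
    age: int
    truth: GroundTruth


def _tooth_slots(config: SyntheticConfig, rng: np.random.Generator,
                 band_half: int) -> List[int]:
    """Tooth center columns: evenly spaced slots with jitter, non-touching."""
    n = config.teeth_per_image
    slot = config.image_width / n
    margin = band_half + 4  # band must stay inside the image and off neighbours
    if slot < 2 * margin + 2:
        raise ValueError(
            f"layout infeasible: {n} teeth of band width {2*band_half+1} px do not "
            f"fit in image width {config.image_width}"
        )
    centers = []
    for i in range(n):
        lo = int(i * slot + margin)
        hi = int((i + 1) * slot - margin)
        centers.append(int(rng.integers(lo, hi + 1)))
    return centers


def _render_tooth(image: np.ndarray, mask: np.ndarray, config: SyntheticConfig,
                  rng: np.random.Generator, cx: int, band_half: int,
                  tooth_id: int) -> ToothTruth:
    height, width = image.shape
    lower = config.jaw == "lower"

    # crown height and CEJ row scale with the field of view
    crown_h = int(rng.integers(max(5, height // 9), max(6, height // 6) + 1))
    cej_offset = int(rng.integers(crown_h + 2, max(crown_h + 3, height // 4) + 1))

    # target root length, capped so the apex stays inside the image,
    # with a slightly oblique apex
    target_len = rng.uniform(*config.root_length_range)
    target_len = min(target_len, float(height - 5 - cej_offset))
    dx = int(rng.integers(-6, 7))
    dy = int(round(math.sqrt(max(1.0, target_len**2 - dx**2))))

    if lower:
        cej_y = cej_offset
        apex_y = cej_y + dy
        sign = 1
    else:
        cej_y = height - 1 - cej_offset
        apex_y = cej_y - dy
        sign = -1
    apex_x = int(np.clip(cx + dx, 4, width - 5))
    root_len = math.hypot(apex_x - cx, apex_y - cej_y)

    frac = rng.uniform(*config.bl_fraction_range)
    bl_h = max(1, int(round(frac * root_len)))
    bl_percent = 100.0 * bl_h / root_len

    # tooth silhouette: crown rectangle tapering to the apex
    crown_half = band_half + 2
    neck_half = band_half - 4
    ys = [cej_y - sign * crown_h, cej_y - sign * crown_h, cej_y, apex_y, apex_y, cej_y]
    xs = [cx - crown_half, cx + crown_half, cx + neck_half, apex_x + 3, apex_x - 3,
          cx - neck_half]
    rr, cc = polygon(np.asarray(ys), np.asarray(xs), shape=image.shape)
    image[rr, cc] = _GRAY_TOOTH

    # BL band: solid dark rectangle from the CEJ line toward the bone crest;
    # odd width centered on cx so the bbox midpoint is exactly cx
    if lower:
        y0, y1 = cej_y, cej_y + bl_h - 1
    else:
        y0, y1 = cej_y - bl_h + 1, cej_y
    x0, x1 = cx - band_half, cx + band_half
    image[y0 : y1 + 1, x0 : x1 + 1] = _GRAY_BL
    mask[y0 : y1 + 1, x0 : x1 + 1] = 1

    # apex rendered later (bright blob over everything)
    return ToothTruth(
        tooth_id=tooth_id,
        cej_center=Point2D(float(cx), float(cej_y)),
        apex_center=Point2D(float(apex_x), float(apex_y)),
        max_bl_px=bl_h,
        root_length_px=root_len,
        bl_percent=bl_percent,
    )


def _add_apex_blob(image_f: np.ndarray, apex: Point2D) -> None:
    height, width = image_f.shape
    r0 = int(apex.y)
    c0 = int(apex.x)
    rad = 6
    rows = np.arange(max(0, r0 - rad), min(height, r0 + rad + 1))
    cols = np.arange(max(0, c0 - rad), min(width, c0 + rad + 1))
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    blob = _APEX_PEAK * np.exp(
        -((yy - apex.y) ** 2 + (xx - apex.x) ** 2) / (2 * _APEX_SIGMA**2)
    )
    region = image_f[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    np.maximum(region, blob, out=region)


def generate_case(config: SyntheticConfig, case_id: int) -> ImageCase:
    """Generate one radiograph-like case with exact ground truth.

    Deterministic in ``(config.seed, case_id)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, case_id]))
    height, width = config.image_height, config.image_width
    image = np.full((height, width), _GRAY_BONE, dtype=np.float64)
    mask = np.zeros((height, width), dtype=np.uint8)

    band_half = 14  # BL band width 29 px
    centers = _tooth_slots(config, rng, band_half)
    teeth = [
        _render_tooth(image, mask, config, rng, cx, band_half, tooth_id=i)
        for i, cx in enumerate(centers)
    ]
    for tooth in teeth:
        _add_apex_blob(image, tooth.apex_center)

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
    max_bl = max(t.bl_percent for t in teeth)
    truth = GroundTruth(
        teeth=tuple(teeth),
        age=age,
        max_bl_percent=max_bl,
        stage=classify_stage(max_bl, config.thresholds),
        grade=classify_grade(max_bl, age, config.thresholds),
    )
    boxes = tuple(
        DetectionBox(
            class_id=0,
            center=t.apex_center,
            width=float(APEX_BOX_SIZE),
            height=float(APEX_BOX_SIZE),
            confidence=1.0,
        )
        for t in teeth
    )
    return ImageCase(
        case_id=case_id, image=image, mask=mask, apex_boxes=boxes,
        jaw=config.jaw, age=age, truth=truth,
    )


def generate_dataset(config: SyntheticConfig, n_cases: int, out_dir) -> pd.DataFrame:
    """Write a dataset to disk and return the per-tooth manifest.

    Layout: ``images/case_%04d.png``, ``masks/``, ``labels/`` (YOLO-txt),
    and ``manifest.csv`` with one row per tooth, carrying the full ground
    truth including the patient-level stage and grade.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out = Path(out_dir)
    for sub in ("images", "masks", "labels"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    shape = (config.image_height, config.image_width)
    for cid in range(n_cases):
        case = generate_case(config, cid)
        stem = f"case_{cid:04d}"
        write_image(case.image, out / "images" / f"{stem}.png")
        write_mask(case.mask, out / "masks" / f"{stem}.png")
        write_yolo_labels(case.apex_boxes, out / "labels" / f"{stem}.txt", shape)
        for tooth in case.truth.teeth:
            rows.append({
                "case_id": cid,
                "tooth_id": tooth.tooth_id,
                "jaw": case.jaw,
                "age": case.age,
                "cej_x": tooth.cej_center.x,
                "cej_y": tooth.cej_center.y,
                "apex_x": tooth.apex_center.x,
                "apex_y": tooth.apex_center.y,
                "max_bl_px": tooth.max_bl_px,
                "root_len_px": tooth.root_length_px,
                "bl_percent": tooth.bl_percent,
                "stage": case.truth.stage,
                "grade": case.truth.grade,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
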