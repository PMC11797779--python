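"""Bone-loss geometry: from a binary mask and apex points to BL percentage.

The measurement chain works on a segmented bone-loss (BL) mask:

1. connected-component analysis finds each BL region and its bounding box;
   the region's maximum BL height is the vertical extent of that box;
2. the cemento-enamel junction (CEJ) center is the midpoint of the border of
   the region's bounding rectangle facing the crown — the upper border for
   lower teeth, the lower border for upper teeth;
3. root length is the Euclidean pixel distance from the CEJ center to the
   tooth's root apex;
4. BL% = 100 * max BL height / root length, the quantity that drives
   periodontitis staging.

Regions whose BL height converts to 2 mm or less are within the normal
physiological distance from CEJ to bone crest and are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.measure import label, regionprops

from .image_io import Point2D

__all__ = [
    "RegionMeasurement",
    "ToothMeasurement",
    "CalibrationConfig",
    "find_bl_regions",
    "locate_cej_center",
    "euclidean_distance",
    "measure_tooth",
    "associate_regions_to_apexes",
]


@dataclass(frozen=True)
class RegionMeasurement:
    """One 8-connected bone-loss region of the mask.

    ``bbox`` is (x_min, y_min, width, height) in pixels; ``max_height``
    equals the bbox height (the region's vertical extent).
    """

    region_id: int
    bbox: Tuple[int, int, int, int]
    max_height: int
    area: int

    @property
    def x_mid(self) -> float:
        x_min, _, width, _ = self.bbox
        return x_min + (width - 1) / 2.0


@dataclass(frozen=True)
class ToothMeasurement:
    """Per-tooth bone-loss measurement."""

    cej_center: Point2D
    apex_center: Point2D
    max_bl_px: float
    max_bl_mm: float
    root_length_px: float
    bl_percent: float


@dataclass(frozen=True)
class CalibrationConfig:
    """Pixel-size calibration and the normal-bone allowance.

    ``min_bl_mm`` is the physiological CEJ-to-crest distance: measured BL
    heights at or below it are not pathological and are filtered out.
    """

    mm_per_px: float = 0.1
    min_bl_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


def find_bl_regions(mask: np.ndarray, min_area: int = 20) -> List[RegionMeasurement]:
    """Connected-component analysis of a binary BL mask.

    8-connectivity; components smaller than ``min_area`` px^2 are treated as
    speckle and dropped.  Regions are returned left-to-right by bbox x_min.
    """
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("find_bl_regions expects a {0,1} mask")
    labeled = label(arr, connectivity=2)
    regions = []
    for prop in regionprops(labeled):
        if prop.area < min_area:
            continue
        y0, x0, y1, x1 = prop.bbox  # half-open (min_row, min_col, max_row, max_col)
        regions.append(
            RegionMeasurement(
                region_id=prop.label,
                bbox=(int(x0), int(y0), int(x1 - x0), int(y1 - y0)),
                max_height=int(y1 - y0),
                area=int(prop.area),
            )
        )
    regions.sort(key=lambda r: r.bbox[0])
    return regions


def locate_cej_center(region: RegionMeasurement, jaw: str) -> Point2D:
    """CEJ center from a region's bounding rectangle.

    For lower teeth the crown is above the BL area, so the CEJ sits at the
    midpoint of the bbox's upper border; for upper teeth, the lower border.
    The x midpoint is floored on a half pixel.
    """
    if jaw not in ("upper", "lower"):
        raise ValueError(f"jaw must be 'upper' or 'lower', got {jaw!r}")
    x_min, y_min, width, height = region.bbox
    if width < 1 or height < 1:
        raise ValueError("empty region")
    x = (x_min + (x_min + width - 1)) // 2
    y = y_min if jaw == "lower" else y_min + height - 1
    return Point2D(float(x), float(y))


def euclidean_distance(p1: Point2D, p2: Point2D) -> float:
    """Straight-line pixel distance between two points."""
    return math.hypot(p2.x - p1.x, p2.y - p1.y)


def measure_tooth(
    region: RegionMeasurement,
    apex: Point2D,
    jaw: str,
    calib: CalibrationConfig = CalibrationConfig(),
) -> Optional[ToothMeasurement]:
    """Full per-tooth measurement; ``None`` if BL height is within normal.

    Raises
    ------
    ValueError
        If the apex coincides with the CEJ center (zero root length).
    """
    cej = locate_cej_center(region, jaw)
    root_length = euclidean_distance(cej, apex)
    if root_length == 0:
        raise ValueError("apex coincides with CEJ center: zero root length")
    max_bl_px = float(region.max_height)
    max_bl_mm = max_bl_px * calib.mm_per_px
    if max_bl_mm <= calib.min_bl_mm:
        return None
    bl_percent = min(100.0, 100.0 * max_bl_px / root_length)
    return ToothMeasurement(
        cej_center=cej,
        apex_center=apex,
        max_bl_px=max_bl_px,
        max_bl_mm=max_bl_mm,
        root_length_px=root_length,
        bl_percent=bl_percent,
    )


def associate_regions_to_apexes(
    regions: Sequence[RegionMeasurement],
    apexes: Sequence[Point2D],
    jaw: str = "lower",
) -> Tuple[List[Tuple[RegionMeasurement, Point2D]], List[RegionMeasurement], List[Point2D]]:
    """Pair each BL region with its tooth's apex.

    Greedy pairing on increasing horizontal distance between the region's
    bbox x-midpoint and the apex x; ties broken by smaller Euclidean
    distance from the region's CEJ center, then by smaller apex x.

    Returns ``(pairs, unpaired_regions, unpaired_apexes)``.
    """
    candidates = []
    for ri, region in enumerate(regions):
        cej = locate_cej_center(region, jaw)
        for ai, apex in enumerate(apexes):
            dx = abs(region.x_mid - apex.x)
            candidates.append((dx, euclidean_distance(cej, apex), apex.x, ri, ai))
    candidates.sort()
    used_r: set = set()
    used_a: set = set()
    pairs = []
    for _, _, _, ri, ai in candidates:
        if ri in used_r or ai in used_a:
            continue
        used_r.add(ri)
        used_a.add(ai)
        pairs.append((regions[ri], apexes[ai]))
    unpaired_regions = [r for i, r in enumerate(regions) if i not in used_r]
    unpaired_apexes = [a for i, a in enumerate(apexes) if i not in used_a]
    return pairs, unpaired_regions, unpaired_apexes
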