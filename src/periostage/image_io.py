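"""Image/mask I/O, preprocessing, dataset splitting, and augmentation.

The data pipeline mirrors common practice for intraoral radiograph models:
images are resized to a fixed 160x320 raster, contrast-stretched by global
histogram equalization, and scaled to [0, 1]; the dataset is split 80:10:10
into train/validation/test BEFORE augmentation (so augmented copies never
leak across splits), and each train and validation item then gains one
augmented copy (horizontal flip and/or small rotation), doubling those sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize, rotate

logger = logging.getLogger(__name__)

__all__ = [
    "Point2D",
    "DatasetSplit",
    "AugmentTransform",
    "TARGET_SHAPE",
    "ROTATION_ANGLES",
    "preprocess",
    "equalize_histogram",
    "split_cases",
    "split_and_augment",
    "apply_transform",
    "invert_transform",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

#: (rows, cols) every image is resized to before segmentation.
TARGET_SHAPE = (160, 320)

#: Candidate rotation angles (degrees) for augmentation.
ROTATION_ANGLES = (-15.0, -10.0, -5.0, 5.0, 10.0, 15.0)


@dataclass(frozen=True)
class Point2D:
    """Pixel coordinate: ``x`` = column (rightward), ``y`` = row (downward)."""

    x: float
    y: float

    def as_tuple(self) -> tuple:
        return (self.x, self.y)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit grayscale image.

    Uses the classic CDF remapping ``(cdf(v) - cdf_min) / (N - cdf_min)`` so
    that the darkest occupied level maps to 0 and the brightest to 255.  A
    single-level (constant) image is returned unchanged.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("equalize_histogram expects a uint8 image")
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = cdf[hist > 0]
    cdf_min = nonzero[0]
    n = img.size
    if n == cdf_min:  # constant image: equalization is a no-op
        return img.copy()
    lut = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img]


def preprocess(image: np.ndarray, target_shape: tuple = TARGET_SHAPE,
               equalize: bool = True) -> np.ndarray:
    """Resize to ``target_shape``, histogram-equalize, and scale to [0, 1].

    Parameters
    ----------
    image : ndarray
        Single-channel raster of any size, integer or float gray levels.
    equalize : bool
        Apply global histogram equalization (the segmentation branch does;
        the apex-detection branch only resizes and rescales).

    Returns
    -------
    ndarray of float32, shape ``target_shape``, values in [0, 1].
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(
            f"preprocess expects a single-channel image, got shape {img.shape}"
        )
    if img.shape != tuple(target_shape):
        img = resize(
            img.astype(np.float64), target_shape, order=1, preserve_range=True,
            anti_aliasing=False,
        )
    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if equalize:
        img8 = equalize_histogram(img8)
    return (img8.astype(np.float32)) / 255.0


# ---------------------------------------------------------------------------
# splitting and augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive partition of case ids into train/validation/test."""

    train: tuple
    validation: tuple
    test: tuple
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        union = set().union(*parts)
        if len(union) != total:
            raise ValueError("split parts are not disjoint")


@dataclass(frozen=True)
class AugmentTransform:
    """A flip-and/or-rotate augmentation, applied identically to image+mask.

    At least one of ``hflip``/nonzero ``angle`` is set.  Inverses exist for
    every transform; they are exact for flips and multiples of 90 degrees.
    """

    hflip: bool
    angle: float  # degrees, counter-clockwise

    def __post_init__(self) -> None:
        if not self.hflip and self.angle == 0.0:
            raise ValueError("augmentation must flip or rotate")


def split_cases(
    case_ids: Sequence[Hashable],
    ratios: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition case ids by the given ratios.

    Validation/test sizes are ``round(ratio * n)``; the remainder goes to
    train.  The shuffle is driven by ``seed`` only.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    ids = list(case_ids)
    n = len(ids)
    n_val = int(round(ratios[1] * n))
    n_test = int(round(ratios[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("ratios produce a negative split size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train=tuple(shuffled[:n_train]),
        validation=tuple(shuffled[n_train : n_train + n_val]),
        test=tuple(shuffled[n_train + n_val :]),
        ratios=tuple(ratios),
        seed=seed,
    )


def _draw_transform(rng: np.random.Generator) -> AugmentTransform:
    kind = rng.integers(3)
    angle = float(rng.choice(ROTATION_ANGLES))
    if kind == 0:
        return AugmentTransform(hflip=True, angle=0.0)
    if kind == 1:
        return AugmentTransform(hflip=False, angle=angle)
    return AugmentTransform(hflip=True, angle=angle)


def split_and_augment(
    case_ids: Sequence[Hashable],
    ratios: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
    augment_factor: int = 2,
):
    """Split first, then augment train+validation by ``augment_factor``.

    Each train and validation case gains ``augment_factor - 1`` augmented
    copies; the test set is never augmented.  With 1,000 cases and the
    default 80:10:10 ratios this yields 1,600 training and 200 validation
    items and 100 untouched test cases.

    Returns
    -------
    (split, train_items, validation_items) where each item is a
    ``(case_id, transform)`` pair; ``transform`` is ``None`` for originals.
    """
    if len(case_ids) < 2:
        raise ValueError("need at least 2 cases to split")
    if augment_factor < 1:
        raise ValueError("augment_factor must be >= 1")
    split = split_cases(case_ids, ratios=ratios, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA76]))

    def expand(ids):
        items = [(cid, None) for cid in ids]
        for _ in range(augment_factor - 1):
            for cid in ids:
                items.append((cid, _draw_transform(rng)))
        return items

    return split, expand(split.train), expand(split.validation)


def apply_transform(
    raster: np.ndarray, transform: AugmentTransform, is_mask: bool = False
) -> np.ndarray:
    """Apply a flip/rotation to an image or mask.

    Masks are resampled nearest-neighbour and re-binarized; images use
    bilinear interpolation.
    """
    out = np.asarray(raster)
    if transform.hflip:
        out = out[:, ::-1]
    if transform.angle != 0.0:
        order = 0 if is_mask else 1
        out = rotate(
            out.astype(np.float64), transform.angle, order=order,
            preserve_range=True, mode="constant", cval=0.0,
        )
    if is_mask:
        out = (out >= 0.5).astype(np.uint8)
    return out.astype(raster.dtype) if is_mask else out


def invert_transform(
    raster: np.ndarray, transform: AugmentTransform, is_mask: bool = False
) -> np.ndarray:
    """Undo ``apply_transform`` (exact for flips and 90-degree multiples)."""
    out = np.asarray(raster)
    if transform.angle != 0.0:
        order = 0 if is_mask else 1
        out = rotate(
            out.astype(np.float64), -transform.angle, order=order,
            preserve_range=True, mode="constant", cval=0.0,
        )
    if transform.hflip:
        out = out[:, ::-1]
    if is_mask:
        out = (out >= 0.5).astype(np.uint8)
    return out.astype(raster.dtype) if is_mask else out


# ---------------------------------------------------------------------------
# PNG I/O
# ---------------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG as a 2-D uint8 array."""
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")
        return np.asarray(im, dtype=np.uint8)


def write_image(image: np.ndarray, path) -> None:
    """Write a 2-D array (uint8 gray levels) as a grayscale PNG."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("write_image expects a 2-D array")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path, format="PNG")


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG; values are strictly {0, 1}.

    Non-binary pixel values are thresholded at 128 with a logged warning.
    """
    arr = read_image(path)
    levels = np.unique(arr)
    if not np.all(np.isin(levels, (0, 255))):
        logger.warning("mask %s is not binary; thresholding at 128", path)
    return (arr >= 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a {0,1} mask as an 8-bit PNG (foreground = 255)."""
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("write_mask expects values in {0, 1}")
    write_image(arr.astype(np.uint8) * 255, path)
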