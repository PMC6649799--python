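"""Breast segmentation and quality control for CC-view mammograms.

The feature-extraction stage operates only on pixels belonging to the
breast.  This module separates the breast from the dark background of a
digitized film mammogram, discards detached bright objects (view labels,
markers), and rejects images whose segmentation or contrast range makes
texture measurement unreliable.

Only craniocaudal (CC) views are processed.  On CC views the breast forms
a single bright region attached to exactly one lateral image border (the
chest wall); that geometry is what the segmenter checks.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk


class View(str, enum.Enum):
    CC = "CC"
    MLO = "MLO"


class Laterality(str, enum.Enum):
    L = "L"
    R = "R"


class QCReason(str, enum.Enum):
    OK = "ok"
    LOW_CONTRAST_RANGE = "low_contrast_range"
    SEGMENTATION_FAILED = "segmentation_failed"
    WRONG_VIEW = "wrong_view"
    NEGATIVE_IMAGE = "negative_image"


class SegmentationError(RuntimeError):
    """Raised when no acceptable breast region can be found."""


@dataclass
class RawImage:
    """A single digitized mammogram.

    pixels are nonnegative integers in arbitrary digitizer units; the
    texture features downstream are invariant to any monotone remapping
    of these units, so no calibration is attempted here.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    view: View = View.CC
    laterality: Laterality = Laterality.L
    image_id: str = ""
    woman_id: str = ""
    visit_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if min(self.pixels.shape) < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if not 8 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in [8, 16]")
        if self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError("pixel values outside [0, 2^bit_depth - 1]")
        self.view = View(self.view)
        self.laterality = Laterality(self.laterality)

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class BreastMask:
    """Boolean support of the segmented breast region."""

    mask: np.ndarray
    area_fraction: float
    chest_wall_side: str = "left"  # lateral border the breast touches

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class QCReport:
    passed: bool
    reason: QCReason
    range_fraction: float = float("nan")
    area_fraction: float = float("nan")
    image_id: str = ""
    woman_id: str = ""


# smallest/largest plausible breast area as a fraction of the frame
_AREA_BOUNDS = (0.05, 0.95)
_CLOSING_RADIUS = 5


def segment_breast(image: RawImage) -> BreastMask:
    """Segment the breast from the background of a CC-view mammogram.

    Global Otsu threshold, morphological closing (disk radius 5 px), hole
    filling, then selection of the largest 4-connected component.  Bright
    objects not connected to the breast (labels, markers) fall outside the
    selected component and are excluded.

    Raises :class:`SegmentationError` when no foreground exists, when the
    chosen component touches no lateral border (or both), or when its area
    fraction is outside (0.05, 0.95).
    """
    if image.view != View.CC:
        raise SegmentationError("only CC views are segmented")
    pixels = np.asarray(image.pixels, dtype=np.float64)
    if pixels.max() == pixels.min():
        raise SegmentationError("no foreground: constant image")
    thresh = threshold_otsu(pixels)
    fg = pixels > thresh
    if not fg.any():
        raise SegmentationError("no foreground after thresholding")
    fg = closing(fg, disk(_CLOSING_RADIUS))
    fg = ndimage.binary_fill_holes(fg)
    labels = label(fg, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()

    touches_left = bool(mask[:, 0].any())
    touches_right = bool(mask[:, -1].any())
    if touches_left == touches_right:
        raise SegmentationError(
            "breast must touch exactly one lateral border (chest wall)"
        )
    area_fraction = mask.mean()
    if not _AREA_BOUNDS[0] < area_fraction < _AREA_BOUNDS[1]:
        raise SegmentationError(
            f"breast area fraction {area_fraction:.3f} outside plausible range"
        )
    side = "left" if touches_left else "right"
    return BreastMask(mask=mask, area_fraction=float(area_fraction), chest_wall_side=side)


def normalize_chest_wall(image: RawImage, mask: BreastMask) -> tuple[RawImage, BreastMask]:
    """Flip image and mask so the chest wall is on the left border.

    Makes laterality irrelevant downstream; texture features are flip
    invariant anyway, so this only standardizes stored masks.
    """
    if mask.chest_wall_side == "left":
        return image, mask
    flipped = RawImage(
        pixels=image.pixels[:, ::-1].copy(),
        bit_depth=image.bit_depth,
        view=image.view,
        laterality=image.laterality,
        image_id=image.image_id,
        woman_id=image.woman_id,
        visit_index=image.visit_index,
    )
    return flipped, BreastMask(
        mask=mask.mask[:, ::-1].copy(),
        area_fraction=mask.area_fraction,
        chest_wall_side="left",
    )


def quality_check(
    image: RawImage,
    mask: BreastMask | None,
    min_range_fraction: float = 0.05,
) -> QCReport:
    """Decide whether an image is usable for feature extraction.

    Rejections, in order of precedence: MLO views; negative images (film
    scanned inverted, detected as background brighter than breast); and
    an abnormally low contrast range inside the breast, i.e.
    (max - min) / (2^bit_depth - 1) below ``min_range_fraction``.
    """
    ids = dict(image_id=image.image_id, woman_id=image.woman_id)
    if image.view != View.CC:
        return QCReport(False, QCReason.WRONG_VIEW, **ids)
    if mask is None:
        return QCReport(False, QCReason.SEGMENTATION_FAILED, **ids)
    inside = image.pixels[mask.mask]
    outside = image.pixels[~mask.mask]
    if outside.size and np.median(outside) > np.median(inside):
        return QCReport(
            False, QCReason.NEGATIVE_IMAGE,
            area_fraction=mask.area_fraction, **ids,
        )
    range_fraction = float(inside.max() - inside.min()) / image.max_intensity
    if range_fraction < min_range_fraction:
        return QCReport(
            False, QCReason.LOW_CONTRAST_RANGE,
            range_fraction=range_fraction, area_fraction=mask.area_fraction, **ids,
        )
    return QCReport(
        True, QCReason.OK,
        range_fraction=range_fraction, area_fraction=mask.area_fraction, **ids,
    )


def run_preprocess(image: RawImage, min_range_fraction: float = 0.05
                   ) -> tuple[BreastMask | None, QCReport]:
    """Segment then QC an image; segmentation failures become QC failures."""
    if image.view != View.CC:
        return None, quality_check(image, None, min_range_fraction)
    try:
        mask = segment_breast(image)
    except SegmentationError:
        return None, QCReport(
            False, QCReason.SEGMENTATION_FAILED,
            image_id=image.image_id, woman_id=image.woman_id,
        )
    return mask, quality_check(image, mask, min_range_fraction)


# ---------------------------------------------------------------------------
# I/O

def read_image(path: str | Path, bit_depth: int | None = None, **meta) -> RawImage:
    """Read an 8- or 16-bit grayscale PNG/TIFF as a RawImage.

    bit_depth defaults to 8 or 16 according to the stored dtype.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr[..., 0]
    if bit_depth is None:
        bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    meta.setdefault("image_id", Path(path).stem)
    return RawImage(pixels=arr.astype(np.int64), bit_depth=bit_depth, **meta)


def write_mask(path: str | Path, mask: BreastMask) -> None:
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def write_qc_reports(path: str | Path, reports: list[QCReport]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["image_id", "woman_id", "passed", "reason", "area_fraction", "range_fraction"]
        )
        for r in reports:
            writer.writerow(
                [r.image_id, r.woman_id, r.passed, r.reason.value,
                 f"{r.area_fraction:.6f}", f"{r.range_fraction:.6f}"]
            )
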