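"""Threshold binarization and structuring-element morphology.

The candidate region (e.g. a bright nodule on darker parenchyma) is
extracted by a deliberately minimal pipeline: global threshold (Otsu by
default), morphological opening then closing with a disk structuring
element, and retention of the largest 8-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, opening

from .image import GrayImage


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray                       # boolean, same shape as source
    region_pixel_count: int
    bounding_box: tuple[int, int, int, int] | None   # (rmin, rmax, cmin, cmax) inclusive

    @property
    def is_empty(self) -> bool:
        return self.region_pixel_count == 0


def otsu_threshold(image: GrayImage) -> int:
    """Otsu's threshold on the quantized gray levels."""
    return int(threshold_otsu(image.pixels, nbins=image.gray_levels))


def binarize(image: GrayImage, threshold: int | None = None) -> np.ndarray:
    """Boolean mask of pixels strictly brighter than the threshold.

    With ``threshold=None`` Otsu's method picks it from the histogram.
    Values below the gray range give an all-one mask; at or above the
    maximum level, all-zero.
    """
    if threshold is None:
        threshold = otsu_threshold(image)
    return image.pixels > threshold


def morphological_segment(binary: np.ndarray, selem_radius: int = 2) -> SegmentationResult:
    """Clean a binary mask and keep the largest 8-connected component.

    Opening (removes speckle smaller than the disk) then closing (fills
    comparable gaps) with a disk structuring element of the given radius,
    then connected-component labelling.  An empty result is signalled by a
    zero mask, count 0 and no bounding box.
    """
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")
    binary = np.asarray(binary).astype(bool)
    selem = disk(selem_radius)
    cleaned = closing(opening(binary, selem), selem)
    labels = label(cleaned, connectivity=2)
    if labels.max() == 0:
        return SegmentationResult(np.zeros_like(binary), 0, None)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(sizes.argmax())
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))
    return SegmentationResult(mask, int(mask.sum()), bbox)


def segment(image: GrayImage, threshold: int | None = None,
            selem_radius: int = 2) -> SegmentationResult:
    """Binarize then morphologically extract the candidate region."""
    return morphological_segment(binarize(image, threshold), selem_radius)
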