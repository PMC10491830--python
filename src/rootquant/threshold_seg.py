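"""Brightness-threshold segmentation of stained root micrographs.

The engine mirrors a Fiji/ImageJ-style macro: isolate the root section
from the near-white slide background, select every pixel strictly darker
than a global brightness cutoff, and express the selected (stained,
"mycorrhized") area as a fraction of the root section area — the t-index.

The threshold is a fixed global cutoff set *ex ante*; no per-image
adaptation is attempted.
"""

from __future__ import annotations

from scipy.ndimage import binary_fill_holes

import numpy as np
from skimage.measure import label

from .errors import ValidationError
from .metrics import ColonizationMeasure, t_index, trouvelot_class
from .raster_io import BinaryMask, GrayImage

__all__ = [
    "extract_root_mask",
    "threshold_select",
    "measure_threshold",
    "DEFAULT_THRESHOLD",
    "DEFAULT_BG_CUTOFF",
]

#: Default brightness threshold for the colonized ("darkest") pixels.
DEFAULT_THRESHOLD = 100

#: Default background cutoff used to isolate the root section.
DEFAULT_BG_CUTOFF = 240

#: Connected components smaller than this fraction of the image area are
#: discarded as debris when isolating the root.
MIN_COMPONENT_FRACTION = 0.001


def extract_root_mask(img: GrayImage, bg_cutoff: float = DEFAULT_BG_CUTOFF) -> BinaryMask:
    """Isolate root tissue from the background.

    Pixels darker than ``bg_cutoff`` are candidate tissue; holes are
    filled, then only 8-connected components covering at least 0.1 % of
    the image area are retained.  An empty mask is a legal result.
    """
    if not (0 <= bg_cutoff <= 255):
        raise ValidationError(f"bg_cutoff {bg_cutoff} outside [0, 255]")
    candidate = img.pixels < bg_cutoff
    if not candidate.any():
        return BinaryMask(candidate)
    filled = binary_fill_holes(candidate)
    labels, n = label(filled, connectivity=2, return_num=True)
    if n == 0:
        return BinaryMask(filled)
    min_area = MIN_COMPONENT_FRACTION * filled.size
    keep = np.zeros_like(filled)
    counts = np.bincount(labels.ravel())
    for lab in range(1, n + 1):
        if counts[lab] >= min_area:
            keep |= labels == lab
    return BinaryMask(keep)


def threshold_select(img: GrayImage, threshold: float, within: BinaryMask) -> BinaryMask:
    """Select pixels strictly below ``threshold``, restricted to ``within``.

    Strict inequality: a pixel exactly at the threshold is not selected.
    """
    if not (0 <= threshold <= 255):
        raise ValidationError(f"threshold {threshold} outside [0, 255]")
    if within.geometry != img.geometry:
        raise ValidationError(
            f"mask geometry {within.geometry} != image geometry {img.geometry}"
        )
    return BinaryMask((img.pixels < threshold) & (within.pixels > 0))


def measure_threshold(
    img: GrayImage,
    threshold: float = DEFAULT_THRESHOLD,
    bg_cutoff: float = DEFAULT_BG_CUTOFF,
    image_id: str = "",
) -> ColonizationMeasure:
    """Measure one image: root area, dark-pixel area, t-index, class.

    A frame with no detectable root yields a zero measure flagged
    ``empty`` rather than an error.
    """
    root = extract_root_mask(img, bg_cutoff)
    selected = threshold_select(img, threshold, root)
    total = root.area
    colonized = selected.area
    flags = []
    if total == 0:
        flags.append("empty")
        value = 0.0
    else:
        value = t_index(colonized, total)
    return ColonizationMeasure(
        image_id=image_id,
        colonized_area=colonized,
        reference_area=total,
        index_value=value,
        method="threshold",
        trouvelot_class=trouvelot_class(value),
        flags=tuple(flags),
    )
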