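"""IF-guided segmentation of DSB foci and inside/outside quantification.

The immunofluorescence (IF) image of a DSB marker (γH2AX, 53BP1, BRCA1) is
smoothed with a 3x3 spatial median filter, binarised with an intensity
threshold (absolute or Otsu), and the resulting mask partitions the nucleus
into "inside foci" and "outside foci" regions in which the compact-chromatin
fraction is quantified separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .classify import ClassificationMap, FractionSummary, compact_fraction
from .io import BinaryMask, IntensityImage


@dataclass
class InsideOutsideResult:
    """Compact-chromatin fractions inside vs outside the foci mask.

    ``inside`` and ``outside`` partition the nucleus mask exactly;
    each fraction is NaN-flagged (``defined`` False) when its region
    contains no classified pixel.
    """

    inside: FractionSummary
    outside: FractionSummary
    n_pixels_inside: int
    n_pixels_outside: int

    @property
    def fraction_inside(self) -> float:
        return self.inside.fraction_compact

    @property
    def fraction_outside(self) -> float:
        return self.outside.fraction_compact


def median_filter_3x3(img: IntensityImage) -> IntensityImage:
    """3x3 spatial median filter with edge replication at the borders."""
    smoothed = ndimage.median_filter(img.values, size=3, mode="nearest")
    return IntensityImage(values=smoothed,
                          channel_label=img.channel_label,
                          pixel_size_um=img.pixel_size_um)


def threshold_mask(img: IntensityImage,
                   threshold: float | str = "otsu") -> BinaryMask:
    """Binarise an intensity image: mask = (value >= threshold).

    ``threshold`` may be a numeric value or ``"otsu"`` to maximise the
    between-class variance of the image histogram.  A threshold above the
    image maximum yields an empty mask with a warning.
    """
    if isinstance(threshold, str):
        if threshold.lower() != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        thr = float(threshold_otsu(img.values))
    else:
        thr = float(threshold)
    mask = img.values >= thr
    if not mask.any():
        warnings.warn(f"threshold {thr:g} exceeds the image maximum; "
                      "mask is empty", stacklevel=2)
    return BinaryMask(values=mask,
                      provenance=f"channel={img.channel_label!r} "
                                 f"threshold={thr:g}")


def foci_mask(if_img: IntensityImage,
              threshold: float | str = "otsu",
              min_size_px: int = 0) -> BinaryMask:
    """Median-filter an IF image and threshold it into a DSB-foci mask.

    ``min_size_px`` optionally removes connected components smaller than
    that many pixels (off by default).
    """
    mask = threshold_mask(median_filter_3x3(if_img), threshold)
    if min_size_px > 0:
        lab, n = ndimage.label(mask.values, structure=np.ones((3, 3), int))
        sizes = ndimage.sum_labels(mask.values, lab, index=np.arange(1, n + 1))
        keep = np.isin(lab, 1 + np.flatnonzero(sizes >= min_size_px))
        mask = BinaryMask(keep, provenance=mask.provenance +
                          f" min_size={min_size_px}")
    return mask


def nucleus_mask(donor: IntensityImage,
                 threshold: float | str = "otsu") -> BinaryMask:
    """Segment the nucleus from the donor-channel intensity image."""
    mask = threshold_mask(median_filter_3x3(donor), threshold)
    return BinaryMask(mask.values, provenance="nucleus: " + mask.provenance)


def inside_outside(cm: ClassificationMap, foci: BinaryMask,
                   nucleus: BinaryMask) -> InsideOutsideResult:
    """Compact fractions inside (nucleus AND foci) vs outside (nucleus AND NOT foci)."""
    if foci.shape != cm.shape or nucleus.shape != cm.shape:
        raise ValueError("mask shapes must match the classification map")
    inside = BinaryMask(nucleus.values & foci.values, provenance="inside foci")
    outside = BinaryMask(nucleus.values & ~foci.values, provenance="outside foci")
    return InsideOutsideResult(
        inside=compact_fraction(cm, inside),
        outside=compact_fraction(cm, outside),
        n_pixels_inside=int(inside.values.sum()),
        n_pixels_outside=int(outside.values.sum()),
    )


def normalized_inside_fraction(res: InsideOutsideResult) -> float:
    """Inside-foci compact fraction normalised to the surrounding nucleoplasm.

    Returns NaN when the outside fraction is zero or undefined.
    """
    fo = res.fraction_outside
    if not res.outside.defined or fo == 0:
        return float("nan")
    return res.fraction_inside / fo
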