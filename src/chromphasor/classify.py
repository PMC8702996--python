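"""Reciprocal-mode cursor classification of image pixels.

Each pixel's phasor is tested against the open/compact cursor discs; the
cursor containing it assigns the label back to the image pixel.  Pixels
inside both discs go to the nearer centre (exact ties to compact); pixels
inside neither disc, or below the photon threshold, stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fret import Cursor
from .io import BinaryMask, IntensityImage
from .phasor import PhasorImage

# label codes
UNCLASSIFIED = 0
OPEN = 1
COMPACT = 2

#: Minimum photons per pixel for classification; below this the phasor
#: standard error exceeds the default cursor radius.
DEFAULT_PHOTON_THRESHOLD = 30


@dataclass
class ClassificationMap:
    """Per-pixel open/compact/unclassified labels."""

    labels: np.ndarray  # int array over {UNCLASSIFIED, OPEN, COMPACT}
    photon_threshold: float
    palette: tuple[Cursor, Cursor]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def count(self, label: int, mask: np.ndarray | None = None) -> int:
        sel = self.labels == label
        if mask is not None:
            sel &= mask
        return int(sel.sum())


@dataclass
class FractionSummary:
    """Counts of open/compact pixels and the compact fraction.

    ``fraction_compact`` is NaN (``defined`` False) when no pixel falls in
    either cursor — unclassified pixels are excluded from numerator and
    denominator.
    """

    n_open: int
    n_compact: int

    @property
    def defined(self) -> bool:
        return (self.n_open + self.n_compact) > 0

    @property
    def fraction_compact(self) -> float:
        total = self.n_open + self.n_compact
        return self.n_compact / total if total else float("nan")


def classify_pixels(ph: PhasorImage, palette: tuple[Cursor, Cursor],
                    photon_threshold: float = DEFAULT_PHOTON_THRESHOLD,
                    ) -> ClassificationMap:
    """Map the cursor palette back onto image pixels."""
    open_cursor, compact_cursor = _check_palette(palette)
    labels = np.full(ph.shape, UNCLASSIFIED, dtype=np.uint8)
    ok = ph.defined() & (ph.photons >= photon_threshold)
    g, s = ph.g, ph.s
    d_open = (g - open_cursor.center.g) ** 2 + (s - open_cursor.center.s) ** 2
    d_comp = (g - compact_cursor.center.g) ** 2 + (s - compact_cursor.center.s) ** 2
    in_open = ok & (d_open <= open_cursor.radius ** 2)
    in_comp = ok & (d_comp <= compact_cursor.radius ** 2)
    labels[in_open & ~in_comp] = OPEN
    labels[in_comp & ~in_open] = COMPACT
    both = in_open & in_comp
    # nearer centre wins; ties (to numerical precision) go to compact
    tie = np.isclose(d_open, d_comp, rtol=1e-9, atol=1e-15)
    labels[both & (d_open < d_comp) & ~tie] = OPEN
    labels[both & ((d_comp <= d_open) | tie)] = COMPACT
    return ClassificationMap(labels=labels, photon_threshold=photon_threshold,
                             palette=(open_cursor, compact_cursor))


def compact_fraction(cm: ClassificationMap,
                     mask: BinaryMask | None = None) -> FractionSummary:
    """Fraction of classified pixels labelled compact, optionally in a mask."""
    sel = None
    if mask is not None:
        if mask.shape != cm.shape:
            raise ValueError("mask shape does not match classification map")
        sel = mask.values
    return FractionSummary(n_open=cm.count(OPEN, sel),
                           n_compact=cm.count(COMPACT, sel))


def acceptor_excess_check(donor: IntensityImage, acceptor: IntensityImage,
                          nucleus: BinaryMask) -> tuple[float, bool]:
    """Check that the FRET acceptor is in excess of the donor.

    Returns (mean acceptor / mean donor over the nucleus, ratio > 1).
    A FRET experiment is only interpretable when every donor has acceptors
    available, hence the strict > 1 requirement.
    """
    if donor.shape != acceptor.shape or donor.shape != nucleus.shape:
        raise ValueError("donor, acceptor and nucleus shapes must match")
    if not nucleus.values.any():
        raise ValueError("nucleus mask is empty")
    donor_mean = float(donor.values[nucleus.values].mean())
    if donor_mean == 0:
        raise ZeroDivisionError("zero mean donor intensity in the nucleus")
    ratio = float(acceptor.values[nucleus.values].mean()) / donor_mean
    return ratio, ratio > 1.0


def _check_palette(palette) -> tuple[Cursor, Cursor]:
    labels = sorted(c.label for c in palette)
    if len(palette) != 2 or labels != ["compact", "open"]:
        raise ValueError("palette must contain exactly one open and one "
                         "compact cursor")
    open_cursor = next(c for c in palette if c.label == "open")
    compact_cursor = next(c for c in palette if c.label == "compact")
    return open_cursor, compact_cursor


def export_label_map(cm: ClassificationMap, path) -> None:
    """Write the label map as an RGB TIFF (teal=open, red=compact, black=unclassified)."""
    import tifffile
    rgb = np.zeros(cm.shape + (3,), dtype=np.uint8)
    rgb[cm.labels == OPEN] = (0, 128, 128)
    rgb[cm.labels == COMPACT] = (255, 0, 0)
    tifffile.imwrite(path, rgb)
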