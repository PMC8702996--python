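"""Reading and writing of FLIM decay stacks, intensity images, masks and tables.

Decay stacks are stored as plain multi-page grayscale TIFF (one page per time
bin) with a JSON sidecar carrying the acquisition metadata (laser repetition
rate, number of time bins, pixel size, harmonic).  This keeps the container
lossless and tool-agnostic; vendor FLIM formats are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Raised when a file on disk does not match the expected layout."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """FLIM acquisition parameters.

    Parameters
    ----------
    rep_rate_hz : float
        Laser repetition frequency in Hz.  The decay histogram spans one
        period ``T = 1 / rep_rate_hz``.
    n_bins : int
        Number of time bins per laser period.
    pixel_size_um : float
        Pixel edge length in micrometres.
    harmonic : int
        Harmonic number used in the phasor transform (1 = fundamental).
    """

    rep_rate_hz: float = 80e6
    n_bins: int = 256
    pixel_size_um: float = 0.09
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.rep_rate_hz <= 0:
            raise ValueError("rep_rate_hz must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.harmonic < 1:
            raise ValueError("harmonic must be a positive integer")

    @property
    def period_s(self) -> float:
        return 1.0 / self.rep_rate_hz

    @property
    def omega(self) -> float:
        """Angular frequency of the selected harmonic, rad/s."""
        return 2.0 * np.pi * self.harmonic * self.rep_rate_hz

    def bin_centers_s(self) -> np.ndarray:
        """Bin-center times over one period.

        Bin ``b`` covers ``[b, b+1) * T / n_bins``; decay counts are
        attributed to the bin center to minimise discretisation bias of the
        phasor integral.
        """
        dt = self.period_s / self.n_bins
        return (np.arange(self.n_bins) + 0.5) * dt

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "rep_rate_hz": self.rep_rate_hz,
            "n_bins": self.n_bins,
            "pixel_size_um": self.pixel_size_um,
            "harmonic": self.harmonic,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        d = json.loads(Path(path).read_text())
        return cls(rep_rate_hz=d["rep_rate_hz"], n_bins=int(d["n_bins"]),
                   pixel_size_um=d["pixel_size_um"], harmonic=int(d["harmonic"]))


@dataclass
class DecayImage:
    """Per-pixel photon-count decay histograms, indexed (row, col, bin)."""

    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-D (row, col, bin)")
        if 0 in self.counts.shape:
            raise ValueError("counts must be non-empty in every axis")
        if self.counts.shape[2] != self.meta.n_bins:
            raise ValueError(
                f"bin axis length {self.counts.shape[2]} != meta.n_bins "
                f"{self.meta.n_bins}")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            err = float(np.abs(self.counts - rounded).max())
            if err > 1e-6:
                raise ValueError(
                    f"non-integer photon counts (max rounding error {err:g})")
            self.counts = rounded.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    def photon_sum(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=2)


@dataclass
class IntensityImage:
    """A 2-D intensity image for one detection channel."""

    values: np.ndarray
    channel_label: str = ""
    pixel_size_um: float = 0.09

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity values must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """A 2-D boolean region mask with provenance text."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & other.values,
                          provenance=f"({self.provenance}) AND ({other.provenance})")

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.values, provenance=f"NOT ({self.provenance})")


# ---------------------------------------------------------------------------
# readers / writers

def read_decay_stack(path: str | Path, meta: AcquisitionMeta) -> DecayImage:
    """Read a multi-page TIFF decay stack.

    Page ``b`` of the file becomes ``counts[:, :, b]``.  The page count must
    equal ``meta.n_bins``; float data are integer-cast with the rounding
    error checked.
    """
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise FormatError(f"expected a multi-page 2-D TIFF, got shape {pages.shape}")
    if pages.shape[0] != meta.n_bins:
        raise FormatError(
            f"decay stack has {pages.shape[0]} pages but meta.n_bins is "
            f"{meta.n_bins}")
    counts = np.moveaxis(pages, 0, 2)
    if np.any(counts < 0):
        raise ValueError("decay stack contains negative values")
    return DecayImage(counts=counts, meta=meta)


def write_decay_stack(img: DecayImage, path: str | Path) -> None:
    """Write a decay stack as a multi-page TIFF (page b = counts[:, :, b])."""
    pages = np.moveaxis(img.counts, 2, 0)
    dtype = np.uint16 if pages.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, pages.astype(dtype), photometric="minisblack")


def read_intensity(path: str | Path, channel_label: str = "",
                   pixel_size_um: float = 0.09) -> IntensityImage:
    """Read a single-page grayscale TIFF intensity image."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
        raise FormatError("multi-page TIFF passed to read_intensity")
    if arr.ndim != 2:
        raise FormatError(f"grayscale single-page TIFF required, got shape {arr.shape}")
    return IntensityImage(values=arr, channel_label=channel_label,
                          pixel_size_um=pixel_size_um)


def write_intensity(img: IntensityImage, path: str | Path) -> None:
    tifffile.imwrite(path, img.values.astype(np.float32))


def read_mask(path: str | Path, provenance: str = "") -> BinaryMask:
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise FormatError("mask TIFF must be single-page grayscale")
    return BinaryMask(values=arr > 0, provenance=provenance or str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 8-bit TIFF with foreground = 255."""
    tifffile.imwrite(path, (mask.values.astype(np.uint8) * 255))


def write_table(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular rows as comma-separated text with a header line."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)
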