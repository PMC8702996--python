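"""Per-pixel phasor transform, reference calibration and phasor algebra.

The phasor of a decay histogram :math:`C_b` at harmonic :math:`n` is

.. math::

    g = \\frac{\\sum_b C_b \\cos(\\omega t_b)}{\\sum_b C_b}, \\qquad
    s = \\frac{\\sum_b C_b \\sin(\\omega t_b)}{\\sum_b C_b},

with :math:`t_b` the bin centre, :math:`\\omega = 2\\pi n / T` and
:math:`T` the laser period.  Single-exponential decays fall on the universal
semicircle :math:`(g - 1/2)^2 + s^2 = 1/4`; mixtures of species combine
linearly, weighted by intensity fraction.  All decays are treated as
*wrapped* (periodic) exponentials, appropriate for 80 MHz excitation where
nanosecond decays do not fully relax within the 12.5 ns period; the
closed-form single-exponential phasor is exact for the wrapped decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .io import AcquisitionMeta, DecayImage


class CalibrationError(ValueError):
    """Raised when a calibration reference is degenerate."""


@dataclass(frozen=True)
class PhasorPoint:
    """A single point (g, s) in phasor space."""

    g: float
    s: float

    def as_complex(self) -> complex:
        return complex(self.g, self.s)

    @property
    def modulation(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.s, self.g))


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates with the photon sum.

    Pixels with zero photons have no defined phasor; their ``g``/``s`` are
    NaN and :meth:`defined` is False there.  NaN rather than (0, 0) is used
    because (0, 0) is a legal phasor (the infinite-lifetime limit).
    """

    g: np.ndarray
    s: np.ndarray
    photons: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        if not (self.g.shape == self.s.shape == self.photons.shape):
            raise ValueError("g, s and photons must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape

    def defined(self) -> np.ndarray:
        """Boolean map of pixels with a defined phasor."""
        return ~np.isnan(self.g)

    def mean_phasor(self, min_photons: float = 0.0) -> PhasorPoint:
        """Photon-weighted mean phasor over defined pixels.

        Weighting by photons makes the mean equal the phasor of the pooled
        decay (phasor linearity).
        """
        ok = self.defined() & (self.photons >= min_photons)
        w = self.photons[ok].astype(float)
        if w.sum() <= 0:
            raise ValueError("no photons in the selected pixels")
        return PhasorPoint(float(np.average(self.g[ok], weights=w)),
                           float(np.average(self.s[ok], weights=w)))


@dataclass(frozen=True)
class CalibrationReference:
    """A reference-dye measurement with known single-exponential lifetime."""

    measured: PhasorPoint
    known_lifetime_ns: float
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        if self.known_lifetime_ns <= 0:
            raise ValueError("known_lifetime_ns must be positive")
        if self.measured.modulation == 0:
            raise CalibrationError("reference modulation is zero")


def phasor_transform(img: DecayImage) -> PhasorImage:
    """Transform a decay stack to per-pixel phasor coordinates.

    Returns NaN phasors at zero-photon pixels; photon sums are conserved
    exactly.
    """
    meta = img.meta
    t = meta.bin_centers_s()
    w = meta.omega
    cos_b = np.cos(w * t)
    sin_b = np.sin(w * t)
    counts = img.counts.astype(float)
    photons = counts.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (counts @ cos_b) / photons
        s = (counts @ sin_b) / photons
    empty = photons == 0
    g[empty] = np.nan
    s[empty] = np.nan
    return PhasorImage(g=g, s=s, photons=img.counts.sum(axis=2), meta=meta)


def single_exponential_phasor(tau_ns: float, meta: AcquisitionMeta) -> PhasorPoint:
    """Closed-form phasor of a single-exponential decay.

    ``g = 1/(1 + (wt)^2)``, ``s = wt/(1 + (wt)^2)`` with
    ``w = 2*pi*harmonic*rep_rate`` — exact for the wrapped periodic decay.
    """
    if tau_ns <= 0:
        raise ValueError("tau_ns must be positive")
    wt = meta.omega * tau_ns * 1e-9
    return PhasorPoint(1.0 / (1.0 + wt * wt), wt / (1.0 + wt * wt))


def calibrate(ph: PhasorImage, ref: CalibrationReference) -> PhasorImage:
    """Apply a global phase/modulation correction from a reference dye.

    Treating (g, s) as the complex number ``z = g + i s``, every pixel is
    multiplied by ``z_theory(ref) / z_measured(ref)`` — a rotation by the
    instrument phase error and a scaling by the modulation error.  The
    reference measurement absorbs the instrument response; no per-pixel IRF
    deconvolution is attempted.
    """
    z_meas = ref.measured.as_complex()
    if abs(z_meas) == 0:
        raise CalibrationError("measured reference phasor has zero modulation")
    z_theory = single_exponential_phasor(ref.known_lifetime_ns, ref.meta).as_complex()
    corr = z_theory / z_meas
    z = ph.g + 1j * ph.s
    zc = z * corr
    return PhasorImage(g=zc.real, s=zc.imag, photons=ph.photons, meta=ph.meta)


def lifetime_from_phasor(p: PhasorPoint, meta: AcquisitionMeta) -> tuple[float, float]:
    """Invert a phasor to (phase lifetime, modulation lifetime) in ns.

    ``tau_phase = s / (g * w)``; ``tau_mod = sqrt(1/(g^2+s^2) - 1) / w``.
    The two agree exactly on the universal circle (single exponentials).
    """
    if p.g <= 0:
        raise ValueError("phase lifetime undefined for g <= 0")
    m2 = p.g * p.g + p.s * p.s
    if not (0 < m2 <= 1 + 1e-12):
        raise ValueError("phasor modulation must lie in (0, 1]")
    w = meta.omega
    tau_phase = (p.s / p.g) / w
    tau_mod = np.sqrt(max(1.0 / m2 - 1.0, 0.0)) / w
    return tau_phase * 1e9, float(tau_mod) * 1e9


def mixture_phasor(components: list[tuple[PhasorPoint, float]]) -> PhasorPoint:
    """Intensity-weighted linear combination of component phasors."""
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("intensity fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"intensity fractions must sum to 1, got {fracs.sum()!r}")
    g = sum(f * p.g for p, f in components)
    s = sum(f * p.s for p, f in components)
    return PhasorPoint(float(g), float(s))


def export_phasor_csv(ph: PhasorImage, path) -> None:
    """Write per-pixel phasor coordinates as CSV (row, col, g, s, photons)."""
    rows, cols = np.indices(ph.shape)
    ok = ph.defined()
    pd.DataFrame({
        "row": rows[ok], "col": cols[ok],
        "g": ph.g[ok], "s": ph.s[ok], "photons": ph.photons[ok],
    }).to_csv(path, index=False)


def export_phasor_density(ph: PhasorImage, path, bins: int = 256,
                          g_range=(0.0, 1.0), s_range=(0.0, 0.6)) -> np.ndarray:
    """Export the phasor-plot density as a 2-D histogram TIFF.

    Rows of the written image run along s (bottom edge = s_range[0]),
    columns along g.
    """
    ok = ph.defined()
    hist, _, _ = np.histogram2d(ph.s[ok], ph.g[ok], bins=bins,
                                range=[s_range, g_range])
    tifffile.imwrite(path, hist.astype(np.float32))
    return hist
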