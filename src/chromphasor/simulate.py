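"""Synthetic FLIM-nucleus generator.

Emulates the imaging experiment end to end so every pipeline stage can be
tested against known ground truth: an elliptical nucleus containing "open"
chromatin (unquenched donor, 2.5 ns) and "compact" chromatin foci
(FRET-quenched donor, 16 % efficiency, 2.1 ns), disk-shaped DSB foci
co-localised with a simulated immunofluorescence channel, and an acceptor
intensity channel in excess of the donor.

Photon arrival times follow a *wrapped* exponential — at 80 MHz excitation
nanosecond decays overlap successive periods, and wrapping keeps the
closed-form single-exponential phasor exact.  Per-pixel photon counts are
Poisson; conditional on the count, the binned histogram is multinomial over
the bin-integrated wrapped-exponential probabilities, which is exactly
equivalent to binning individual draws of ``(-tau * ln U) mod T``.

Not modelled: instrument response convolution, detector afterpulsing,
photobleaching, 3-D nuclear structure, chromatin dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import AcquisitionMeta, BinaryMask, DecayImage, IntensityImage


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic nucleus.

    Defaults mirror the emulated acquisition: 256x256 frame at 90 nm/pixel,
    80 MHz repetition rate, 256 time bins; donor lifetime 2.5 ns, compact
    FRET efficiency 16 %, and on the order of 100 site-specific DSB foci.
    """

    image_size: int = 256
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    tau_open_ns: float = 2.5
    fret_e_compact: float = 0.16
    compact_area_fraction: float = 0.3
    n_compact_foci: int = 200
    compact_focus_radius_px: float = 4.0
    n_dsb_foci: int = 100
    dsb_radius_px: float = 5.0
    dsb_opens_chromatin: bool = True
    photons_per_pixel: float = 200.0
    dark_photons_per_pixel: float = 1.0
    background_fraction: float = 0.0
    autofluorescence_tau_ns: float = 1.0
    if_snr: float = 10.0
    if_background_level: float = 20.0
    acceptor_donor_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ConfigurationError("image_size must be at least 8 pixels")
        if not (0.0 <= self.fret_e_compact < 1.0):
            raise ConfigurationError("fret_e_compact must lie in [0, 1)")
        if not (0.0 <= self.compact_area_fraction <= 1.0):
            raise ConfigurationError("compact_area_fraction must lie in [0, 1]")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ConfigurationError("background_fraction must lie in [0, 1)")
        if self.photons_per_pixel <= 0:
            raise ConfigurationError("photons_per_pixel must be positive")
        for r in (self.compact_focus_radius_px, self.dsb_radius_px):
            if r >= self.image_size / 2:
                raise ConfigurationError("focus radii must be < image_size/2")


@dataclass
class GroundTruth:
    """Per-pixel truth maps underlying a simulated acquisition."""

    nucleus: BinaryMask
    compact_map: BinaryMask
    dsb_map: BinaryMask
    per_pixel_tau_ns: np.ndarray
    per_pixel_E: np.ndarray

    def compact_fraction(self) -> float:
        """True compact fraction over nucleus pixels."""
        nuc = self.nucleus.values
        return float(self.compact_map.values[nuc].mean())


def _rngs(seed: int, n: int = 5) -> list[np.random.Generator]:
    """Independent child generators from one global seed (splittable)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _disk(shape: tuple[int, int], center: tuple[float, float],
          radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def make_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Lay out the nucleus, compact-chromatin foci and DSB foci.

    The nucleus is a centred ellipse covering ~70 % of the frame.  Compact
    foci are random disks dropped until ``compact_area_fraction`` of the
    nucleus is covered (within 2 %); DSB foci are ``n_dsb_foci`` random
    disks.  With ``dsb_opens_chromatin``, compact pixels inside DSB disks
    are reassigned to open chromatin, emulating decompaction at break sites.
    Deterministic given ``cfg.seed``.
    """
    rng = _rngs(cfg.seed)[0]
    n = cfg.image_size
    c = (n - 1) / 2.0
    rr, cc = np.ogrid[:n, :n]
    # semi-axes 0.48/0.46 of the frame: area pi*0.48*0.46 ~ 0.69 of the frame
    nucleus = ((rr - c) / (0.48 * n)) ** 2 + ((cc - c) / (0.46 * n)) ** 2 <= 1.0
    nucleus_area = int(nucleus.sum())

    compact = np.zeros((n, n), dtype=bool)
    target = cfg.compact_area_fraction
    if target > 0:
        nuc_rows, nuc_cols = np.nonzero(nucleus)
        max_attempts = max(50 * cfg.n_compact_foci, 2000)
        attempts = 0
        while compact[nucleus].mean() < target:
            if attempts >= max_attempts:
                raise ConfigurationError(
                    f"could not reach compact_area_fraction={target} with "
                    f"radius {cfg.compact_focus_radius_px} after "
                    f"{max_attempts} attempts")
            i = rng.integers(len(nuc_rows))
            disk = _disk((n, n), (nuc_rows[i], nuc_cols[i]),
                         cfg.compact_focus_radius_px)
            compact |= disk & nucleus
            attempts += 1

    dsb = np.zeros((n, n), dtype=bool)
    if cfg.n_dsb_foci > 0:
        nuc_rows, nuc_cols = np.nonzero(nucleus)
        idx = rng.integers(len(nuc_rows), size=cfg.n_dsb_foci)
        for i in idx:
            dsb |= _disk((n, n), (nuc_rows[i], nuc_cols[i]), cfg.dsb_radius_px)
        dsb &= nucleus

    if cfg.dsb_opens_chromatin:
        compact &= ~dsb

    E = np.where(compact, cfg.fret_e_compact, 0.0)
    E[~nucleus] = 0.0
    tau = cfg.tau_open_ns * (1.0 - E)
    return GroundTruth(
        nucleus=BinaryMask(nucleus, "simulated nucleus"),
        compact_map=BinaryMask(compact, "simulated compact chromatin"),
        dsb_map=BinaryMask(dsb, "simulated DSB foci"),
        per_pixel_tau_ns=tau,
        per_pixel_E=E,
    )


def decay_bin_probabilities(tau_ns: float, meta: AcquisitionMeta) -> np.ndarray:
    """Bin-integrated probabilities of a wrapped exponential over one period."""
    T = meta.period_s
    tau = tau_ns * 1e-9
    edges = np.linspace(0.0, T, meta.n_bins + 1)
    q = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    return q / (1.0 - np.exp(-T / tau))


def ideal_decay_counts(tau_ns: float, meta: AcquisitionMeta,
                       total_photons: float = 1e9) -> np.ndarray:
    """Noiseless (expected-value) decay histogram, integer-rounded."""
    return np.rint(decay_bin_probabilities(tau_ns, meta) * total_photons
                   ).astype(np.int64)


def _fill_species(counts: np.ndarray, pix: np.ndarray, n_photons: np.ndarray,
                  tau_ns: float, meta: AcquisitionMeta,
                  rng: np.random.Generator) -> None:
    """Add multinomial wrapped-exponential draws for one lifetime species."""
    if len(pix[0]) == 0:
        return
    q = decay_bin_probabilities(tau_ns, meta)
    counts[pix] += rng.multinomial(n_photons, q)


def simulate_decay_image(gt: GroundTruth, cfg: SimulationConfig,
                         ) -> tuple[DecayImage, IntensityImage, IntensityImage]:
    """Generate the donor decay stack, acceptor image and IF image.

    Per nucleus pixel the photon count is Poisson(``photons_per_pixel``);
    each photon comes from the pixel's donor species (lifetime
    ``tau_open * (1 - E)``) or, with probability ``background_fraction``,
    from autofluorescence.  Outside the nucleus only uniform dark counts
    occur.  The acceptor channel is Poisson with mean
    ``acceptor_donor_ratio x photons_per_pixel`` in the nucleus; the IF
    channel shows Gaussian-profile spots (sigma = dsb_radius/2, peak
    ``if_snr x`` background) at the DSB foci over a Poisson background.
    Deterministic given ``cfg.seed``.
    """
    _, rng_noise, rng_acc, rng_if, _ = _rngs(cfg.seed)
    n = cfg.image_size
    meta = cfg.meta
    counts = np.zeros((n, n, meta.n_bins), dtype=np.int64)

    nucleus = gt.nucleus.values
    n_total = rng_noise.poisson(cfg.photons_per_pixel, size=(n, n))
    n_total[~nucleus] = 0
    f_b = cfg.background_fraction
    n_bg = (rng_noise.binomial(n_total, f_b) if f_b > 0
            else np.zeros_like(n_total))
    n_donor = n_total - n_bg

    for tau in np.unique(gt.per_pixel_tau_ns[nucleus]):
        pix = np.nonzero(nucleus & (gt.per_pixel_tau_ns == tau))
        _fill_species(counts, pix, n_donor[pix], tau, meta, rng_noise)
    if f_b > 0:
        pix = np.nonzero(nucleus)
        _fill_species(counts, pix, n_bg[pix], cfg.autofluorescence_tau_ns,
                      meta, rng_noise)
    if cfg.dark_photons_per_pixel > 0:
        # dark counts are uncorrelated with the laser: uniform over bins
        dark = rng_noise.poisson(cfg.dark_photons_per_pixel / meta.n_bins,
                                 size=counts.shape)
        counts += dark

    donor = DecayImage(counts=counts, meta=meta)

    acc_mean = np.where(nucleus,
                        cfg.acceptor_donor_ratio * cfg.photons_per_pixel,
                        cfg.dark_photons_per_pixel)
    acceptor = IntensityImage(rng_acc.poisson(acc_mean).astype(float),
                              channel_label="acceptor",
                              pixel_size_um=meta.pixel_size_um)

    if_img = _simulate_if_channel(gt, cfg, rng_if)
    return donor, acceptor, if_img


def _simulate_if_channel(gt: GroundTruth, cfg: SimulationConfig,
                         rng: np.random.Generator) -> IntensityImage:
    from scipy import ndimage
    n = cfg.image_size
    sigma = cfg.dsb_radius_px / 2.0
    spots = ndimage.gaussian_filter(gt.dsb_map.values.astype(float), sigma)
    if spots.max() > 0:
        spots /= spots.max()
    mean = cfg.if_background_level * (1.0 + cfg.if_snr * spots)
    return IntensityImage(rng.poisson(mean).astype(float),
                          channel_label="IF",
                          pixel_size_um=cfg.meta.pixel_size_um)


def simulate_reference(tau_ns: float, meta: AcquisitionMeta | None = None,
                       shape: tuple[int, int] = (8, 8),
                       photons_per_pixel: float = 1e6,
                       noiseless: bool = True,
                       shift_bins: int = 0,
                       uniform_admixture: float = 0.0,
                       seed: int = 0) -> DecayImage:
    """Simulate a spatially uniform reference-dye decay stack.

    Optional corruptions exercise calibration: ``shift_bins`` circularly
    delays the decay by whole bins (a pure phasor rotation by
    ``omega * shift_bins * T / n_bins``) and ``uniform_admixture`` replaces
    that intensity fraction with uniform counts (a pure modulation scaling
    by ``1 - uniform_admixture``).
    """
    meta = meta or AcquisitionMeta()
    if not (0.0 <= uniform_admixture < 1.0):
        raise ValueError("uniform_admixture must lie in [0, 1)")
    q = decay_bin_probabilities(tau_ns, meta)
    q = np.roll(q, shift_bins)
    q = (1.0 - uniform_admixture) * q + uniform_admixture / meta.n_bins
    if noiseless:
        page = np.rint(q * photons_per_pixel).astype(np.int64)
        counts = np.broadcast_to(page, shape + (meta.n_bins,)).copy()
    else:
        rng = np.random.default_rng(seed)
        n_phot = rng.poisson(photons_per_pixel, size=shape)
        counts = rng.multinomial(n_phot, q)
    return DecayImage(counts=counts, meta=meta)


def reference_corruption_effect(shift_bins: int, uniform_admixture: float,
                                meta: AcquisitionMeta) -> tuple[float, float]:
    """Exact (rotation_rad, modulation_scale) produced by the corruptions."""
    return (meta.omega * shift_bins * meta.period_s / meta.n_bins,
            1.0 - uniform_admixture)
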