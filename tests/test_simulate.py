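import numpy as np
import pytest

from chromphasor import (AcquisitionMeta, CalibrationReference,
                         SimulationConfig, calibrate, classify_pixels,
                         compact_fraction, default_palette,
                         lifetime_from_phasor, make_ground_truth,
                         phasor_transform, simulate_decay_image,
                         simulate_reference, single_exponential_phasor)
from chromphasor.simulate import (ConfigurationError,
                                  reference_corruption_effect)


def small_cfg(**kw):
    defaults = dict(image_size=64, n_compact_foci=40,
                    compact_focus_radius_px=3.0, n_dsb_foci=10,
                    dsb_radius_px=3.0, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGroundTruth:
    def test_zero_compact_fraction_gives_empty_map(self):
        gt = make_ground_truth(small_cfg(compact_area_fraction=0.0))
        assert not gt.compact_map.values.any()

    def test_same_seed_reproduces_identical_truth(self):
        a = make_ground_truth(small_cfg(seed=9))
        b = make_ground_truth(small_cfg(seed=9))
        np.testing.assert_array_equal(a.compact_map.values, b.compact_map.values)
        np.testing.assert_array_equal(a.dsb_map.values, b.dsb_map.values)
        np.testing.assert_array_equal(a.per_pixel_tau_ns, b.per_pixel_tau_ns)

    def test_realized_compact_fraction_near_request(self):
        gt = make_ground_truth(small_cfg(compact_area_fraction=0.3,
                                         dsb_opens_chromatin=False,
                                         n_dsb_foci=0))
        assert gt.compact_fraction() == pytest.approx(0.3, abs=0.02)

    def test_nucleus_contains_all_structure(self):
        gt = make_ground_truth(small_cfg())
        nuc = gt.nucleus.values
        assert not (gt.compact_map.values & ~nuc).any()
        assert not (gt.dsb_map.values & ~nuc).any()

    def test_dsb_opens_chromatin_clears_overlap(self):
        gt = make_ground_truth(small_cfg(dsb_opens_chromatin=True,
                                         n_dsb_foci=15))
        assert not (gt.compact_map.values & gt.dsb_map.values).any()

    def test_per_pixel_efficiency_map(self):
        cfg = small_cfg()
        gt = make_ground_truth(cfg)
        assert set(np.unique(gt.per_pixel_E)) <= {0.0, cfg.fret_e_compact}
        np.testing.assert_allclose(
            gt.per_pixel_tau_ns,
            cfg.tau_open_ns * (1 - gt.per_pixel_E))

    def test_unreachable_area_fraction_raises(self):
        with pytest.raises(ConfigurationError):
            make_ground_truth(small_cfg(compact_area_fraction=0.99,
                                        compact_focus_radius_px=1.0,
                                        n_compact_foci=1))

    @pytest.mark.parametrize("kwargs", [
        {"fret_e_compact": 1.0}, {"compact_area_fraction": 1.5},
        {"background_fraction": 1.0}, {"photons_per_pixel": 0},
        {"dsb_radius_px": 64.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            small_cfg(**kwargs)


class TestSimulatedAcquisition:
    def test_bit_reproducibility(self):
        cfg = small_cfg(seed=3)
        gt = make_ground_truth(cfg)
        d1, a1, i1 = simulate_decay_image(gt, cfg)
        d2, a2, i2 = simulate_decay_image(gt, cfg)
        np.testing.assert_array_equal(d1.counts, d2.counts)
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(i1.values, i2.values)

    def test_photon_counts_are_poisson(self):
        cfg = small_cfg(photons_per_pixel=50, dark_photons_per_pixel=0,
                        n_dsb_foci=0, compact_area_fraction=0.0)
        gt = make_ground_truth(cfg)
        donor, _, _ = simulate_decay_image(gt, cfg)
        totals = donor.photon_sum()[gt.nucleus.values]
        assert totals.mean() == pytest.approx(50, rel=0.05)
        assert totals.var() == pytest.approx(totals.mean(), rel=0.15)

    def test_all_open_nucleus_centroid_at_unquenched_donor(self, meta):
        cfg = small_cfg(compact_area_fraction=0.0, n_dsb_foci=0,
                        photons_per_pixel=500, dark_photons_per_pixel=0)
        gt = make_ground_truth(cfg)
        donor, _, _ = simulate_decay_image(gt, cfg)
        p = phasor_transform(donor).mean_phasor(min_photons=1)
        assert p.g == pytest.approx(0.39, abs=0.01)
        assert p.s == pytest.approx(0.49, abs=0.01)

    def test_all_compact_nucleus_centroid_at_quenched_donor(self, meta):
        cfg = small_cfg(compact_area_fraction=1.0, n_compact_foci=500,
                        compact_focus_radius_px=10.0, n_dsb_foci=0,
                        dsb_opens_chromatin=False,
                        photons_per_pixel=500, dark_photons_per_pixel=0)
        gt = make_ground_truth(cfg)
        donor, _, _ = simulate_decay_image(gt, cfg)
        p = phasor_transform(donor).mean_phasor(min_photons=1)
        assert p.g == pytest.approx(0.47, abs=0.01)
        assert p.s == pytest.approx(0.50, abs=0.01)

    def test_acceptor_exceeds_donor(self):
        cfg = small_cfg(acceptor_donor_ratio=2.0)
        gt = make_ground_truth(cfg)
        donor, acceptor, _ = simulate_decay_image(gt, cfg)
        nuc = gt.nucleus.values
        ratio = acceptor.values[nuc].mean() / donor.photon_sum()[nuc].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_if_channel_bright_at_dsb_foci(self):
        cfg = small_cfg(n_dsb_foci=8, if_snr=10.0)
        gt = make_ground_truth(cfg)
        _, _, if_img = simulate_decay_image(gt, cfg)
        inside = if_img.values[gt.dsb_map.values].mean()
        outside = if_img.values[gt.nucleus.values & ~gt.dsb_map.values].mean()
        assert inside > 3 * outside

    def test_increasing_efficiency_rotates_centroid_along_circle(self, meta):
        # higher FRET efficiency = shorter lifetime = larger g
        gs = []
        for E in [0.1, 0.16, 0.3]:
            cfg = small_cfg(compact_area_fraction=1.0, n_compact_foci=500,
                            compact_focus_radius_px=10.0, n_dsb_foci=0,
                            dsb_opens_chromatin=False, fret_e_compact=E,
                            photons_per_pixel=300, dark_photons_per_pixel=0)
            gt = make_ground_truth(cfg)
            donor, _, _ = simulate_decay_image(gt, cfg)
            gs.append(phasor_transform(donor).mean_phasor(min_photons=1).g)
        assert gs == sorted(gs)

    def test_background_species_pulls_phasor_off_circle(self, meta):
        cfg = small_cfg(compact_area_fraction=0.0, n_dsb_foci=0,
                        photons_per_pixel=1000, dark_photons_per_pixel=0,
                        background_fraction=0.4,
                        autofluorescence_tau_ns=0.3)
        gt = make_ground_truth(cfg)
        donor, _, _ = simulate_decay_image(gt, cfg)
        p = phasor_transform(donor).mean_phasor(min_photons=1)
        pure = single_exponential_phasor(2.5, meta)
        bg = single_exponential_phasor(0.3, meta)
        expected_g = 0.6 * pure.g + 0.4 * bg.g
        assert p.g == pytest.approx(expected_g, abs=0.02)


class TestSimulatedReference:
    def test_noiseless_fluorescein_phasor(self, meta):
        ref = simulate_reference(4.04, meta)
        p = phasor_transform(ref).mean_phasor()
        assert p.g == pytest.approx(0.195, abs=2e-3)
        assert p.s == pytest.approx(0.396, abs=2e-3)

    def test_corruption_then_calibration_recovers_truth(self, meta):
        shift, admix = 12, 0.15
        corrupted = simulate_reference(4.04, meta, shift_bins=shift,
                                       uniform_admixture=admix,
                                       photons_per_pixel=1e9)
        measured = phasor_transform(corrupted).mean_phasor()
        ref = CalibrationReference(measured, 4.04, meta)
        # calibrating the corrupted stack against itself restores the dye
        cal = calibrate(phasor_transform(corrupted), ref)
        ideal = single_exponential_phasor(4.04, meta)
        assert cal.g[0, 0] == pytest.approx(ideal.g, abs=1e-6)
        assert cal.s[0, 0] == pytest.approx(ideal.s, abs=1e-6)

    def test_corruption_effect_is_exact_rotation_and_scaling(self, meta):
        shift, admix = 7, 0.2
        clean = phasor_transform(simulate_reference(
            4.04, meta, photons_per_pixel=1e9)).mean_phasor()
        corrupted = phasor_transform(simulate_reference(
            4.04, meta, shift_bins=shift, uniform_admixture=admix,
            photons_per_pixel=1e9)).mean_phasor()
        rot, scale = reference_corruption_effect(shift, admix, meta)
        z = clean.as_complex() * scale * np.exp(1j * rot)
        assert corrupted.g == pytest.approx(z.real, abs=1e-6)
        assert corrupted.s == pytest.approx(z.imag, abs=1e-6)

    def test_noisy_reference_converges_to_closed_form(self, meta):
        ref = simulate_reference(4.04, meta, noiseless=False,
                                 photons_per_pixel=5000, seed=2)
        p = phasor_transform(ref).mean_phasor()
        ideal = single_exponential_phasor(4.04, meta)
        assert p.g == pytest.approx(ideal.g, abs=0.01)
        assert p.s == pytest.approx(ideal.s, abs=0.01)
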