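"""Compact-chromatin mapping on a synthetic nucleus.

Simulates a 128-pixel nucleus with 40 % compact chromatin at 500 photons
per pixel, phasor-transforms the decay stack, classifies every pixel with
the open/compact cursor palette, and compares the recovered compact
fraction with the simulator's ground truth.
"""

from chromphasor import (SimulationConfig, classify_pixels, compact_fraction,
                         default_palette, make_ground_truth, phasor_transform,
                         simulate_decay_image)

cfg = SimulationConfig(image_size=128, photons_per_pixel=500,
                       compact_area_fraction=0.4, n_compact_foci=80,
                       compact_focus_radius_px=3.0, n_dsb_foci=0,
                       dsb_opens_chromatin=False, seed=11)
gt = make_ground_truth(cfg)
donor, acceptor, _ = simulate_decay_image(gt, cfg)

ph = phasor_transform(donor)
cm = classify_pixels(ph, default_palette(cfg.meta))
frac = compact_fraction(cm, gt.nucleus)

print(f"nucleus pixels:           {int(gt.nucleus.values.sum())}")
print(f"true compact fraction:    {gt.compact_fraction():.3f}")
print(f"recovered compact frac.:  {frac.fraction_compact:.3f} "
      f"({frac.n_compact} compact / {frac.n_open} open pixels)")
# The recovered fraction tracks the ground truth to within a few percent;
# the residual error comes from photon-noise scatter of per-pixel phasors
# across the two adjacent cursor discs.
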