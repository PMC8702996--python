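"""Chromatin compaction inside vs outside DSB repair foci.

Simulates a nucleus in which DNA double-strand-break (DSB) foci locally
open the chromatin, segments the foci from the simulated
immunofluorescence channel (3x3 median filter + Otsu threshold), and
quantifies the compact-chromatin fraction inside vs outside the foci mask.
"""

from chromphasor import (SimulationConfig, analyze_cell, make_ground_truth,
                         simulate_decay_image)

cfg = SimulationConfig(image_size=128, photons_per_pixel=500,
                       compact_area_fraction=0.4, n_compact_foci=80,
                       compact_focus_radius_px=3.0, n_dsb_foci=15,
                       dsb_radius_px=4.0, dsb_opens_chromatin=True, seed=21)
gt = make_ground_truth(cfg)
donor, acceptor, if_img = simulate_decay_image(gt, cfg)

rec = analyze_cell(donor, acceptor=acceptor, if_image=if_img,
                   nucleus=gt.nucleus, cell_id="demo", channel="IF")

print(f"acceptor:donor ratio:      {rec.acceptor_donor_ratio:.2f} (> 1 required)")
print(f"compact fraction (whole):  {rec.fraction_compact:.3f}")
print(f"compact fraction inside:   {rec.fraction_inside:.3f}")
print(f"compact fraction outside:  {rec.fraction_outside:.3f}")
print(f"normalized inside/outside: {rec.normalized_inside:.3f}")
# Because the simulated breaks decompact their surroundings, the fraction
# inside the IF-guided mask falls well below the nucleoplasm value and the
# normalized ratio drops below 1.
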