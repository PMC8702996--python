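"""Size analysis of compact-chromatin foci.

Runs the particle analysis (8-connected labelling with hole filling, area
= pixel count x pixel area) on classification maps from two simulations
that differ only in compact-focus radius, and shows the area histogram
shifting to larger foci.
"""

import numpy as np

from chromphasor import (SimulationConfig, analyze_foci, area_histogram,
                         classify_pixels, default_palette, make_ground_truth,
                         phasor_transform, simulate_decay_image)

tables = {}
for radius in (2.0, 4.0):
    cfg = SimulationConfig(image_size=128, photons_per_pixel=2000,
                           compact_area_fraction=0.06, n_compact_foci=40,
                           compact_focus_radius_px=radius, n_dsb_foci=0,
                           dsb_opens_chromatin=False, seed=5)
    gt = make_ground_truth(cfg)
    donor, _, _ = simulate_decay_image(gt, cfg)
    cm = classify_pixels(phasor_transform(donor), default_palette(cfg.meta))
    tables[radius] = analyze_foci(cm, cfg.meta.pixel_size_um)

edges = np.linspace(0, 0.5, 11)
for radius, table in tables.items():
    areas = table.areas()
    counts, _ = area_histogram([table], bin_edges=edges)
    print(f"focus radius {radius:.0f} px: {len(areas)} particles, "
          f"mean area {areas.mean():.3f} um^2, median {np.median(areas):.3f}")
    print(f"  histogram (0-0.5 um^2, 10 bins): {[int(c) for c in counts]}")
# Doubling the generative focus radius roughly quadruples the mean particle
# area, moving histogram mass into the larger bins.
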