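"""Cohort-level statistics on simulated cells.

Simulates two conditions — an untreated-like cohort and a DSB-induced
cohort with a higher global compact fraction and decompacted break foci —
runs the full per-cell pipeline, and applies the two tests used for such
data: an unpaired t-test between conditions on the whole-nucleus compact
fraction and a paired t-test of inside-focus vs outside-focus fractions.
"""

from chromphasor import SimulationConfig, run_pipeline


def cell(seed, frac, n_dsb):
    return SimulationConfig(image_size=96, photons_per_pixel=500,
                            compact_area_fraction=frac, n_compact_foci=60,
                            compact_focus_radius_px=3.0, n_dsb_foci=n_dsb,
                            dsb_radius_px=3.0, dsb_opens_chromatin=True,
                            seed=seed)


configs = {
    "untreated": [cell(s, 0.30, 0) for s in range(5)],
    "4OHT-2h": [cell(100 + s, 0.45, 12) for s in range(5)],
}
report = run_pipeline(configs, use_ground_truth_masks=True)

for condition, summary in report.summaries.items():
    fc = summary["fraction_compact"]
    print(f"{condition}: compact fraction median {fc['median']:.3f} "
          f"(min {fc['min']:.3f}, max {fc['max']:.3f}, n={fc['n']})")
for name, t in report.tests.items():
    print(f"{name}: t={t.statistic:.2f}, df={t.df:.0f}, p={t.p_value:.2e} "
          f"({t.kind})")
# The unpaired test detects the designed between-condition compaction
# difference; the paired test confirms that chromatin inside the induced
# foci is less compact than the surrounding nucleoplasm.
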