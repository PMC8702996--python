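# chromphasor

Phasor FLIM-FRET analysis of chromatin compaction.

`chromphasor` is for microscopists and image analysts who use **histone
FRET** — Förster resonance energy transfer between fluorescent-protein-tagged
H2B histones on adjacent nucleosomes — as a nanoscale readout of chromatin
compaction, and who want a scriptable, testable implementation of the full
analysis chain: per-pixel phasor transformation of time-resolved photon
counts, reference-dye calibration, FRET-trajectory-based cursor
classification of open vs compact chromatin, quantification of compaction
inside vs outside immunofluorescence-defined DNA double-strand-break (DSB)
foci, and particle-size analysis of compact-chromatin foci. A built-in
synthetic FLIM-nucleus simulator provides ground truth for every stage, so
the whole pipeline is verifiable without microscope data.

## The model

Each pixel's fluorescence decay histogram `C_b` (bins `b` over one laser
period `T`) is reduced to a **phasor**

    g = Σ_b C_b cos(ω t_b) / Σ_b C_b,   s = Σ_b C_b sin(ω t_b) / Σ_b C_b,

with `ω = 2πn/T` (harmonic `n`, here the 80 MHz fundamental) and `t_b` the
bin centre. Single-exponential decays lie on the universal semicircle
`(g − ½)² + s² = ¼`; mixtures combine linearly by intensity fraction.
Calibration against fluorescein at pH 9 (single-exponential, 4.04 ns)
multiplies every pixel's `z = g + is` by `z_theory/z_measured`, removing the
instrument's phase and modulation errors.

A donor quenched by FRET at efficiency `E` keeps a single-exponential decay
with lifetime `τ_D(1 − E)`; sweeping `E`, mixed with an unquenched
autofluorescence background, traces the curved **FRET trajectory** in phasor
space. The unquenched H2B-eGFP donor (τ = 2.5 ns, `(g, s) ≈ (0.39, 0.49)`)
defines the *open* cursor; the compact state at `E = 1 − 2.1/2.5 = 16 %`
(τ = 2.1 ns, `(g, s) ≈ (0.47, 0.50)`) defines the *compact* cursor, each a
disc of radius 0.05. Used in reciprocal mode, the cursors label every image
pixel open / compact / unclassified, giving the per-nucleus compact
fraction; an IF channel (γH2AX, 53BP1 or BRCA1 analog), smoothed with a 3×3
median filter and thresholded, splits that fraction into inside-focus vs
outside-focus components; and compact pixels are grouped into particles
(8-connected, holes filled) whose areas are pixel count × pixel area.

## Worked example

```bash
python examples/04_dsb_foci_analysis.py
```

```
acceptor:donor ratio:      2.00 (> 1 required)
compact fraction (whole):  0.408
compact fraction inside:   0.131
compact fraction outside:  0.435
normalized inside/outside: 0.302
```

The script simulates a 128-pixel nucleus with 40 % compact chromatin in
which 15 DSB foci locally decompact the chromatin, then analyses it
blind: the acceptor:donor check confirms the FRET acceptor is in excess;
the whole-nucleus compact fraction (0.408) recovers the simulated ground
truth (0.402); and the fraction of compact pixels inside the IF-segmented
foci (0.131) is far below the surrounding nucleoplasm (0.435), a
normalized ratio of 0.30 — the decompaction-at-breaks signature the
method is designed to detect.

Other examples cover the cursor palette and FRET trajectory
(`01_phasor_basics.py`), reference calibration (`02_calibration.py`),
compact-fraction recovery (`03_simulated_nucleus.py`), focus-size
histograms (`05_foci_size_histogram.py`) and cohort statistics with
paired/unpaired t-tests (`06_cohort_stats.py`).

A thin CLI mirrors the library: `chromphasor simulate` writes a synthetic
acquisition (decay stack + metadata sidecar, acceptor/IF TIFFs,
ground-truth masks), `chromphasor phasor` transforms and calibrates a
stack, and `chromphasor run` executes the cohort pipeline from a JSON
config, logging all realized thresholds and seeds.

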