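# Methods

## Phasor transform and decay model

The decay histogram in each pixel is reduced to the first-harmonic phasor
`(g, s)` using bin-centre evaluation: bin `b` spans
`[b, b+1)·T/n_bins` and its counts are attributed to the bin centre, which
minimises discretisation bias of the cosine/sine sums. All analytic results
use the **wrapped** (periodic) exponential: at an 80 MHz repetition rate the
12.5 ns period does not let a 2.5 ns decay relax fully, and the excitation
pile-up from previous periods matters. Conveniently, the closed forms
`g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)` are exact for the wrapped continuous
decay, so single-exponential pixels lie on the universal semicircle
regardless of how strongly the decay wraps. At the default 256 bins the
residual discretisation error on `(g, s)` is below 2×10⁻³ (about 3×10⁻⁶ for
the phase; the phase-lifetime round trip of a 4.04 ns stack is accurate to
~3×10⁻⁴ ns).

Pixels with zero photons (or below the classification photon threshold)
carry NaN phasors and an explicit undefined flag rather than `(0, 0)`,
because `(0, 0)` is itself a legal phasor (the infinite-lifetime limit);
silently mapping empty pixels there would create phantom long-lifetime
pixels.

## Calibration

Calibration is a single global complex correction
`z → z · z_theory(ref)/z_measured(ref)` determined from a reference dye of
known single-exponential lifetime (fluorescein at pH 9, 4.04 ns). This
rotates by the instrument phase error and scales by the modulation error,
absorbing the instrument response into the reference measurement, which is
standard phasor practice; no per-pixel IRF deconvolution is attempted. The
correction is exactly inverse-consistent: corrupting a dataset by a known
rotation and modulation loss and calibrating against the equally corrupted
reference restores the data to numerical precision.

## FRET trajectory and cursor palette

The quenched donor is modelled as a single exponential with lifetime
`τ_D(1−E)` (the classical lifetime definition of FRET efficiency). With an
unquenched background species at intensity fraction `f_b` (measured at
E = 0), the donor's intensity fraction shrinks with quenching:

    f_D(E) = (1−f_b)(1−E) / ((1−f_b)(1−E) + f_b),

and the trajectory point is the intensity-weighted mixture
`f_D·P_quenched(E) + (1−f_D)·P_background`. With `f_b = 0` the trajectory
runs along the universal circle from the donor phasor to `(1, 0)`; with
background it bows toward the background phasor. The trajectory is sampled
at 101 uniform E values (1 % resolution, far below the cursor radius).

The default palette places the *open* cursor at the unquenched 2.5 ns donor
(`(0.39, 0.49)` to two decimals) and the *compact* cursor at the
16 %-efficiency trajectory point with zero background, i.e. the 2.1 ns
phasor (`(0.47, 0.50)`). Cursors are circular discs of radius 0.05 — the
uncertainty conventionally quoted for these cursor coordinates. The default palette
background fraction is 0: the canonical centres are reproduced exactly with
no background, and the measured autofluorescence fraction of a given
instrument can be passed explicitly by users who have it. Classification
uses the nearer centre when a phasor falls inside both discs, with ties (to
numerical precision) assigned to compact — deterministic and documented;
the default photon threshold of 30 photons/pixel marks dimmer pixels
unclassified, since below that the phasor standard error exceeds the disc
radius. Unclassified pixels are excluded from both numerator and
denominator of the compact fraction, which is therefore a fraction over the
two cursors only.

## Foci segmentation and particle analysis

IF images are smoothed with a 3×3 spatial median filter (edge replication
at borders keeps the output shape; the filter is idempotent on binary steps
away from borders) and binarised with an inclusive `value ≥ threshold`
comparison; the threshold is either a user value or Otsu's
between-class-variance maximiser on the smoothed image. The realized
threshold is always recorded in the mask provenance, since "sufficiently
harsh" IF thresholds are operator choices. No minimum focus size is imposed
by default. Inside/outside quantification partitions the nucleus mask
exactly into `nucleus ∧ foci` and `nucleus ∧ ¬foci` and computes the
compact fraction in each; the normalized inside fraction divides the two.

Particle analysis of the compact-pixel binary uses 8-connected foreground
with 4-connected background for hole detection — the Jordan-consistent
pairing, matching common particle-analysis behaviour — so background
regions fully enclosed by a particle count toward its area. Particles of
any size are kept, including those touching the image border. Area is
pixel count × pixel area (0.0081 µm² at 90 nm/pixel). Histogram binning
defaults to 20 uniform bins from 0 to the 99th percentile of pooled areas.

## Synthetic data generator

The simulator emulates the acquisition geometry the analysis targets:
256×256 frames at 90 nm/pixel, 80 MHz excitation, 256 time bins; a centred
elliptical nucleus covering ~70 % of the frame; compact chromatin as random
disks accreted until the requested area fraction (default 0.3) is reached;
~100 DSB foci (default radius 5 px ≈ 0.45 µm) which, when
`dsb_opens_chromatin` is set, locally reassign compact pixels to open —
the decompaction-at-breaks phenomenology the mask analysis measures.
Defaults: donor 2.5 ns, compact efficiency 0.16, 200 photons/pixel (a
plausible confocal TCSPC budget for ~20 µs dwell with frame integration),
zero autofluorescence fraction (consistent with the palette), acceptor
2× donor, IF spots as Gaussians of σ = half the focus radius at 10× the
Poisson background.

Photon statistics are exact: per-pixel counts are Poisson; conditional on
the count, bins are multinomial over bin-integrated wrapped-exponential
probabilities, equivalent to binning individual arrival times
`(−τ ln U) mod T`. One global seed feeds a splittable generator
(`numpy.random.SeedSequence.spawn`), so ground-truth layout and the three
noise channels are independently reproducible. Reference-dye stacks can be
corrupted by whole-bin circular delays (exact phasor rotations) and uniform
count admixture (exact modulation scaling) to exercise calibration.

What the simulator does **not** emulate: instrument response width,
detector afterpulsing, photobleaching, chromatin texture beyond disk foci,
3-D structure, or spatially varying autofluorescence. Tests passing on
synthetic data therefore validate the computational chain and its
statistical behaviour under Poisson noise, not robustness to those
instrument- and sample-specific effects.

## Statistics

Between-condition comparisons use the two-sided two-sample Student's t-test
with pooled variance (Welch's variant available by flag); within-cell
inside-vs-outside comparisons use the two-sided paired t-test. Both are
computed with `scipy.stats` and cross-checked in the test suite against
textbook formulas. No multiple-testing correction is applied, and cohort
summaries report min / max / median (box-and-whisker convention), with
quartiles labelled as extensions.

## Numerical choices and problem sizes

- Noiseless "ideal" stacks are expected-value histograms scaled to ≥10⁹
  photons and rounded, keeping rounding error ≤10⁻⁹ of the phasor.
- Classification at 100–500 photons/pixel carries phasor scatter
  (σ_g ≈ 0.065 at 100 photons) comparable to the 0.085 cursor separation;
  recovery of the compact fraction is accurate to a few percentage points
  in balanced mixtures, where spill between the adjacent discs largely
  cancels, and degrades toward extreme fractions. Particle-size analyses
  are run at ~2000 photons/pixel, where spurious single-pixel
  misclassifications are rare.
- Tests and examples use 64–128 px nuclei for speed and 256 px for the
  end-to-end recovery checks; cohort demonstrations use n = 4–6 cells per
  condition, which suffices for the designed effect sizes.
- The compact-area accretion loop stops at the first overshoot of the
  target fraction (realized fraction within one disk area of the request)
  and raises a configuration error if the target is unreachable within the
  attempt budget.

## Known limitations

- The two-cursor palette reports a binary compaction state; no continuous
  per-pixel efficiency map is produced.
- No phasor-space smoothing is applied before cursor mapping; at low photon
  counts users should raise the photon threshold or photon budget rather
  than expect spatial filtering to rescue classification.
- The unpaired test's equal-variance assumption is a convention choice,
  recorded in the report notes.
- Vendor FLIM container formats (.fbd, .sdt, .ptu) are out of scope; decay
  stacks travel as multi-page TIFF plus a JSON metadata sidecar.
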