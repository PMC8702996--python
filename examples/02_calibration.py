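"""Reference-dye calibration of a FLIM acquisition.

Simulates a fluorescein reference stack (known 4.04 ns single-exponential
lifetime) corrupted by an instrument phase delay and a modulation loss,
then shows that calibrating against the corrupted reference removes both
errors: the recovered phase and modulation lifetimes return to 4.04 ns.
"""

from chromphasor import (AcquisitionMeta, CalibrationReference, calibrate,
                         lifetime_from_phasor, phasor_transform,
                         simulate_reference)

meta = AcquisitionMeta()

# instrument corruption: 12-bin delay (a phasor rotation) plus 15 % of the
# signal replaced by uniform counts (a modulation scaling)
corrupted = simulate_reference(4.04, meta, shift_bins=12,
                               uniform_admixture=0.15)
measured = phasor_transform(corrupted).mean_phasor()
tau_p, tau_m = lifetime_from_phasor(measured, meta)
print(f"uncalibrated reference: g={measured.g:.3f} s={measured.s:.3f} "
      f"tau_phase={tau_p:.2f} ns tau_mod={tau_m:.2f} ns")

reference = CalibrationReference(measured=measured, known_lifetime_ns=4.04,
                                 meta=meta)
calibrated = calibrate(phasor_transform(corrupted), reference)
p = calibrated.mean_phasor()
tau_p, tau_m = lifetime_from_phasor(p, meta)
print(f"calibrated reference:   g={p.g:.3f} s={p.s:.3f} "
      f"tau_phase={tau_p:.2f} ns tau_mod={tau_m:.2f} ns")
# Both lifetimes read 4.04 ns after calibration: the complex correction
# factor measured on the dye absorbs the instrument response.
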