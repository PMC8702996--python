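import numpy as np
import pytest

from chromphasor import AcquisitionMeta, DecayImage
from chromphasor.simulate import ideal_decay_counts


@pytest.fixture
def meta() -> AcquisitionMeta:
    """Default acquisition: 80 MHz, 256 bins, 90 nm/pixel, first harmonic."""
    return AcquisitionMeta()


@pytest.fixture
def noiseless_stack_factory(meta):
    """Build a noiseless single-exponential decay stack of a given shape."""

    def _make(tau_ns: float, shape=(4, 4), total=1e9, m=None) -> DecayImage:
        m = m or meta
        page = ideal_decay_counts(tau_ns, m, total_photons=total)
        counts = np.broadcast_to(page, shape + (m.n_bins,)).copy()
        return DecayImage(counts=counts, meta=m)

    return _make
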