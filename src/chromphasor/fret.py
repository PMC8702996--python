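"""FRET efficiency, the background-corrected FRET trajectory, and cursors.

A donor quenched by FRET with efficiency ``E`` keeps a single-exponential
decay with lifetime ``tau_D * (1 - E)``.  In the presence of an unquenched
background species (cellular autofluorescence) at intensity fraction
``f_b`` (measured at E = 0), the observed phasor at efficiency E is the
intensity-weighted mixture of the quenched-donor phasor and the background
phasor.  Because quenching also dims the donor, the donor's intensity
fraction shrinks with E:

    f_D(E) = (1 - f_b) (1 - E) / ((1 - f_b) (1 - E) + f_b)

Sweeping E over [0, 1] traces the curved FRET trajectory in phasor space;
with no background the trajectory runs along the universal circle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .io import AcquisitionMeta
from .phasor import PhasorPoint, mixture_phasor, single_exponential_phasor

import numpy as np

#: FRET efficiency of the compact-chromatin state (donor 2.5 -> 2.1 ns).
COMPACT_FRET_E = 0.16
#: Unquenched donor (H2B-eGFP) lifetime, ns.
DONOR_TAU_NS = 2.5
#: Default cursor radius in phasor units.
CURSOR_RADIUS = 0.05


def fret_efficiency(tau_d_ns: float, tau_da_ns: float) -> float:
    """FRET efficiency from unquenched and quenched donor lifetimes.

    ``E = 1 - tau_DA / tau_D``.  Negative efficiencies (tau_DA > tau_D)
    are not modelled.
    """
    if tau_d_ns <= 0 or tau_da_ns <= 0:
        raise ValueError("lifetimes must be positive")
    if tau_da_ns > tau_d_ns:
        raise ValueError("quenched lifetime exceeds unquenched lifetime")
    return 1.0 - tau_da_ns / tau_d_ns


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters defining a FRET trajectory.

    ``background`` and ``background_fraction`` describe the unquenched
    autofluorescence species; ``background_fraction`` is the intensity
    fraction it contributes at E = 0.
    """

    donor_lifetime_ns: float = DONOR_TAU_NS
    background: PhasorPoint = field(default_factory=lambda: PhasorPoint(0.0, 0.0))
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.donor_lifetime_ns <= 0:
            raise ValueError("donor_lifetime_ns must be positive")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must lie in [0, 1)")


@dataclass
class FretTrajectory:
    """A sampled FRET trajectory: ordered (E, phasor) pairs for E in [0, 1]."""

    params: TrajectoryParams
    samples: list[tuple[float, PhasorPoint]]

    def nearest_efficiency(self, p: PhasorPoint) -> float:
        """E of the trajectory sample closest to ``p`` in phasor space."""
        d = [(p.g - q.g) ** 2 + (p.s - q.s) ** 2 for _, q in self.samples]
        return self.samples[int(np.argmin(d))][0]


@dataclass(frozen=True)
class Cursor:
    """A circular disc in phasor space used to classify image pixels."""

    center: PhasorPoint
    radius: float
    label: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cursor radius must be positive")

    def contains(self, g, s):
        return (g - self.center.g) ** 2 + (s - self.center.s) ** 2 <= self.radius ** 2


def trajectory_point(E: float, params: TrajectoryParams,
                     meta: AcquisitionMeta) -> PhasorPoint:
    """Phasor at FRET efficiency E on the trajectory defined by ``params``."""
    if not (0.0 <= E <= 1.0):
        raise ValueError("E must lie in [0, 1]")
    f_b = params.background_fraction
    if E == 1.0:
        # donor fully quenched: it emits nothing
        return params.background if f_b > 0 else PhasorPoint(1.0, 0.0)
    quenched = single_exponential_phasor(params.donor_lifetime_ns * (1.0 - E), meta)
    donor_weight = (1.0 - f_b) * (1.0 - E)
    f_d = donor_weight / (donor_weight + f_b)
    return mixture_phasor([(quenched, f_d), (params.background, 1.0 - f_d)])


def build_trajectory(params: TrajectoryParams, meta: AcquisitionMeta,
                     n_samples: int = 101) -> FretTrajectory:
    """Sample the FRET trajectory at a uniform E grid over [0, 1]."""
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    Es = np.linspace(0.0, 1.0, n_samples)
    return FretTrajectory(
        params=params,
        samples=[(float(E), trajectory_point(float(E), params, meta)) for E in Es])


def default_palette(meta: AcquisitionMeta,
                    radius: float = CURSOR_RADIUS) -> tuple[Cursor, Cursor]:
    """The two-cursor open/compact palette.

    The open cursor sits at the unquenched 2.5 ns donor phasor
    (g, s) = (0.39, 0.49); the compact cursor at the 16 %-efficiency point of
    the zero-background trajectory, i.e. the 2.1 ns phasor (0.47, 0.50).
    Radius 0.05 in phasor units by default.
    """
    open_cursor = Cursor(single_exponential_phasor(DONOR_TAU_NS, meta),
                         radius, "open")
    compact_center = trajectory_point(COMPACT_FRET_E, TrajectoryParams(), meta)
    compact_cursor = Cursor(compact_center, radius, "compact")
    return open_cursor, compact_cursor


def palette_to_json(palette: tuple[Cursor, Cursor], path: str | Path,
                    provenance: dict | None = None) -> None:
    """Serialise a cursor palette with its lifetime/efficiency provenance."""
    prov = provenance or {
        "donor_lifetime_ns": DONOR_TAU_NS,
        "compact_fret_efficiency": COMPACT_FRET_E,
        "background_fraction": 0.0,
    }
    Path(path).write_text(json.dumps({
        "cursors": [
            {"label": c.label, "g": c.center.g, "s": c.center.s,
             "radius": c.radius}
            for c in palette
        ],
        "provenance": prov,
    }, indent=1))


def palette_from_json(path: str | Path) -> tuple[Cursor, Cursor]:
    d = json.loads(Path(path).read_text())
    cursors = {c["label"]: Cursor(PhasorPoint(c["g"], c["s"]),
                                  c["radius"], c["label"])
               for c in d["cursors"]}
    return cursors["open"], cursors["compact"]
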