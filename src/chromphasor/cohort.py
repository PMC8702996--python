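"""Cross-cell aggregation, paired/unpaired t-tests and the full pipeline.

``analyze_cell`` runs one nucleus through calibration, classification,
inside/outside mask analysis and particle analysis; ``run_pipeline`` maps
it over a cohort (simulated or file-based), aggregates per-condition
summaries (min / max / median, with quartiles as extensions) and applies
the two statistical comparisons used for this kind of data: an unpaired
Student's t-test between conditions and a paired t-test of inside-focus vs
outside-focus fractions within cells.  No multiple-testing correction is
applied (single pairwise tests); this is noted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import masks as _masks
from .classify import (DEFAULT_PHOTON_THRESHOLD, ClassificationMap,
                       acceptor_excess_check, classify_pixels,
                       compact_fraction)
from .fret import Cursor, default_palette
from .io import AcquisitionMeta, BinaryMask, DecayImage, IntensityImage
from .particles import FociTable, analyze_foci
from .phasor import CalibrationReference, PhasorImage, calibrate, phasor_transform
from .simulate import GroundTruth, SimulationConfig, make_ground_truth, simulate_decay_image


@dataclass
class TestResult:
    """Outcome of a t-test."""

    statistic: float
    df: float
    p_value: float
    kind: str  # "paired" | "unpaired"
    two_sided: bool = True


@dataclass
class CellRecord:
    """Per-cell quantification of chromatin compaction."""

    cell_id: str
    condition: str
    fraction_compact: float
    fraction_inside: float | None = None
    fraction_outside: float | None = None
    normalized_inside: float | None = None
    channel: str = ""
    acceptor_donor_ratio: float | None = None
    foci_table: FociTable | None = None

    def to_row(self) -> dict:
        return {
            "cell_id": self.cell_id, "condition": self.condition,
            "channel": self.channel,
            "fraction_compact": self.fraction_compact,
            "fraction_inside": self.fraction_inside,
            "fraction_outside": self.fraction_outside,
            "normalized_inside": self.normalized_inside,
            "acceptor_donor_ratio": self.acceptor_donor_ratio,
        }


def unpaired_t(group_a: list[float], group_b: list[float],
               equal_var: bool = True) -> TestResult:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    Welch's correction is available via ``equal_var=False``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if equal_var and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      p_value=float(res.pvalue), kind="unpaired")


def paired_t(x: list[float], y: list[float]) -> TestResult:
    """Two-sided paired t-test (one-sample t on differences, df = n - 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    if np.var(x - y, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      p_value=float(res.pvalue), kind="paired")


def summarize(values: list[float]) -> dict:
    """Box-and-whisker style summary: min, max, median (+ quartiles)."""
    v = np.asarray([x for x in values if x is not None and not np.isnan(x)])
    if v.size == 0:
        return {"n": 0}
    return {"n": int(v.size), "min": float(v.min()), "max": float(v.max()),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "mean": float(v.mean())}


def analyze_cell(donor_stack: DecayImage,
                 acceptor: IntensityImage | None = None,
                 if_image: IntensityImage | None = None,
                 reference: CalibrationReference | None = None,
                 palette: tuple[Cursor, Cursor] | None = None,
                 nucleus: BinaryMask | None = None,
                 foci: BinaryMask | None = None,
                 photon_threshold: float = DEFAULT_PHOTON_THRESHOLD,
                 foci_threshold: float | str = "otsu",
                 nucleus_threshold: float | str = "otsu",
                 cell_id: str = "cell", condition: str = "",
                 channel: str = "") -> CellRecord:
    """Quantify one nucleus: phasor, classify, fractions, foci particles.

    ``nucleus`` and ``foci`` masks may be supplied directly (e.g. ground
    truth); otherwise they are segmented from the donor photon image and
    the IF image respectively.
    """
    ph = phasor_transform(donor_stack)
    if reference is not None:
        ph = calibrate(ph, reference)
    palette = palette or default_palette(donor_stack.meta)

    pixel_size = donor_stack.meta.pixel_size_um
    donor_int = IntensityImage(donor_stack.photon_sum().astype(float),
                               channel_label="donor", pixel_size_um=pixel_size)
    if nucleus is None:
        nucleus = _masks.nucleus_mask(donor_int, nucleus_threshold)

    cm = classify_pixels(ph, palette, photon_threshold)
    frac = compact_fraction(cm, nucleus)

    record = CellRecord(cell_id=cell_id, condition=condition, channel=channel,
                        fraction_compact=frac.fraction_compact)

    if acceptor is not None:
        ratio, _ = acceptor_excess_check(donor_int, acceptor, nucleus)
        record.acceptor_donor_ratio = ratio

    if foci is None and if_image is not None:
        foci = _masks.foci_mask(if_image, foci_threshold)
    if foci is not None:
        res = _masks.inside_outside(cm, foci, nucleus)
        record.fraction_inside = res.fraction_inside
        record.fraction_outside = res.fraction_outside
        record.normalized_inside = _masks.normalized_inside_fraction(res)

    record.foci_table = analyze_foci(cm, pixel_size, source=cell_id)
    return record


@dataclass
class CohortReport:
    """Aggregated pipeline output across cells."""

    cells: list[CellRecord]
    failures: dict[str, str]
    summaries: dict[str, dict]
    tests: dict[str, TestResult]
    notes: list[str] = field(default_factory=list)


def run_pipeline(configs: dict[str, list[SimulationConfig]],
                 use_ground_truth_masks: bool = False) -> CohortReport:
    """Run the full pipeline on a simulated cohort.

    ``configs`` maps condition name -> list of per-cell simulation configs.
    Per-cell failures are quarantined and reported rather than aborting the
    cohort.  Between-condition compact fractions are compared with the
    unpaired test; within-cell inside vs outside fractions with the paired
    test.
    """
    if not configs or all(len(v) == 0 for v in configs.values()):
        raise ValueError("empty cohort")
    cells: list[CellRecord] = []
    failures: dict[str, str] = {}
    for condition, cfgs in configs.items():
        for i, cfg in enumerate(cfgs):
            cid = f"{condition}-{i:03d}"
            try:
                gt = make_ground_truth(cfg)
                donor, acceptor, if_img = simulate_decay_image(gt, cfg)
                kwargs = {}
                if use_ground_truth_masks:
                    kwargs = {"nucleus": gt.nucleus, "foci": gt.dsb_map}
                cells.append(analyze_cell(
                    donor, acceptor=acceptor, if_image=if_img,
                    cell_id=cid, condition=condition, channel="IF",
                    **kwargs))
            except Exception as exc:  # noqa: BLE001 — isolated so one bad cell cannot abort the cohort
                failures[cid] = f"{type(exc).__name__}: {exc}"

    summaries = {}
    by_condition: dict[str, list[CellRecord]] = {}
    for rec in cells:
        by_condition.setdefault(rec.condition, []).append(rec)
    for condition, recs in by_condition.items():
        summaries[condition] = {
            "fraction_compact": summarize([r.fraction_compact for r in recs]),
            "fraction_inside": summarize([r.fraction_inside for r in recs
                                          if r.fraction_inside is not None]),
            "fraction_outside": summarize([r.fraction_outside for r in recs
                                           if r.fraction_outside is not None]),
            "normalized_inside": summarize([r.normalized_inside for r in recs
                                            if r.normalized_inside is not None]),
        }

    tests: dict[str, TestResult] = {}
    conditions = list(by_condition)
    if len(conditions) == 2:
        a = [r.fraction_compact for r in by_condition[conditions[0]]]
        b = [r.fraction_compact for r in by_condition[conditions[1]]]
        if len(a) >= 2 and len(b) >= 2:
            try:
                tests["fraction_compact_between_conditions"] = unpaired_t(a, b)
            except ValueError:
                pass
    for condition, recs in by_condition.items():
        pairs = [(r.fraction_inside, r.fraction_outside) for r in recs
                 if r.fraction_inside is not None
                 and r.fraction_outside is not None
                 and not (np.isnan(r.fraction_inside)
                          or np.isnan(r.fraction_outside))]
        if len(pairs) >= 2:
            try:
                tests[f"inside_vs_outside[{condition}]"] = paired_t(
                    [p[0] for p in pairs], [p[1] for p in pairs])
            except ValueError:
                pass

    return CohortReport(
        cells=cells, failures=failures, summaries=summaries, tests=tests,
        notes=["unpaired test: Student's (equal variance), two-sided",
               "no multiple-testing correction applied",
               "box summaries report min/max/median; quartiles are extensions"])
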