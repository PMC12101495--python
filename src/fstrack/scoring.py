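"""Scoring against ground truth and parameter-grid tuning.

Presence calls are scored as a confusion matrix over every
(sample, fecal category) pair; apportionment is scored as the Pearson
correlation between predicted portions and the portions implied by the
true cell fractions; predicted cell fractions can additionally be
regressed against the true ones (a diagnostic linear calibration,
never applied automatically).  ``run_grid`` sweeps the post-alignment
parameter grid — minimum identity, minimum overlap, genome masking and
limit of detection — re-using the parsed alignments, and ranks
parameter sets by negative predictive value (ties broken by higher
sensitivity, then higher specificity, then the parameter tuple).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .alignments import FilterThresholds, ReadAlignment, filter_alignments
from .attribution import SampleReport, report
from .depth import compute_depth
from .genome_db import SourceDatabase
from .geq import DetectionRule, cell_fractions, estimate_geq


# ---------------------------------------------------------------- truth

@dataclass
class GroundTruthTable:
    """True per-(sample, category) cell fractions from mixture design."""

    fractions: dict[tuple[str, str], float] = field(default_factory=dict)

    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.fractions})

    def categories(self) -> list[str]:
        return sorted({c for _, c in self.fractions})

    def true_fraction(self, sample: str, category: str) -> float:
        return self.fractions.get((sample, category), 0.0)

    def true_present(self, sample: str, category: str) -> bool:
        return self.true_fraction(sample, category) > 0.0

    def true_portions(self, sample: str) -> dict[str, float]:
        """Portions implied by the true fractions (spiked sources only)."""
        fracs = {
            c: f for (s, c), f in self.fractions.items() if s == sample and f > 0
        }
        total = sum(fracs.values())
        return {c: f / total for c, f in fracs.items()} if total > 0 else {}

    @classmethod
    def from_tsv(cls, path) -> "GroundTruthTable":
        table = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("sample\tcategory"):
                    continue
                sample, cat, frac = line.split("\t")
                table.fractions[(sample, cat)] = float(frac)
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tcategory\ttrue_cell_fraction\n")
            for (s, c), f in sorted(self.fractions.items()):
                fh.write(f"{s}\t{c}\t{f:.8g}\n")


# ------------------------------------------------------------- scoring

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


@dataclass(frozen=True)
class AttributionScore:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None


def score_attribution(
    reports: Sequence[SampleReport],
    truth: GroundTruthTable,
    fecal_categories: Sequence[str],
) -> AttributionScore:
    """Confusion counts and rates over (sample x fecal category).

    Rates with a zero denominator are reported as None (missing), not
    as zero.  A scored sample absent from the truth table's sample set
    is a hard error.
    """
    truth_samples = set(truth.samples())
    tp = fp = fn = tn = 0
    for rep in reports:
        if rep.sample_id not in truth_samples:
            raise KeyError(f"sample {rep.sample_id!r} missing from ground truth")
        for cat in fecal_categories:
            predicted = rep.call(cat).present
            actual = truth.true_present(rep.sample_id, cat)
            if predicted and actual:
                tp += 1
            elif predicted and not actual:
                fp += 1
            elif not predicted and actual:
                fn += 1
            else:
                tn += 1
    counts = ConfusionCounts(tp, fp, fn, tn)
    return AttributionScore(
        counts=counts,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
        ppv=_ratio(tp, tp + fp),
    )


def score_apportionment(
    reports: Sequence[SampleReport],
    truth: GroundTruthTable,
    fecal_categories: Sequence[str],
) -> float | None:
    """Pearson r between predicted and true source portions.

    Pairs run over every (sample, fecal category); a category with no
    predicted portion contributes zero.  Returns None when either
    vector is constant or fewer than 3 pairs exist.
    """
    predicted, actual = [], []
    for rep in reports:
        true_portions = truth.true_portions(rep.sample_id)
        for cat in fecal_categories:
            predicted.append(rep.portions.get(cat, 0.0))
            actual.append(true_portions.get(cat, 0.0))
    if len(predicted) < 3:
        raise ValueError("need at least 3 (sample, category) pairs")
    p = np.asarray(predicted)
    a = np.asarray(actual)
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        return None
    return float(stats.pearsonr(p, a).statistic)


@dataclass(frozen=True)
class Calibration:
    slope: float
    intercept: float
    r_squared: float


def calibrate_cell_fractions(
    predicted: Sequence[float], true: Sequence[float]
) -> Calibration:
    """Ordinary least squares of true on predicted cell fractions.

    Purely diagnostic: the paper-style calibration slope quantifies
    systematic under- or over-estimation and is never applied to the
    reported fractions.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(p) == 0:
        raise ValueError("degenerate calibration: constant predictor")
    res = stats.linregress(p, t)
    return Calibration(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


# -------------------------------------------------------------- tuning

@dataclass(frozen=True)
class ParameterGrid:
    """Post-alignment parameter sweep; the default grid brackets the
    tuned optimum (93, 70, 0, 0.01) with 8 x 4 x 4 x 5 = 640 sets."""

    identities: tuple[float, ...] = (85, 87, 89, 91, 93, 95, 97, 99)
    overlaps: tuple[float, ...] = (30, 50, 70, 90)
    maskings: tuple[float, ...] = (0, 25, 50, 75)
    lods: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001, 0.00001)

    def __post_init__(self) -> None:
        if not (self.identities and self.overlaps and self.maskings and self.lods):
            raise ValueError("every grid axis needs at least one value")

    @property
    def size(self) -> int:
        return (
            len(self.identities) * len(self.overlaps) * len(self.maskings) * len(self.lods)
        )

    def combinations(self) -> Iterable[tuple[float, float, float, float]]:
        return itertools.product(self.identities, self.overlaps, self.maskings, self.lods)


@dataclass
class TuningSample:
    """One sample's parsed alignments plus what GEQ estimation needs."""

    sample_id: str
    alignments: list[ReadAlignment]
    total_bp: int
    total_reads: int
    ags_bp: float


@dataclass(frozen=True)
class TuningResult:
    min_identity: float
    min_overlap: float
    masking_percent: float
    lod_percent: float
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    npv: float | None
    apportionment_r: float | None
    calibration: Calibration | None


def evaluate_parameter_set(
    samples: Sequence[TuningSample],
    db: SourceDatabase,
    min_identity: float,
    min_overlap: float,
    masking_percent: float,
    lod_percent: float,
    truth: GroundTruthTable,
    detection_rule: DetectionRule = DetectionRule(),
) -> TuningResult:
    """Score one parameter combination from scratch (no caching)."""
    reports = []
    for s in samples:
        filtered = list(
            filter_alignments(s.alignments, FilterThresholds(min_identity, min_overlap))
        )
        depths = compute_depth(
            filtered,
            db.genome_lengths(),
            masking_percent=masking_percent,
            sample_id=s.sample_id,
            total_reads=s.total_reads,
            total_bp=s.total_bp,
        )
        geq = estimate_geq(s.total_bp, ags_bp=s.ags_bp, sample_id=s.sample_id)
        fracs = cell_fractions(depths, db, geq, detection_rule)
        reports.append(report(fracs, lod_percent))
    return _score_reports(
        reports, truth, db, min_identity, min_overlap, masking_percent, lod_percent
    )


def _score_reports(
    reports, truth, db, min_identity, min_overlap, masking_percent, lod_percent
) -> TuningResult:
    fecal = db.fecal_categories()
    att = score_attribution(reports, truth, fecal)
    try:
        r = score_apportionment(reports, truth, fecal)
    except ValueError:  # fewer than 3 (sample, category) pairs
        r = None
    predicted, actual = [], []
    for rep in reports:
        for cat in fecal:
            predicted.append(rep.cell_fractions.fractions[cat].cell_fraction)
            actual.append(truth.true_fraction(rep.sample_id, cat))
    try:
        calib = calibrate_cell_fractions(predicted, actual)
    except ValueError:
        calib = None
    return TuningResult(
        min_identity,
        min_overlap,
        masking_percent,
        lod_percent,
        att.counts,
        att.sensitivity,
        att.specificity,
        att.npv,
        r,
        calib,
    )


def _rank_key(res: TuningResult):
    def missing_last(v):
        return v if v is not None else -np.inf

    return (
        -missing_last(res.npv),
        -missing_last(res.sensitivity),
        -missing_last(res.specificity),
        res.min_identity,
        res.min_overlap,
        res.masking_percent,
        res.lod_percent,
    )


def run_grid(
    samples: Sequence[TuningSample],
    db: SourceDatabase,
    grid: ParameterGrid,
    truth: GroundTruthTable,
    detection_rule: DetectionRule = DetectionRule(),
) -> list[TuningResult]:
    """Sweep the grid and rank by NPV (ties: sensitivity, specificity).

    Alignment filtering is performed once per (identity, overlap) pair
    and depth once per masking value; only attribution is recomputed
    per LOD.  The ranking is a total deterministic order.
    """
    genome_lengths = db.genome_lengths()
    results: list[TuningResult] = []
    for ident, overlap in itertools.product(grid.identities, grid.overlaps):
        thresholds = FilterThresholds(ident, overlap)
        filtered_per_sample = [
            list(filter_alignments(s.alignments, thresholds)) for s in samples
        ]
        for masking in grid.maskings:
            fracs_per_sample = []
            for s, filtered in zip(samples, filtered_per_sample):
                depths = compute_depth(
                    filtered,
                    genome_lengths,
                    masking_percent=masking,
                    sample_id=s.sample_id,
                    total_reads=s.total_reads,
                    total_bp=s.total_bp,
                )
                geq = estimate_geq(s.total_bp, ags_bp=s.ags_bp, sample_id=s.sample_id)
                fracs_per_sample.append(cell_fractions(depths, db, geq, detection_rule))
            for lod in grid.lods:
                reports = [report(f, lod) for f in fracs_per_sample]
                results.append(
                    _score_reports(reports, truth, db, ident, overlap, masking, lod)
                )
    results.sort(key=_rank_key)
    return results


def tuning_results_to_tsv(results: Sequence[TuningResult], path) -> None:
    def fmt(v):
        return f"{v:.6g}" if v is not None else "NA"

    with open(path, "w") as fh:
        fh.write(
            "min_identity\tmin_overlap\tmasking\tlod\ttp\tfp\tfn\ttn\t"
            "sensitivity\tspecificity\tnpv\tapportionment_r\tslope\tintercept\tr2\n"
        )
        for r in results:
            calib = r.calibration
            fh.write(
                f"{r.min_identity:g}\t{r.min_overlap:g}\t{r.masking_percent:g}\t"
                f"{r.lod_percent:g}\t{r.counts.tp}\t{r.counts.fp}\t{r.counts.fn}\t"
                f"{r.counts.tn}\t{fmt(r.sensitivity)}\t{fmt(r.specificity)}\t"
                f"{fmt(r.npv)}\t{fmt(r.apportionment_r)}\t"
                f"{fmt(calib.slope if calib else None)}\t"
                f"{fmt(calib.intercept if calib else None)}\t"
                f"{fmt(calib.r_squared if calib else None)}\n"
            )
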