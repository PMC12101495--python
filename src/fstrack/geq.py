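"""Genome-equivalents (GEQ) normalization and cell-fraction estimation.

A metagenome's GEQ is its total genome copies: total sequenced bases
divided by the average genome size (AGS).  Dividing a genome's mean
sequencing depth by the GEQ yields the fraction of all cells in the
sample belonging to that genome, so summing over a source category's
genomes gives the category's cell fraction:

    cell_fraction_j = sum_i ( X_i / GEQ )

with X_i the depth of genome i of category j.  The AGS can be supplied
directly, or estimated from coverage of universal single-copy marker
sequences: each marker occurs exactly once per genome, so the summed
read bases aligned to a marker divided by its length estimates the
total genome copies; the GEQ is the median of these per-marker
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .alignments import ReadAlignment
from .depth import DepthTable
from .genome_db import SourceDatabase


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    marker_len_bp: int
    aligned_bp: int


@dataclass
class MarkerHitTable:
    hits: list[MarkerHit] = field(default_factory=list)


@dataclass(frozen=True)
class GeqEstimate:
    sample_id: str
    geq: float
    ags_bp: float
    method: str  # "supplied_ags" | "marker_coverage"


@dataclass(frozen=True)
class DetectionRule:
    """A genome is detected iff it gathered at least ``min_reads``
    filtered reads and its breadth is at least ``min_breadth``."""

    min_reads: int = 1
    min_breadth: float = 0.0


@dataclass(frozen=True)
class CategoryFractions:
    category: str
    cell_fraction: float
    specific_fraction: float
    cross_reactive_fraction: float
    n_genomes_detected: int
    n_specific_detected: int
    is_screen: bool = False


@dataclass
class CellFractionTable:
    sample_id: str
    fractions: dict[str, CategoryFractions] = field(default_factory=dict)
    geq: float = 0.0
    ags_bp: float = 0.0

    def cell_fraction(self, category: str) -> float:
        return self.fractions[category].cell_fraction

    def rescaled(self, factor: float) -> "CellFractionTable":
        """Uniformly rescale every fraction (GEQ error model)."""
        out = CellFractionTable(self.sample_id, geq=self.geq / factor, ags_bp=self.ags_bp)
        for cat, f in self.fractions.items():
            out.fractions[cat] = CategoryFractions(
                cat,
                f.cell_fraction * factor,
                f.specific_fraction * factor,
                f.cross_reactive_fraction * factor,
                f.n_genomes_detected,
                f.n_specific_detected,
                f.is_screen,
            )
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "sample\tcategory\tcell_fraction\tspecific_fraction\t"
                "cross_reactive_fraction\tn_genomes_detected\tn_specific_detected\tgeq\tags_bp\n"
            )
            for f in self.fractions.values():
                fh.write(
                    f"{self.sample_id}\t{f.category}\t{f.cell_fraction:.8g}\t"
                    f"{f.specific_fraction:.8g}\t{f.cross_reactive_fraction:.8g}\t"
                    f"{f.n_genomes_detected}\t{f.n_specific_detected}\t"
                    f"{self.geq:.6g}\t{self.ags_bp:.6g}\n"
                )


def estimate_geq(
    total_bp: int,
    *,
    ags_bp: float | None = None,
    marker_hits: MarkerHitTable | None = None,
    sample_id: str = "sample",
) -> GeqEstimate:
    """Estimate genome equivalents from a supplied AGS or marker hits.

    Exactly one of ``ags_bp`` and ``marker_hits`` must be given.
    """
    if (ags_bp is None) == (marker_hits is None):
        raise ValueError("provide exactly one of ags_bp and marker_hits")
    if ags_bp is not None:
        if ags_bp <= 0:
            raise ValueError("ags_bp must be positive")
        return GeqEstimate(sample_id, total_bp / ags_bp, float(ags_bp), "supplied_ags")
    per_marker = [
        h.aligned_bp / h.marker_len_bp for h in marker_hits.hits if h.aligned_bp > 0
    ]
    if not per_marker:
        raise ValueError("GEQ undefined: no marker has aligned bases")
    geq = float(np.median(per_marker))
    return GeqEstimate(sample_id, geq, total_bp / geq if geq > 0 else 0.0, "marker_coverage")


def marker_hits_from_alignments(
    alignments: Iterable[ReadAlignment],
    marker_intervals: Mapping[str, list[tuple[str, int, int]]],
    marker_lengths: Mapping[str, int],
) -> MarkerHitTable:
    """Accumulate read bases overlapping the markers' genomic copies.

    ``marker_intervals`` maps genome_id to a list of
    (marker_id, start, end) half-open intervals on that genome.
    """
    aligned: dict[str, int] = {m: 0 for m in marker_lengths}
    for aln in alignments:
        for marker_id, start, end in marker_intervals.get(aln.genome_id, ()):
            ov = min(aln.ref_end, end) - max(aln.ref_start, start)
            if ov > 0:
                aligned[marker_id] += ov
    return MarkerHitTable(
        [MarkerHit(m, marker_lengths[m], aligned[m]) for m in marker_lengths]
    )


def cell_fractions(
    depths: DepthTable,
    db: SourceDatabase,
    geq: GeqEstimate,
    detection_rule: DetectionRule = DetectionRule(),
) -> CellFractionTable:
    """Convert per-genome depths into per-category cell fractions.

    Genomes failing the detection rule contribute zero.  Each
    category's fraction splits exactly into a specific part (unflagged
    genomes) and a cross-reactive part.  Aggregation rules fold an
    aggregated category's signal into its target (as cross-reactive
    contribution) before reporting; the environmental screen category
    is computed and labelled as screen.
    """
    if geq.geq <= 0:
        raise ValueError("geq must be positive")
    agg = db.aggregation_map()
    screen = db.screen_category

    table = CellFractionTable(depths.sample_id, geq=geq.geq, ags_bp=geq.ags_bp)
    acc: dict[str, dict[str, float]] = {}
    report_cats = [c for c in db.categories if c not in agg]
    for cat in report_cats:
        acc[cat] = dict(spec=0.0, cross=0.0, n_det=0, n_spec=0)

    for g in db.genomes.values():
        entry = depths.entries.get(g.genome_id)
        if entry is None:
            continue
        detected = (
            entry.n_reads >= detection_rule.min_reads
            and entry.breadth >= detection_rule.min_breadth
        )
        if not detected:
            continue
        target = agg.get(g.source_category, g.source_category)
        a = acc[target]
        a["n_det"] += 1
        contrib = entry.depth / geq.geq
        # genomes folded into another category count as cross-reactive there
        if g.is_cross_reactive or target != g.source_category:
            a["cross"] += contrib
        else:
            a["spec"] += contrib
            a["n_spec"] += 1

    for cat in report_cats:
        a = acc[cat]
        table.fractions[cat] = CategoryFractions(
            category=cat,
            cell_fraction=a["spec"] + a["cross"],
            specific_fraction=a["spec"],
            cross_reactive_fraction=a["cross"],
            n_genomes_detected=int(a["n_det"]),
            n_specific_detected=int(a["n_spec"]),
            is_screen=cat == screen,
        )
    return table
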