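"""Per-genome sequencing depth, breadth and read counts.

Filtered alignments are accumulated into per-genome coverage with a
difference array (+1 at alignment start, -1 at end), giving exact
per-base coverage in linear time.  Depth is the mean coverage; with a
masking percentage ``m`` > 0 the m/2 % highest- and m/2 % lowest-
coverage positions are excluded before averaging (trimmed mean, the
CoverM-style interpretation of target genome masking).  Breadth is the
fraction of (unmasked) positions covered at least once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .alignments import ReadAlignment


@dataclass(frozen=True)
class GenomeDepth:
    genome_id: str
    depth: float
    breadth: float
    n_reads: int
    aligned_bp: int


@dataclass
class DepthTable:
    """Per-genome depth summary for one sample; zero-filled for
    genomes with no surviving alignments."""

    sample_id: str
    entries: dict[str, GenomeDepth] = field(default_factory=dict)
    total_reads: int = 0
    total_bp: int = 0

    def depth_of(self, genome_id: str) -> float:
        return self.entries[genome_id].depth

    def to_tsv(self, path, categories: Mapping[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tcategory\tdepth\tbreadth\tn_reads\taligned_bp\n")
            for gid, e in self.entries.items():
                cat = categories.get(gid, "") if categories else ""
                fh.write(
                    f"{gid}\t{cat}\t{e.depth:.6g}\t{e.breadth:.6g}\t{e.n_reads}\t{e.aligned_bp}\n"
                )


def _trimmed_mean_and_breadth(coverage: np.ndarray, masking_percent: float) -> tuple[float, float]:
    """Mean depth and breadth after symmetric coverage trimming.

    With masking m, floor(L * m/200) positions are dropped from each
    end of the coverage distribution (sorted by coverage) before both
    statistics are computed.
    """
    length = coverage.size
    if masking_percent <= 0:
        depth = float(coverage.mean()) if length else 0.0
        breadth = float(np.count_nonzero(coverage)) / length if length else 0.0
        return depth, breadth
    n_trim = int(length * masking_percent / 200.0)
    ordered = np.sort(coverage)
    kept = ordered[n_trim : length - n_trim] if length - 2 * n_trim > 0 else ordered[:0]
    if kept.size == 0:
        return 0.0, 0.0
    return float(kept.mean()), float(np.count_nonzero(kept)) / kept.size


def compute_depth(
    filtered: Iterable[ReadAlignment],
    genome_lengths: Mapping[str, int],
    *,
    masking_percent: float = 0.0,
    sample_id: str = "sample",
    total_reads: int = 0,
    total_bp: int = 0,
) -> DepthTable:
    """Accumulate filtered alignments into a DepthTable.

    ``genome_lengths`` must cover every genome the alignments mention
    and determines the zero-filled entry set.  Alignments overhanging
    a genome end are clipped to its bounds (counted per genome).
    ``masking_percent`` must lie in [0, 100).
    """
    if not 0.0 <= masking_percent < 100.0:
        raise ValueError("masking_percent must be in [0, 100)")

    diffs: dict[str, np.ndarray] = {}
    n_reads: dict[str, int] = {}
    aligned_bp: dict[str, int] = {}
    for aln in filtered:
        gid = aln.genome_id
        length = genome_lengths.get(gid)
        if length is None:
            raise KeyError(f"genome {gid!r} absent from genome_lengths")
        if gid not in diffs:
            diffs[gid] = np.zeros(length + 1, dtype=np.int64)
            n_reads[gid] = 0
            aligned_bp[gid] = 0
        start = max(0, aln.ref_start)
        end = min(length, aln.ref_end)
        if end <= start:
            continue
        diffs[gid][start] += 1
        diffs[gid][end] -= 1
        n_reads[gid] += 1
        aligned_bp[gid] += aln.aligned_len

    table = DepthTable(sample_id=sample_id, total_reads=total_reads, total_bp=total_bp)
    for gid, length in genome_lengths.items():
        if gid in diffs:
            coverage = np.cumsum(diffs[gid][:-1])
            depth, breadth = _trimmed_mean_and_breadth(coverage, masking_percent)
            table.entries[gid] = GenomeDepth(
                gid, depth, breadth, n_reads[gid], aligned_bp[gid]
            )
        else:
            table.entries[gid] = GenomeDepth(gid, 0.0, 0.0, 0, 0)
    return table
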