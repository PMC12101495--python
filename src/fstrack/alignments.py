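"""Parsing and threshold filtering of read-to-database alignments.

Reads are mapped against the concatenated source database by an
external aligner (bwa mem in the published workflow, or the
simulator's truth SAM here); this module consumes the SAM.  Only
primary records are kept — each read therefore contributes at most one
alignment, and multi-mapping across genomes is resolved by the
aligner.  Two per-record metrics drive filtering:

* identity_percent = 100 * (aligned_len - NM) / aligned_len, the
  read-to-genome alignment identity over aligned query bases;
* overlap_fraction = aligned_len / read_len, the fraction of the read
  covered by the alignment (soft-clipping lowers it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

# CIGAR operation codes consuming both query and reference (M, =, X)
_ALIGNED_OPS = {0, 7, 8}
_QUERY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X


@dataclass(frozen=True)
class ReadAlignment:
    """One primary read-to-genome alignment with filtering metrics.

    ``ref_start``/``ref_end`` are 0-based half-open positions on the
    genome (contig offsets already applied), clipped to genome bounds.
    """

    read_id: str
    genome_id: str
    read_len: int
    aligned_len: int
    edit_distance: int
    ref_start: int
    ref_end: int
    is_primary: bool = True

    @property
    def identity_percent(self) -> float:
        return 100.0 * (self.aligned_len - self.edit_distance) / self.aligned_len

    @property
    def overlap_fraction(self) -> float:
        return self.aligned_len / self.read_len


@dataclass(frozen=True)
class FilterThresholds:
    """Retention thresholds; both boundaries are inclusive (>=)."""

    min_identity: float = 93.0
    min_overlap: float = 70.0

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_overlap):
            if not 0.0 < v <= 100.0:
                raise ValueError("thresholds must be in (0, 100]")


@dataclass
class ParseStats:
    """Counters accumulated while streaming a SAM file."""

    n_records: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_missing_nm: int = 0
    n_clipped_overhang: int = 0
    n_parsed: int = 0
    total_read_bp: int = 0


def parse_alignments(
    sam_path,
    contig_table: Mapping[str, tuple[str, int, int]],
    stats: ParseStats | None = None,
) -> Iterator[ReadAlignment]:
    """Stream primary mapped records of a SAM file as ReadAlignment.

    ``contig_table`` maps each reference contig to
    (genome_id, offset within genome, contig length); an alignment to a
    contig absent from the table is a hard error.  Records without an
    NM tag are skipped with a counted warning.  Secondary,
    supplementary and unmapped records are dropped.
    """
    stats = stats if stats is not None else ParseStats()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            stats.n_records += 1
            if rec.is_unmapped:
                stats.n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.n_secondary += 1
                continue
            contig = rec.reference_name
            if contig not in contig_table:
                raise KeyError(f"reference {contig!r} not in contig table")
            genome_id, offset, contig_len = contig_table[contig]
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                stats.n_missing_nm += 1
                logger.warning("record %s lacks NM tag; skipped", rec.query_name)
                continue
            aligned_len = sum(
                length for op, length in rec.cigartuples if op in _ALIGNED_OPS
            )
            read_len = sum(
                length for op, length in rec.cigartuples if op in _QUERY_OPS
            )
            if aligned_len == 0 or read_len == 0:
                continue
            start = rec.reference_start + offset
            end = rec.reference_end + offset
            genome_end = offset + contig_len
            if start < offset or end > genome_end:
                stats.n_clipped_overhang += 1
                start = max(start, offset)
                end = min(end, genome_end)
            stats.n_parsed += 1
            stats.total_read_bp += read_len
            yield ReadAlignment(
                read_id=rec.query_name,
                genome_id=genome_id,
                read_len=read_len,
                aligned_len=aligned_len,
                edit_distance=int(nm),
                ref_start=start,
                ref_end=end,
            )


def filter_alignments(
    alignments: Iterable[ReadAlignment],
    thresholds: FilterThresholds = FilterThresholds(),
) -> Iterator[ReadAlignment]:
    """Retain alignments meeting both thresholds, preserving order."""
    for aln in alignments:
        if (
            aln.identity_percent >= thresholds.min_identity
            and aln.overlap_fraction * 100.0 >= thresholds.min_overlap
        ):
            yield aln


def read_contig_table(path) -> dict[str, tuple[str, int, int]]:
    """Read a contigs TSV (contig, genome_id, offset, length)."""
    table: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("contig\t") or line.startswith("#"):
                continue
            contig, gid, off, length = line.split("\t")
            table[contig] = (gid, int(off), int(length))
    return table
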