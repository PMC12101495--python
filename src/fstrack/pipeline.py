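"""End-to-end orchestration: SAM in, attribution/apportionment out.

One ``run_sample`` call executes the whole post-alignment chain —
parse, identity/overlap filter, depth, GEQ, cell fractions,
attribution, apportionment — under a single resolved configuration,
and writes every intermediate table plus a log of thresholds and stage
counts beside the results, so a run is fully reproducible from its
output directory alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignments import FilterThresholds, ParseStats, filter_alignments, parse_alignments
from .attribution import DEFAULT_LOD_PERCENT, SampleReport, report
from .depth import compute_depth
from .genome_db import SourceDatabase
from .geq import (
    DetectionRule,
    cell_fractions,
    estimate_geq,
    marker_hits_from_alignments,
)
from .simulate import read_marker_table

logger = logging.getLogger("fstrack")


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run.

    The GEQ backend is either a supplied average genome size
    (``ags_bp``) or a marker-coordinates table (``markers_path``);
    exactly one must be set.
    """

    database: str = ""
    min_identity: float = 93.0
    min_overlap: float = 70.0
    masking_percent: float = 0.0
    lod_percent: float = DEFAULT_LOD_PERCENT
    detection_min_reads: int = 1
    detection_min_breadth: float = 0.0
    ags_bp: float | None = None
    markers_path: str | None = None
    output_dir: str = "fstrack_out"
    log_level: str = "INFO"
    seed: int | None = None  # simulation only; recorded for provenance

    def __post_init__(self) -> None:
        if self.ags_bp is not None and self.markers_path:
            raise ValueError("set only one of ags_bp and markers_path")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analytic settings (output location excluded)."""
        data = asdict(self)
        data.pop("output_dir", None)
        data.pop("log_level", None)
        text = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(text).hexdigest()[:12]


@dataclass
class StageCounts:
    """Record counts at every pipeline stage, for the run log."""

    n_records: int = 0
    n_primary: int = 0
    n_filtered: int = 0
    filtered_aligned_bp: int = 0
    total_read_bp: int = 0


@dataclass
class RunResult:
    report: SampleReport
    counts: StageCounts
    output_dir: Path


def run_sample(
    config: RunConfig,
    sam_path,
    *,
    db: SourceDatabase | None = None,
    sample_id: str | None = None,
) -> RunResult:
    """Process one sample's alignments end to end and write reports."""
    if db is None:
        if not config.database:
            raise ValueError("no database in config and none supplied")
        db = SourceDatabase.read(config.database)
    sam_path = Path(sam_path)
    if not sam_path.exists():
        raise FileNotFoundError(sam_path)
    sample_id = sample_id or sam_path.stem

    out = Path(config.output_dir) / sample_id
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        logger.info(
            "fstrack %s run %s: identity>=%g overlap>=%g masking=%g lod=%g%%",
            __version__,
            sample_id,
            config.min_identity,
            config.min_overlap,
            config.masking_percent,
            config.lod_percent,
        )
        config.to_yaml(out / "run_config.yaml")

        stats = ParseStats()
        parsed = list(parse_alignments(sam_path, db.contig_table(), stats))
        thresholds = FilterThresholds(config.min_identity, config.min_overlap)
        filtered = list(filter_alignments(parsed, thresholds))
        counts = StageCounts(
            n_records=stats.n_records,
            n_primary=stats.n_parsed,
            n_filtered=len(filtered),
            filtered_aligned_bp=sum(a.aligned_len for a in filtered),
            total_read_bp=stats.total_read_bp,
        )
        logger.info(
            "records=%d primary=%d filtered=%d (skipped: unmapped=%d secondary=%d no-NM=%d)",
            stats.n_records,
            stats.n_parsed,
            len(filtered),
            stats.n_unmapped,
            stats.n_secondary,
            stats.n_missing_nm,
        )

        depths = compute_depth(
            filtered,
            db.genome_lengths(),
            masking_percent=config.masking_percent,
            sample_id=sample_id,
            total_reads=stats.n_parsed,
            total_bp=stats.total_read_bp,
        )
        depths.to_tsv(
            out / "genome_depth.tsv",
            categories={g.genome_id: g.source_category for g in db.genomes.values()},
        )

        if config.markers_path:
            intervals, lengths = read_marker_table(config.markers_path)
            hits = marker_hits_from_alignments(filtered, intervals, lengths)
            geq = estimate_geq(stats.total_read_bp, marker_hits=hits, sample_id=sample_id)
        else:
            geq = estimate_geq(
                stats.total_read_bp, ags_bp=config.ags_bp, sample_id=sample_id
            )
        logger.info("GEQ=%.4g (AGS=%.4g bp, %s)", geq.geq, geq.ags_bp, geq.method)

        rule = DetectionRule(config.detection_min_reads, config.detection_min_breadth)
        fracs = cell_fractions(depths, db, geq, rule)
        fracs.to_tsv(out / "cell_fractions.tsv")

        sample_report = report(fracs, config.lod_percent)
        sample_report.write_tsv(out / "attribution.tsv", out / "apportionment.tsv")
        present = sample_report.present_categories()
        logger.info(
            "present sources: %s", ", ".join(present) if present else "(none)"
        )
        _stamp_outputs(out, config)
        return RunResult(sample_report, counts, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stamp_outputs(out_dir: Path, config: RunConfig) -> None:
    """Prepend a version/config-hash comment to every TSV of the run."""
    stamp = f"# fstrack {__version__} config={config.digest()}\n"
    for tsv in out_dir.glob("*.tsv"):
        text = tsv.read_text()
        if not text.startswith("#"):
            tsv.write_text(stamp + text)
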