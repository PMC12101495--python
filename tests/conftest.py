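"""Shared fixtures: small synthetic genome sets, databases and samples.

Everything is generated programmatically at test time from fixed
seeds; nothing is read from stored data files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

import fstrack as fs

# six fecal spike-in categories plus one unspiked category (pig) and an
# environmental background set; pig shares a species with wastewater to
# exercise cross-reactivity
FECAL_CATEGORIES = ["wastewater", "cat", "goat", "chicken", "cow", "dog", "pig"]
MIX_FRACTIONS = {
    "wastewater": 0.10,
    "cat": 0.05,
    "goat": 0.05,
    "chicken": 0.05,
    "cow": 0.05,
    "dog": 0.05,
}


def write_sam(path, contigs: dict[str, int], rows: list[str]) -> Path:
    """Write a minimal SAM file from header lengths and record lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for row in rows:
            fh.write(row + "\n")
    return path


@dataclass
class MixBench:
    """An end-to-end benchmark: genomes, flagged database, reads, truth."""

    genomes: fs.GenomeSet
    db: fs.SourceDatabase
    sample: "fs.simulate.SimulatedSample"
    truth: fs.GroundTruthTable
    markers_path: Path
    workdir: Path


def _build_bench(tmp_path: Path, *, n_reads: int, error_rate: float, seed: int) -> MixBench:
    cats = {c: 3 for c in FECAL_CATEGORIES}
    cats["environmental"] = 4
    genomes = fs.generate_genomes(
        cats,
        shared_species=[("wastewater", "pig", 0.02)],
        seed=seed,
        out_dir=tmp_path / "genomes",
    )
    ani = fs.all_vs_all(genomes.sequences_str())
    db = fs.build_database(
        genomes.manifest,
        [(r.query_id, r.reference_id, r.ani_percent) for r in ani if r.defined],
        screen_category="environmental",
    )
    spec = fs.mixture_from_fractions(
        MIX_FRACTIONS, n_reads=n_reads, error_rate=error_rate, seed=seed + 1
    )
    sample = fs.simulate_mixture(
        genomes, spec, out_dir=tmp_path / "reads", sample_id="mix"
    )
    truth = fs.GroundTruthTable.from_tsv(sample.truth_path)
    return MixBench(
        genomes=genomes,
        db=db,
        sample=sample,
        truth=truth,
        markers_path=tmp_path / "genomes" / "markers.tsv",
        workdir=tmp_path,
    )


@pytest.fixture(scope="session")
def mix_bench(tmp_path_factory) -> MixBench:
    """Error-free mixture mirroring the mixed-spike-in design
    (10% wastewater + 5% each of five sources, 65% background)."""
    return _build_bench(
        tmp_path_factory.mktemp("mix"), n_reads=200_000, error_rate=0.0, seed=101
    )


@pytest.fixture(scope="session")
def noisy_bench(tmp_path_factory) -> MixBench:
    """Same design with 1% per-base sequencing error."""
    return _build_bench(
        tmp_path_factory.mktemp("noisy"), n_reads=200_000, error_rate=0.01, seed=202
    )


@pytest.fixture(scope="session")
def small_bench(tmp_path_factory) -> MixBench:
    """A light-weight mixture for tests that only need plumbing."""
    return _build_bench(
        tmp_path_factory.mktemp("small"), n_reads=20_000, error_rate=0.0, seed=303
    )


def run_bench(
    bench: MixBench,
    *,
    db: fs.SourceDatabase | None = None,
    sam_path=None,
    sample_id: str = "mix",
    out_name: str = "out",
    **config_kwargs,
) -> fs.pipeline.RunResult:
    config = fs.RunConfig(
        markers_path=str(bench.markers_path),
        output_dir=str(bench.workdir / out_name),
        **config_kwargs,
    )
    return fs.run_sample(
        config,
        sam_path or bench.sample.sam_path,
        db=db or bench.db,
        sample_id=sample_id,
    )
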