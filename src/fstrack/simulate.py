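"""Synthetic spike-in benchmark generation with exact ground truth.

This module builds self-contained analogues of a spike-in mesocosm
experiment: toy genomes organised into source categories (with
engineered cross-reactive species shared between categories and an
optional environmental background set), mixtures specified by cell
densities and volumes, and substitution-error short reads whose true
origin is recorded in a truth SAM — so the whole pipeline runs
without an external aligner and every estimate can be compared with a
value known by construction.

True cell fractions follow the mixing arithmetic used at mesocosm
construction: with cell density rho_i (cells/mL) and volume V_i (mL)
for each source and a background matrix (rho_lake, V_lake),

    total cells      = sum_i rho_i V_i + rho_lake V_lake
    source_i cells   = rho_i V_i
    cell fraction_i  = source_i cells / total cells

Universal single-copy marker sequences are embedded exactly once per
genome (spaced well apart) so that marker-coverage GEQ estimation has
a target; markers are short enough that they cannot dominate an ANI
fragment, keeping unrelated genomes below the flagging threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}

DEFAULT_MARKER_LEN = 400


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


# ------------------------------------------------------------- genomes

@dataclass
class GenomeSet:
    """Toy genomes with labels, marker coordinates and file locations."""

    sequences: dict[str, np.ndarray]  # genome_id -> uint8 codes 0..3
    categories: dict[str, str]  # genome_id -> category
    marker_intervals: dict[str, list[tuple[str, int, int]]]
    marker_lengths: dict[str, int]
    manifest: list[tuple[str, str, str]]  # (genome_id, fasta path, category)
    directory: Path | None = None
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)

    def genome_ids(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.sequences)
        return [g for g, c in self.categories.items() if c == category]

    def sequence_str(self, genome_id: str) -> str:
        return _decode(self.sequences[genome_id])

    def sequences_str(self) -> dict[str, str]:
        return {g: _decode(s) for g, s in self.sequences.items()}

    def genome_lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.sequences.items()}

    def drop_category(self, category: str) -> "GenomeSet":
        """A copy without one category's genomes (database ablation)."""
        keep = [g for g, c in self.categories.items() if c != category]
        return GenomeSet(
            sequences={g: self.sequences[g] for g in keep},
            categories={g: self.categories[g] for g in keep},
            marker_intervals={g: self.marker_intervals[g] for g in keep},
            marker_lengths=dict(self.marker_lengths),
            manifest=[row for row in self.manifest if row[0] in keep],
            directory=self.directory,
            shared_pairs=[p for p in self.shared_pairs if p[0] in keep and p[1] in keep],
        )


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """I.i.d. substitutions at ``rate``; every hit changes the base."""
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out, n


def generate_genomes(
    n_per_category: Mapping[str, int],
    *,
    genome_len: int = 20_000,
    shared_species: Sequence[tuple[str, str, float]] = (),
    n_markers: int = 3,
    marker_len: int = DEFAULT_MARKER_LEN,
    seed: int = 0,
    out_dir=None,
) -> GenomeSet:
    """Generate uniform-random genomes per category with embedded markers.

    Each ``shared_species`` entry (catA, catB, divergence) clones one
    catA genome into a catB slot with i.i.d. substitutions at the given
    divergence (<= 0.05 keeps the pair above the 95% ANI species
    boundary), engineering cross-reactivity.  ``n_markers`` universal
    single-copy marker sequences are embedded exactly once per genome
    at evenly spaced positions.
    """
    for _, _, div in shared_species:
        if not 0.0 <= div <= 0.05:
            raise ValueError("shared-species divergence must be in [0, 0.05]")
    if genome_len < (n_markers + 1) * marker_len:
        raise ValueError("genome_len too small for the requested markers")
    rng = np.random.default_rng(seed)

    markers = {
        f"marker_{i}": rng.integers(0, 4, size=marker_len).astype(np.uint8)
        for i in range(n_markers)
    }
    # slots spaced >= genome_len/(n_markers+1) apart so no two markers can
    # fall inside one ANI fragment
    slots = [
        int((i + 1) * genome_len / (n_markers + 1)) for i in range(n_markers)
    ]

    def new_genome() -> np.ndarray:
        g = rng.integers(0, 4, size=genome_len).astype(np.uint8)
        for (mid, mseq), pos in zip(markers.items(), slots):
            g[pos : pos + marker_len] = mseq
        return g

    sequences: dict[str, np.ndarray] = {}
    categories: dict[str, str] = {}
    for cat in n_per_category:
        for i in range(n_per_category[cat]):
            gid = f"{cat}_g{i}"
            sequences[gid] = new_genome()
            categories[gid] = cat

    shared_pairs: list[tuple[str, str]] = []
    replaced: dict[str, int] = {}
    for cat_a, cat_b, divergence in shared_species:
        src = f"{cat_a}_g0"
        if src not in sequences:
            raise KeyError(f"shared-species source category {cat_a!r} has no genomes")
        slot = n_per_category[cat_b] - 1 - replaced.get(cat_b, 0)
        if slot < 0:
            raise ValueError(f"category {cat_b!r} has no free slot for a shared species")
        replaced[cat_b] = replaced.get(cat_b, 0) + 1
        dst = f"{cat_b}_g{slot}"
        sequences[dst], _ = _mutate(sequences[src], divergence, rng)
        shared_pairs.append((src, dst))

    marker_intervals = {
        gid: [
            (mid, pos, pos + marker_len)
            for mid, pos in zip(markers, slots)
        ]
        for gid in sequences
    }
    marker_lengths = {mid: marker_len for mid in markers}

    manifest: list[tuple[str, str, str]] = []
    directory = None
    if out_dir is not None:
        directory = Path(out_dir)
        directory.mkdir(parents=True, exist_ok=True)
        for gid, codes in sequences.items():
            fasta = directory / f"{gid}.fasta"
            seq = _decode(codes)
            with open(fasta, "w") as fh:
                fh.write(f">{gid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
            manifest.append((gid, str(fasta), categories[gid]))
        with open(directory / "manifest.tsv", "w") as fh:
            fh.write("genome_id\tpath\tcategory\n")
            for gid, path, cat in manifest:
                fh.write(f"{gid}\t{path}\t{cat}\n")
        with open(directory / "markers.tsv", "w") as fh:
            fh.write(f"# seed={seed}\n")
            fh.write("genome_id\tmarker_id\tstart\tend\n")
            for gid, intervals in marker_intervals.items():
                for mid, start, end in intervals:
                    fh.write(f"{gid}\t{mid}\t{start}\t{end}\n")
    else:
        manifest = [(gid, "", categories[gid]) for gid in sequences]

    return GenomeSet(
        sequences=sequences,
        categories=categories,
        marker_intervals=marker_intervals,
        marker_lengths=marker_lengths,
        manifest=manifest,
        directory=directory,
        shared_pairs=shared_pairs,
    )


def read_marker_table(path) -> tuple[dict[str, list[tuple[str, int, int]]], dict[str, int]]:
    """Read a markers TSV back into interval and length maps."""
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            gid, mid, start, end = line.split("\t")
            intervals.setdefault(gid, []).append((mid, int(start), int(end)))
            lengths[mid] = int(end) - int(start)
    return intervals, lengths


# ------------------------------------------------------------- mixture

@dataclass(frozen=True)
class SourceSpike:
    name: str
    cell_density_rho: float  # cells/mL
    volume_ml: float


@dataclass(frozen=True)
class MixtureSpec:
    """A mesocosm-style mixture: fecal spike-ins plus background water."""

    sources: tuple[SourceSpike, ...]
    rho_lake: float
    v_lake: float
    n_reads: int = 100_000
    read_len: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.sources:
            if s.cell_density_rho < 0 or s.volume_ml < 0:
                raise ValueError("densities and volumes must be non-negative")
        if self.rho_lake < 0 or self.v_lake < 0:
            raise ValueError("background density and volume must be non-negative")
        if not 0.0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must be in [0, 0.25]")

    def digest(self) -> str:
        text = repr(self).encode()
        return hashlib.sha256(text).hexdigest()[:12]


def true_cell_fractions(spec: MixtureSpec) -> dict[str, float]:
    """Exact per-source cell fractions of the mixture design."""
    total = sum(s.cell_density_rho * s.volume_ml for s in spec.sources)
    total += spec.rho_lake * spec.v_lake
    if total <= 0:
        raise ValueError("mixture contains no cells")
    return {
        s.name: s.cell_density_rho * s.volume_ml / total for s in spec.sources
    }


def mixture_from_fractions(
    fractions: Mapping[str, float], **sequencing
) -> MixtureSpec:
    """Convenience: a unit-density mixture realizing given cell fractions."""
    total = sum(fractions.values())
    if total > 1.0 + 1e-12:
        raise ValueError("fractions must sum to at most 1")
    sources = tuple(
        SourceSpike(name, 1e6, frac) for name, frac in fractions.items()
    )
    return MixtureSpec(sources=sources, rho_lake=1e6, v_lake=1.0 - total, **sequencing)


# --------------------------------------------------------------- reads

@dataclass
class SimulatedSample:
    sample_id: str
    fastq_path: Path
    sam_path: Path
    provenance_path: Path
    truth_path: Path
    ground_truth: dict[str, float]
    n_reads: int
    read_len: int
    total_bp: int


_CHUNK = 20_000


def simulate_reads(
    genomes: GenomeSet,
    fractions: Mapping[str, float],
    *,
    n_reads: int,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir,
    sample_id: str = "sample",
    background_category: str | None = None,
    abundance_skew: float | None = None,
) -> SimulatedSample:
    """Simulate substitution-error reads at given source cell fractions.

    Each read's origin category is drawn proportional to its cell
    fraction, the genome uniformly within the category (or by a
    geometric series with ratio ``abundance_skew`` when set), position
    and strand uniformly.  Any fraction mass not assigned to a source
    goes to ``background_category``.  A truth SAM (CIGAR all-M, NM set
    to the substitutions applied) and a per-read provenance table are
    written beside the FASTQ, so no external aligner is needed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    spill = 1.0 - sum(fractions.values())
    if spill < -1e-9:
        raise ValueError("fractions sum to more than 1")
    weights = dict(fractions)
    if spill > 1e-9:
        if background_category is None:
            raise ValueError(
                "fractions sum to less than 1 and no background_category given"
            )
        weights[background_category] = weights.get(background_category, 0.0) + spill

    genome_ids: list[str] = []
    probs: list[float] = []
    for cat, w in weights.items():
        members = genomes.genome_ids(cat)
        if not members:
            raise KeyError(f"category {cat!r} has no genomes")
        if abundance_skew is None:
            per = [1.0] * len(members)
        else:
            per = [abundance_skew**i for i in range(len(members))]
        norm = sum(per)
        for gid, p in zip(members, per):
            genome_ids.append(gid)
            probs.append(w * p / norm)
    probs_arr = np.array(probs)
    probs_arr = probs_arr / probs_arr.sum()

    lengths = np.array([len(genomes.sequences[g]) for g in genome_ids])
    if (lengths < read_len).any():
        raise ValueError("read_len exceeds a genome length")

    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fastq_path = out / f"{sample_id}.fastq"
    sam_path = out / f"{sample_id}.sam"
    prov_path = out / f"{sample_id}.provenance.tsv"
    truth_path = out / f"{sample_id}.truth.tsv"

    qual = "I" * read_len
    origin_counts: dict[str, int] = {g: 0 for g in genome_ids}

    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam, open(
        prov_path, "w"
    ) as prov:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        for gid in genomes.sequences:
            sam.write(f"@SQ\tSN:{gid}\tLN:{len(genomes.sequences[gid])}\n")
        sam.write(f"@CO\tseed={seed} error_rate={error_rate} sample={sample_id}\n")
        prov.write(f"# seed={seed}\n")
        prov.write("read_id\tgenome_id\tcategory\tstart\tstrand\tn_subs\n")

        read_no = 0
        remaining = n_reads
        while remaining > 0:
            chunk = min(_CHUNK, remaining)
            remaining -= chunk
            gidx = rng.choice(len(genome_ids), size=chunk, p=probs_arr)
            starts = rng.integers(0, lengths[gidx] - read_len + 1)
            strands = rng.integers(0, 2, size=chunk)
            err_mask = (
                rng.random((chunk, read_len)) < error_rate
                if error_rate > 0
                else None
            )
            fq_parts: list[str] = []
            sam_parts: list[str] = []
            prov_parts: list[str] = []
            for i in range(chunk):
                gid = genome_ids[gidx[i]]
                start = int(starts[i])
                frag = genomes.sequences[gid][start : start + read_len]
                if err_mask is not None and err_mask[i].any():
                    frag = frag.copy()
                    hits = np.flatnonzero(err_mask[i])
                    frag[hits] = (frag[hits] + rng.integers(1, 4, size=hits.size)) % 4
                    n_subs = int(hits.size)
                else:
                    n_subs = 0
                rid = f"{sample_id}_r{read_no}"
                read_no += 1
                origin_counts[gid] += 1
                frag_str = _decode(frag)
                if strands[i]:
                    read_str = _decode(_revcomp_codes(frag))
                    flag = 16
                else:
                    read_str = frag_str
                    flag = 0
                fq_parts.append(f"@{rid}\n{read_str}\n+\n{qual}\n")
                sam_parts.append(
                    f"{rid}\t{flag}\t{gid}\t{start + 1}\t60\t{read_len}M\t*\t0\t0\t"
                    f"{frag_str}\t{qual}\tNM:i:{n_subs}\n"
                )
                prov_parts.append(
                    f"{rid}\t{gid}\t{genomes.categories[gid]}\t{start}\t"
                    f"{'-' if strands[i] else '+'}\t{n_subs}\n"
                )
            fq.write("".join(fq_parts))
            sam.write("".join(sam_parts))
            prov.write("".join(prov_parts))

    ground_truth = {
        cat: frac for cat, frac in fractions.items() if cat != background_category
    }
    with open(truth_path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("sample\tcategory\ttrue_cell_fraction\n")
        for cat, frac in ground_truth.items():
            fh.write(f"{sample_id}\t{cat}\t{frac:.10g}\n")

    return SimulatedSample(
        sample_id=sample_id,
        fastq_path=fastq_path,
        sam_path=sam_path,
        provenance_path=prov_path,
        truth_path=truth_path,
        ground_truth=ground_truth,
        n_reads=n_reads,
        read_len=read_len,
        total_bp=n_reads * read_len,
    )


def subset_sam(sam_in, sam_out, keep_genomes: set[str]) -> int:
    """Restrict a truth SAM to alignments on ``keep_genomes``.

    Emulates mapping against a database from which the other genomes
    were removed: their reads simply fail to align (no homolog exists).
    Returns the number of records kept.
    """
    kept = 0
    with open(sam_in) as fin, open(sam_out, "w") as fout:
        for line in fin:
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    name = next(
                        f[3:] for f in line.rstrip("\n").split("\t") if f.startswith("SN:")
                    )
                    if name not in keep_genomes:
                        continue
                fout.write(line)
                continue
            ref = line.split("\t", 4)[2]
            if ref in keep_genomes:
                fout.write(line)
                kept += 1
    return kept


def remap_reads(
    sam_in,
    sam_out,
    *,
    from_genome: str,
    to_genome: str,
    to_sequence: np.ndarray,
    keep_genomes: set[str] | None = None,
) -> int:
    """Re-place one genome's reads onto a homologous genome.

    Emulates an aligner's behaviour when ``from_genome`` is absent from
    the database but a near-identical species representative
    (``to_genome``) is present: reads keep their coordinates (the
    homolog is a substitution-level clone) and NM is recomputed against
    the target sequence.  Records on genomes outside ``keep_genomes``
    (when given) are dropped, except those being remapped.  Returns the
    number of remapped records.
    """
    target = _decode(to_sequence)
    n = 0
    with open(sam_in) as fin, open(sam_out, "w") as fout:
        for line in fin:
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    name = next(
                        f[3:] for f in line.rstrip("\n").split("\t") if f.startswith("SN:")
                    )
                    if name == from_genome or (
                        keep_genomes is not None and name not in keep_genomes
                    ):
                        continue
                fout.write(line)
                continue
            fields = line.rstrip("\n").split("\t")
            ref = fields[2]
            if ref == from_genome:
                pos = int(fields[3]) - 1
                seq = fields[9]
                ref_frag = target[pos : pos + len(seq)]
                nm = sum(a != b for a, b in zip(seq, ref_frag))
                fields[2] = to_genome
                fields = [
                    f if not f.startswith("NM:i:") else f"NM:i:{nm}" for f in fields
                ]
                fout.write("\t".join(fields) + "\n")
                n += 1
            elif keep_genomes is None or ref in keep_genomes:
                fout.write(line)
    return n


def simulate_mixture(
    genomes: GenomeSet,
    spec: MixtureSpec,
    *,
    out_dir,
    sample_id: str = "sample",
    background_category: str | None = "environmental",
) -> SimulatedSample:
    """Simulate a full mixture from a MixtureSpec (Eq-style fractions)."""
    fractions = true_cell_fractions(spec)
    return simulate_reads(
        genomes,
        fractions,
        n_reads=spec.n_reads,
        read_len=spec.read_len,
        error_rate=spec.error_rate,
        seed=spec.seed,
        out_dir=out_dir,
        sample_id=sample_id,
        background_category=background_category,
    )
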