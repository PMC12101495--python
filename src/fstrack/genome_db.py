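"""Source-labelled genome database with cross-reactivity flagging.

A database assigns every reference genome to a source category
(wastewater, septage, cow, dog, ... or any user-defined label).  Genome
pairs in *different* categories whose ANI meets the species-level
threshold (>= 95% by default) are flagged cross-reactive: reads mapping
to such genomes cannot, on their own, establish that a source is
present.  A category may additionally play one of two special roles:

* ``environmental_screen`` — autochthonous (background) genomes whose
  captured signal is reported but excluded from apportionment;
* ``aggregate_into:<target>`` — a category (e.g. human-specific
  genomes) whose signal is folded into a target fecal category, its
  genomes being treated as cross-reactive contributors to the target.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

ROLE_FECAL = "fecal_source"
ROLE_SCREEN = "environmental_screen"


@dataclass
class GenomeRecord:
    """One reference genome and its source label and flags.

    ``cross_reactive_with`` holds (genome_id, category) partners whose
    ANI met the threshold.  ``aggregation_flagged`` marks genomes of an
    aggregated category, which are cross-reactive by construction even
    without an ANI partner.
    """

    genome_id: str
    source_category: str
    length_bp: int
    sequence_path: str
    cross_reactive_with: set[tuple[str, str]] = field(default_factory=set)
    aggregation_flagged: bool = False
    contigs: list[tuple[str, int]] = field(default_factory=list)  # (name, length)

    @property
    def is_cross_reactive(self) -> bool:
        return bool(self.cross_reactive_with) or self.aggregation_flagged

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"genome {self.genome_id}: length_bp must be positive")


@dataclass(frozen=True)
class SourceCategory:
    name: str
    role: str = ROLE_FECAL
    aggregate_into: str | None = None

    @property
    def is_fecal(self) -> bool:
        return self.role == ROLE_FECAL and self.aggregate_into is None


class SourceDatabase:
    """Genomes plus categories, with symmetric cross-reactivity flags."""

    def __init__(
        self,
        genomes: Iterable[GenomeRecord],
        categories: Iterable[SourceCategory],
        ani_threshold: float = 95.0,
    ):
        self.genomes: dict[str, GenomeRecord] = {}
        for g in genomes:
            if g.genome_id in self.genomes:
                raise ValueError(f"duplicate genome_id {g.genome_id!r}")
            self.genomes[g.genome_id] = g
        self.categories: dict[str, SourceCategory] = {c.name: c for c in categories}
        self.ani_threshold = float(ani_threshold)
        self._validate()

    def _validate(self) -> None:
        screens = [c for c in self.categories.values() if c.role == ROLE_SCREEN]
        if len(screens) > 1:
            raise ValueError("at most one category may be the environmental screen")
        for c in self.categories.values():
            if c.aggregate_into is not None:
                target = self.categories.get(c.aggregate_into)
                if target is None or not target.is_fecal:
                    raise ValueError(
                        f"aggregation target {c.aggregate_into!r} of {c.name!r} "
                        "must be an existing fecal source category"
                    )
        for g in self.genomes.values():
            if g.source_category not in self.categories:
                raise ValueError(
                    f"genome {g.genome_id!r} has unknown category {g.source_category!r}"
                )
            for pid, pcat in g.cross_reactive_with:
                partner = self.genomes.get(pid)
                if partner is None or (g.genome_id, g.source_category) not in partner.cross_reactive_with:
                    raise ValueError(f"asymmetric cross-reactivity flag on {g.genome_id!r}")

    # -- queries -------------------------------------------------------

    @property
    def screen_category(self) -> str | None:
        for c in self.categories.values():
            if c.role == ROLE_SCREEN:
                return c.name
        return None

    def fecal_categories(self) -> list[str]:
        return [c.name for c in self.categories.values() if c.is_fecal]

    def aggregation_map(self) -> dict[str, str]:
        return {
            c.name: c.aggregate_into
            for c in self.categories.values()
            if c.aggregate_into is not None
        }

    def genomes_in(self, category: str) -> list[GenomeRecord]:
        return [g for g in self.genomes.values() if g.source_category == category]

    def specific_genomes(self, category: str) -> set[str]:
        """Genome ids of ``category`` that carry no cross-reactivity flag.

        Detection of at least one such genome is the first condition for
        calling the source present.
        """
        if category not in self.categories:
            raise KeyError(f"unknown category {category!r}")
        if not self.categories[category].is_fecal:
            raise ValueError(f"category {category!r} is not a fecal source")
        return {
            g.genome_id
            for g in self.genomes_in(category)
            if not g.is_cross_reactive
        }

    def genome_lengths(self) -> dict[str, int]:
        return {g.genome_id: g.length_bp for g in self.genomes.values()}

    def contig_table(self) -> dict[str, tuple[str, int, int]]:
        """Map contig name -> (genome_id, offset within genome, length)."""
        table: dict[str, tuple[str, int, int]] = {}
        for g in self.genomes.values():
            offset = 0
            for name, length in g.contigs:
                if name in table:
                    raise ValueError(f"contig name {name!r} occurs in more than one genome")
                table[name] = (g.genome_id, offset, length)
                offset += length
        return table

    # -- serialization -------------------------------------------------

    def write(self, directory) -> None:
        """Serialize to a directory of TSVs (manifest, flags, categories, contigs)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "manifest.tsv", "w") as fh:
            fh.write("genome_id\tpath\tcategory\tlength_bp\n")
            for g in self.genomes.values():
                fh.write(f"{g.genome_id}\t{g.sequence_path}\t{g.source_category}\t{g.length_bp}\n")
        with open(d / "flags.tsv", "w") as fh:
            fh.write("genome_id\tcategory\tflag\tpartner_ids\n")
            for g in self.genomes.values():
                partners = ";".join(
                    f"{pid}|{pcat}" for pid, pcat in sorted(g.cross_reactive_with)
                )
                flag = "cross_reactive" if g.is_cross_reactive else "specific"
                if g.aggregation_flagged:
                    flag = "cross_reactive_aggregated"
                fh.write(f"{g.genome_id}\t{g.source_category}\t{flag}\t{partners}\n")
        with open(d / "categories.tsv", "w") as fh:
            fh.write(f"# ani_threshold={self.ani_threshold}\n")
            fh.write("name\trole\taggregate_into\n")
            for c in self.categories.values():
                fh.write(f"{c.name}\t{c.role}\t{c.aggregate_into or ''}\n")
        with open(d / "contigs.tsv", "w") as fh:
            fh.write("contig\tgenome_id\toffset\tlength\n")
            for contig, (gid, off, length) in self.contig_table().items():
                fh.write(f"{contig}\t{gid}\t{off}\t{length}\n")

    @classmethod
    def read(cls, directory) -> "SourceDatabase":
        d = Path(directory)
        ani_threshold = 95.0
        categories = []
        with open(d / "categories.tsv") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    if key == "ani_threshold":
                        ani_threshold = float(val)
                    continue
                if line.startswith("name\t") or not line:
                    continue
                name, role, target = line.split("\t")
                categories.append(SourceCategory(name, role, target or None))
        genomes: dict[str, GenomeRecord] = {}
        with open(d / "manifest.tsv") as fh:
            next(fh)
            for line in fh:
                gid, path, cat, length = line.rstrip("\n").split("\t")
                genomes[gid] = GenomeRecord(gid, cat, int(length), path)
        with open(d / "contigs.tsv") as fh:
            next(fh)
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        for contig, gid, off, length in sorted(rows, key=lambda r: (r[1], int(r[2]))):
            genomes[gid].contigs.append((contig, int(length)))
        with open(d / "flags.tsv") as fh:
            next(fh)
            for line in fh:
                gid, _cat, flag, partners = (line.rstrip("\n").split("\t") + [""])[:4]
                g = genomes[gid]
                g.aggregation_flagged = flag == "cross_reactive_aggregated"
                if partners:
                    for item in partners.split(";"):
                        pid, _, pcat = item.partition("|")
                        g.cross_reactive_with.add((pid, pcat))
        return cls(genomes.values(), categories, ani_threshold)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SourceDatabase):
            return NotImplemented
        return (
            self.ani_threshold == other.ani_threshold
            and self.categories == other.categories
            and {g.genome_id for g in self.genomes.values()}
            == {g.genome_id for g in other.genomes.values()}
            and all(
                (g.source_category, g.length_bp, g.cross_reactive_with, g.aggregation_flagged)
                == (
                    other.genomes[gid].source_category,
                    other.genomes[gid].length_bp,
                    other.genomes[gid].cross_reactive_with,
                    other.genomes[gid].aggregation_flagged,
                )
                for gid, g in self.genomes.items()
            )
        )


def read_manifest(path) -> list[tuple[str, str, str]]:
    """Read a manifest TSV of genome_id<TAB>fasta path<TAB>category."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            gid, fasta, cat = line.split("\t")
            rows.append((gid, fasta, cat))
    return rows


def read_ani_tsv(path) -> list[tuple[str, str, float]]:
    """Read an ANI TSV of query<TAB>reference<TAB>ani_percent."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query\t"):
                continue
            q, r, ani = line.split("\t")
            rows.append((q, r, float(ani)))
    return rows


def build_database(
    manifest: Iterable[tuple[str, str, str]],
    ani_table: Iterable[tuple[str, str, float]] = (),
    *,
    ani_threshold: float = 95.0,
    screen_category: str | None = None,
    aggregation_rules: Mapping[str, str] | None = None,
    base_dir: str | os.PathLike | None = None,
) -> SourceDatabase:
    """Build a database from a genome manifest and an ANI table.

    ``manifest`` rows are (genome_id, fasta_path, category); every FASTA
    is parsed to record contig names and lengths.  ``ani_table`` rows
    are (query, reference, ani_percent); the flagging rule uses the
    maximum of the two directions for each unordered pair (pairs absent
    from the table are treated as below threshold) and only pairs in
    different categories are ever flagged.
    """
    aggregation_rules = dict(aggregation_rules or {})
    genomes: dict[str, GenomeRecord] = {}
    for gid, fasta, cat in manifest:
        if gid in genomes:
            raise ValueError(f"duplicate genome_id {gid!r} in manifest")
        fasta_path = Path(base_dir) / fasta if base_dir else Path(fasta)
        contigs = [(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
        total = sum(length for _, length in contigs)
        if total == 0:
            raise ValueError(f"empty FASTA for genome {gid!r}: {fasta_path}")
        genomes[gid] = GenomeRecord(
            genome_id=gid,
            source_category=cat,
            length_bp=total,
            sequence_path=str(fasta_path),
            contigs=contigs,
        )

    category_names = {g.source_category for g in genomes.values()}
    for src, target in aggregation_rules.items():
        if src not in category_names:
            raise ValueError(f"aggregation rule for unknown category {src!r}")
        if target not in category_names:
            raise ValueError(f"aggregation target {target!r} is not a database category")
    if screen_category is not None and screen_category not in category_names:
        raise ValueError(f"screen category {screen_category!r} has no genomes")

    categories = []
    for name in sorted(category_names):
        if name == screen_category:
            categories.append(SourceCategory(name, ROLE_SCREEN))
        elif name in aggregation_rules:
            categories.append(SourceCategory(name, ROLE_FECAL, aggregation_rules[name]))
        else:
            categories.append(SourceCategory(name))

    # max over the two fastANI-style directions of each unordered pair
    pair_ani: dict[frozenset, float] = {}
    for q, r, ani in ani_table:
        if q == r or q not in genomes or r not in genomes:
            continue
        key = frozenset((q, r))
        pair_ani[key] = max(pair_ani.get(key, 0.0), ani)
    for key, ani in pair_ani.items():
        a, b = sorted(key)
        ga, gb = genomes[a], genomes[b]
        if ga.source_category == gb.source_category:
            continue
        if ani >= ani_threshold:
            ga.cross_reactive_with.add((b, gb.source_category))
            gb.cross_reactive_with.add((a, ga.source_category))

    for g in genomes.values():
        if g.source_category in aggregation_rules:
            g.aggregation_flagged = True

    return SourceDatabase(genomes.values(), categories, ani_threshold)
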