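"""Synthetic benchmark generator: mixing arithmetic, reads, determinism."""

import numpy as np
import pytest

import fstrack as fs
from fstrack.simulate import (
    MixtureSpec,
    SourceSpike,
    generate_genomes,
    mixture_from_fractions,
    simulate_reads,
    true_cell_fractions,
)


class TestTrueCellFractions:
    def test_single_source_arithmetic(self):
        spec = MixtureSpec(
            sources=(SourceSpike("cow", 1e6, 1.0),), rho_lake=1e6, v_lake=9.0
        )
        assert true_cell_fractions(spec)["cow"] == pytest.approx(0.1)

    def test_mixed_design_fractions(self):
        # the mixed mesocosm: 10% wastewater-associated cells and 5% each
        # of cat, goat, chicken, cow and dog; 65% background
        spec = MixtureSpec(
            sources=(
                SourceSpike("wastewater", 1e6, 10.0),
                SourceSpike("cat", 1e6, 5.0),
                SourceSpike("goat", 1e6, 5.0),
                SourceSpike("chicken", 1e6, 5.0),
                SourceSpike("cow", 1e6, 5.0),
                SourceSpike("dog", 1e6, 5.0),
            ),
            rho_lake=1e6,
            v_lake=65.0,
        )
        fracs = true_cell_fractions(spec)
        assert fracs["wastewater"] == pytest.approx(0.10)
        for cat in ("cat", "goat", "chicken", "cow", "dog"):
            assert fracs[cat] == pytest.approx(0.05)
        assert sum(fracs.values()) == pytest.approx(0.35)

    def test_zero_volume_source_has_zero_fraction(self):
        spec = MixtureSpec(
            sources=(SourceSpike("cow", 1e6, 0.0),), rho_lake=1e6, v_lake=1.0
        )
        assert true_cell_fractions(spec)["cow"] == 0.0

    def test_all_zero_mixture_is_error(self):
        spec = MixtureSpec(sources=(SourceSpike("cow", 0.0, 1.0),), rho_lake=0.0, v_lake=1.0)
        with pytest.raises(ValueError):
            true_cell_fractions(spec)

    def test_density_volume_equivalence(self):
        # only the rho*V products matter
        a = MixtureSpec(sources=(SourceSpike("cow", 2e6, 0.5),), rho_lake=1e6, v_lake=9.0)
        b = MixtureSpec(sources=(SourceSpike("cow", 1e6, 1.0),), rho_lake=3e6, v_lake=3.0)
        assert true_cell_fractions(a) == true_cell_fractions(b)


class TestGenerateGenomes:
    def test_shared_species_is_flagged_via_ani(self, tmp_path):
        genomes = generate_genomes(
            {"pig": 2, "wastewater": 2},
            shared_species=[("wastewater", "pig", 0.02)],
            seed=30,
            out_dir=tmp_path,
        )
        (src, dst) = genomes.shared_pairs[0]
        res = fs.estimate_ani(genomes.sequence_str(src), genomes.sequence_str(dst))
        assert res.ani_percent >= 95.0
        ani_rows = [
            (r.query_id, r.reference_id, r.ani_percent)
            for r in fs.all_vs_all(genomes.sequences_str())
            if r.defined
        ]
        db = fs.build_database(genomes.manifest, ani_rows)
        assert db.genomes[src].is_cross_reactive
        assert db.genomes[dst].is_cross_reactive

    def test_zero_divergence_clone_has_ani_100(self, tmp_path):
        genomes = generate_genomes(
            {"a": 1, "b": 1}, shared_species=[("a", "b", 0.0)], seed=31, out_dir=tmp_path
        )
        src, dst = genomes.shared_pairs[0]
        assert np.array_equal(genomes.sequences[src], genomes.sequences[dst])
        assert fs.estimate_ani(
            genomes.sequence_str(src), genomes.sequence_str(dst)
        ).ani_percent == 100.0

    def test_no_shared_species_no_flags(self, tmp_path):
        genomes = generate_genomes({"a": 2, "b": 2}, seed=32, out_dir=tmp_path)
        ani_rows = [
            (r.query_id, r.reference_id, r.ani_percent)
            for r in fs.all_vs_all(genomes.sequences_str())
            if r.defined
        ]
        db = fs.build_database(genomes.manifest, ani_rows)
        assert not any(g.is_cross_reactive for g in db.genomes.values())

    def test_each_marker_embedded_exactly_once_per_genome(self, tmp_path):
        genomes = generate_genomes({"a": 2}, seed=33, out_dir=tmp_path)
        for gid in genomes.sequences:
            seq = genomes.sequence_str(gid)
            for mid, start, end in genomes.marker_intervals[gid]:
                marker = seq[start:end]
                assert seq.count(marker) == 1

    def test_markers_shared_across_all_genomes(self, tmp_path):
        genomes = generate_genomes({"a": 1, "b": 1}, seed=34, out_dir=tmp_path)
        a, b = genomes.genome_ids("a")[0], genomes.genome_ids("b")[0]
        for (mid, s1, e1), (_, s2, e2) in zip(
            genomes.marker_intervals[a], genomes.marker_intervals[b]
        ):
            assert genomes.sequence_str(a)[s1:e1] == genomes.sequence_str(b)[s2:e2]

    def test_excessive_divergence_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_genomes(
                {"a": 1, "b": 1}, shared_species=[("a", "b", 0.10)], seed=0, out_dir=tmp_path
            )

    def test_genome_too_small_for_markers_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_genomes({"a": 1}, genome_len=1000, seed=0, out_dir=tmp_path)


class TestSimulateReads:
    def test_error_free_reads_parse_at_full_identity(self, tmp_path):
        genomes = generate_genomes({"a": 2}, seed=40, out_dir=tmp_path / "g")
        sample = simulate_reads(
            genomes, {"a": 1.0}, n_reads=500, seed=41, out_dir=tmp_path / "r"
        )
        contigs = {g: (g, 0, 20_000) for g in genomes.sequences}
        parsed = list(fs.parse_alignments(sample.sam_path, contigs))
        assert len(parsed) == 500
        assert all(a.identity_percent == 100.0 for a in parsed)
        assert all(a.overlap_fraction == 1.0 for a in parsed)

    def test_origin_proportions_within_binomial_noise(self, tmp_path):
        genomes = generate_genomes({"A": 2, "env": 2}, seed=42, out_dir=tmp_path / "g")
        n = 20_000
        frac = 0.2
        sample = simulate_reads(
            genomes,
            {"A": frac},
            n_reads=n,
            seed=43,
            out_dir=tmp_path / "r",
            background_category="env",
        )
        n_a = 0
        with open(sample.provenance_path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("read_id\t"):
                    continue
                if line.split("\t")[2] == "A":
                    n_a += 1
        sigma = (frac * (1 - frac) / n) ** 0.5
        assert abs(n_a / n - frac) <= 3 * sigma

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        genomes = generate_genomes({"a": 2, "env": 1}, seed=44, out_dir=tmp_path / "g")
        kwargs = dict(n_reads=400, error_rate=0.01, seed=45, background_category="env")
        s1 = simulate_reads(genomes, {"a": 0.5}, out_dir=tmp_path / "r1", **kwargs)
        s2 = simulate_reads(genomes, {"a": 0.5}, out_dir=tmp_path / "r2", **kwargs)
        assert s1.fastq_path.read_bytes() == s2.fastq_path.read_bytes()
        assert s1.sam_path.read_bytes() == s2.sam_path.read_bytes()

    def test_error_rate_produces_matching_nm_tags(self, tmp_path):
        # NM in the truth SAM equals the mismatches between SEQ and genome
        genomes = generate_genomes({"a": 1}, seed=46, out_dir=tmp_path / "g")
        sample = simulate_reads(
            genomes, {"a": 1.0}, n_reads=200, error_rate=0.02, seed=47, out_dir=tmp_path / "r"
        )
        seq = genomes.sequence_str("a_g0")
        with open(sample.sam_path) as fh:
            for line in fh:
                if line.startswith("@"):
                    continue
                f = line.rstrip("\n").split("\t")
                pos, read = int(f[3]) - 1, f[9]
                nm = next(int(t[5:]) for t in f[11:] if t.startswith("NM:i:"))
                assert nm == sum(a != b for a, b in zip(read, seq[pos : pos + len(read)]))

    def test_truth_table_matches_requested_fractions(self, tmp_path):
        genomes = generate_genomes({"a": 1, "b": 1, "env": 1}, seed=48, out_dir=tmp_path / "g")
        sample = simulate_reads(
            genomes,
            {"a": 0.1, "b": 0.02},
            n_reads=100,
            seed=49,
            out_dir=tmp_path / "r",
            background_category="env",
        )
        truth = fs.GroundTruthTable.from_tsv(sample.truth_path)
        assert truth.true_fraction("sample", "a") == pytest.approx(0.1)
        assert truth.true_fraction("sample", "b") == pytest.approx(0.02)
        assert ("sample", "env") not in truth.fractions

    def test_invalid_inputs(self, tmp_path):
        genomes = generate_genomes({"a": 1}, seed=50, out_dir=tmp_path / "g")
        with pytest.raises(ValueError):
            simulate_reads(genomes, {"a": 1.0}, n_reads=0, out_dir=tmp_path / "r")
        with pytest.raises(ValueError):
            simulate_reads(genomes, {"a": 0.5}, n_reads=10, out_dir=tmp_path / "r")
        with pytest.raises(ValueError):
            simulate_reads(
                genomes, {"a": 1.0}, n_reads=10, read_len=30_000, out_dir=tmp_path / "r"
            )
        with pytest.raises(ValueError):
            MixtureSpec(sources=(), rho_lake=1e6, v_lake=1.0, error_rate=0.5)


def test_mixture_from_fractions_round_trip():
    fracs = {"a": 0.1, "b": 0.05}
    spec = mixture_from_fractions(fracs, n_reads=10)
    out = true_cell_fractions(spec)
    assert out["a"] == pytest.approx(0.1)
    assert out["b"] == pytest.approx(0.05)
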