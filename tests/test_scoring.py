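"""Scoring arithmetic, closed-form oracles and the tuning grid."""

import itertools
import math

import numpy as np
import pytest

import fstrack as fs
from fstrack.attribution import SampleReport, SourceCall, REASON_PRESENT, REASON_BELOW_LOD
from fstrack.geq import CategoryFractions, CellFractionTable
from fstrack.scoring import (
    GroundTruthTable,
    ParameterGrid,
    TuningSample,
    calibrate_cell_fractions,
    evaluate_parameter_set,
    run_grid,
    score_apportionment,
    score_attribution,
)


def make_report(sample_id, fractions, present, portions=None):
    t = CellFractionTable(sample_id, geq=100.0)
    calls = []
    for cat, frac in fractions.items():
        t.fractions[cat] = CategoryFractions(cat, frac, frac, 0.0, 1, 1)
        if cat in present:
            calls.append(SourceCall(cat, True, REASON_PRESENT))
        else:
            calls.append(SourceCall(cat, False, REASON_BELOW_LOD))
    return SampleReport(sample_id, calls, t, portions or {}, 0.01)


def truth_of(rows):
    t = GroundTruthTable()
    for sample, cat, frac in rows:
        t.fractions[(sample, cat)] = frac
    return t


class TestScoreAttribution:
    CATS = ["A", "B"]

    def test_all_correct_gives_perfect_rates(self):
        truth = truth_of([("s1", "A", 0.1), ("s1", "B", 0.0)])
        rep = make_report("s1", {"A": 0.1, "B": 0.0}, present={"A"})
        score = score_attribution([rep], truth, self.CATS)
        assert score.sensitivity == 1.0 and score.specificity == 1.0

    def test_hand_counts(self):
        # tp=3 fp=1 fn=1 tn=5 over five samples x two categories
        truth_rows, reports = [], []
        design = [  # (true A, true B, called A, called B)
            (1, 0, 1, 0), (1, 0, 1, 0), (1, 0, 1, 1), (0, 1, 0, 0), (0, 0, 0, 0),
        ]
        for i, (ta, tb, ca, cb) in enumerate(design):
            sid = f"s{i}"
            truth_rows += [(sid, "A", 0.1 * ta), (sid, "B", 0.1 * tb)]
            present = {c for c, flag in zip("AB", (ca, cb)) if flag}
            reports.append(make_report(sid, {"A": 0.1, "B": 0.1}, present))
        score = score_attribution(reports, truth_of(truth_rows), self.CATS)
        assert (score.counts.tp, score.counts.fp, score.counts.fn, score.counts.tn) == (3, 1, 1, 5)
        assert score.sensitivity == pytest.approx(0.75)
        assert score.specificity == pytest.approx(5 / 6)
        assert score.npv == pytest.approx(5 / 6)
        assert score.counts.total == 10

    def test_all_negative_truth_yields_undefined_sensitivity(self):
        truth = truth_of([("s1", "A", 0.0), ("s1", "B", 0.0)])
        rep = make_report("s1", {"A": 0.0, "B": 0.0}, present=set())
        score = score_attribution([rep], truth, self.CATS)
        assert score.sensitivity is None
        assert score.specificity == 1.0

    def test_unknown_sample_is_hard_error(self):
        truth = truth_of([("s1", "A", 0.1)])
        rep = make_report("ghost", {"A": 0.1}, present=set())
        with pytest.raises(KeyError):
            score_attribution([rep], truth, ["A"])


class TestScoreApportionment:
    def test_perfect_predictions_give_r_one(self):
        truth = truth_of([("s1", "A", 0.2), ("s1", "B", 0.1), ("s2", "A", 0.3), ("s2", "B", 0.0)])
        reports = [
            make_report("s1", {"A": 0.2, "B": 0.1}, {"A", "B"},
                        portions={"A": 2 / 3, "B": 1 / 3}),
            make_report("s2", {"A": 0.3, "B": 0.0}, {"A"}, portions={"A": 1.0}),
        ]
        assert score_apportionment(reports, truth, ["A", "B"]) == pytest.approx(1.0)

    def test_constant_offset_preserves_r(self):
        truth = truth_of([("s1", "A", 0.2), ("s1", "B", 0.1), ("s1", "C", 0.1)])
        tp = truth.true_portions("s1")
        rep = make_report("s1", {c: 0.1 for c in "ABC"}, {"A", "B", "C"},
                          portions={c: tp[c] + 0.05 for c in "ABC"})
        assert score_apportionment([rep], truth, list("ABC")) == pytest.approx(1.0)

    def test_matches_covariance_formula_on_hand_table(self):
        predicted = [0.5, 0.3, 0.2, 0.0, 0.7, 0.3]
        actual = [0.6, 0.2, 0.2, 0.1, 0.6, 0.4]
        # brute-force Pearson from the definition
        mp, ma = sum(predicted) / 6, sum(actual) / 6
        cov = sum((p - mp) * (a - ma) for p, a in zip(predicted, actual))
        vp = sum((p - mp) ** 2 for p in predicted)
        va = sum((a - ma) ** 2 for a in actual)
        expected = cov / math.sqrt(vp * va)

        truth = truth_of(
            [("s1", c, f) for c, f in zip("ABC", actual[:3])]
            + [("s2", c, f) for c, f in zip("ABC", actual[3:])]
        )
        # the truth table normalizes to portions; feed fractions already
        # normalized so true portions equal `actual`
        assert sum(actual[:3]) == 1.0 and sum(actual[3:]) > 0
        reports = [
            make_report("s1", {c: 0.1 for c in "ABC"}, set("ABC"),
                        portions=dict(zip("ABC", predicted[:3]))),
            make_report("s2", {c: 0.1 for c in "ABC"}, set("ABC"),
                        portions=dict(zip("ABC", [p / sum(actual[3:]) * sum(actual[3:]) for p in predicted[3:]]))),
        ]
        # normalize second sample's truth to portions for the oracle
        t2 = truth.true_portions("s2")
        oracle_actual = actual[:3] + [t2[c] for c in "ABC"]
        mp2, ma2 = sum(predicted) / 6, sum(oracle_actual) / 6
        cov2 = sum((p - mp2) * (a - ma2) for p, a in zip(predicted, oracle_actual))
        vp2 = sum((p - mp2) ** 2 for p in predicted)
        va2 = sum((a - ma2) ** 2 for a in oracle_actual)
        expected = cov2 / math.sqrt(vp2 * va2)
        assert score_apportionment(reports, truth, list("ABC")) == pytest.approx(expected)

    def test_constant_vector_reported_missing(self):
        truth = truth_of([("s1", "A", 0.5), ("s1", "B", 0.5), ("s1", "C", 0.0)])
        rep = make_report("s1", {c: 0.1 for c in "ABC"}, set(),
                          portions={})
        assert score_apportionment([rep], truth, list("ABC")) is None

    def test_too_few_pairs_rejected(self):
        truth = truth_of([("s1", "A", 1.0)])
        rep = make_report("s1", {"A": 0.1}, {"A"}, portions={"A": 1.0})
        with pytest.raises(ValueError):
            score_apportionment([rep], truth, ["A"])


class TestCalibration:
    def test_exact_threefold_underestimate(self):
        predicted = [0.01, 0.02, 0.05, 0.10]
        true = [3 * p for p in predicted]
        cal = calibrate_cell_fractions(predicted, true)
        assert cal.slope == pytest.approx(3.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_identity_slope(self):
        pred = [0.01, 0.03, 0.07]
        assert calibrate_cell_fractions(pred, pred).slope == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        predicted = [0.01, 0.04, 0.02, 0.08, 0.05]
        true = [0.05, 0.11, 0.09, 0.30, 0.16]
        n = len(predicted)
        sx, sy = sum(predicted), sum(true)
        sxx = sum(p * p for p in predicted)
        sxy = sum(p * t for p, t in zip(predicted, true))
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        cal = calibrate_cell_fractions(predicted, true)
        assert cal.slope == pytest.approx(slope)
        assert cal.intercept == pytest.approx(intercept)

    def test_degenerate_predictor_is_error(self):
        with pytest.raises(ValueError):
            calibrate_cell_fractions([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])


class TestParameterGrid:
    def test_default_grid_enumerates_640_combinations(self):
        grid = ParameterGrid()
        assert grid.size == 640
        assert len(list(grid.combinations())) == 640

    def test_single_value_axes_give_one_combination(self):
        grid = ParameterGrid((93,), (70,), (0,), (0.01,))
        assert grid.size == 1

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(identities=())


def _grid_fixture(tmp_path):
    """Tiny two-category benchmark where only identity >= 93 removes the
    cross-source noise reads hitting category B."""
    genomes = fs.generate_genomes({"A": 1, "B": 1, "env": 1}, genome_len=5000,
                                  seed=20, out_dir=tmp_path / "g")
    db = fs.build_database(genomes.manifest, [], screen_category="env")
    lengths = genomes.genome_lengths()

    def aln(rid, gid, start, nm, read_len=150):
        return fs.ReadAlignment(rid, gid, read_len, read_len, nm, start, start + read_len)

    rng = np.random.default_rng(21)
    alignments = []
    for i in range(300):  # true signal on A, identity 100
        alignments.append(aln(f"a{i}", "A_g0", int(rng.integers(0, 4850)), 0))
    for i in range(120):  # noise on B at identity ~90 (15 mismatches / 150)
        alignments.append(aln(f"b{i}", "B_g0", int(rng.integers(0, 4850)), 15))
    sample = TuningSample("s1", alignments, total_bp=63_000, total_reads=420, ags_bp=5000.0)
    truth = truth_of([("s1", "A", 0.7), ("s1", "B", 0.0)])
    return [sample], db, truth


def test_grid_equals_naive_recompute_and_ranks_identity(tmp_path):
    samples, db, truth = _grid_fixture(tmp_path)
    grid = ParameterGrid((85, 89, 93, 97), (30, 70), (0, 50), (0.1, 0.01))
    results = run_grid(samples, db, grid, truth)
    assert len(results) == grid.size

    # cached sweep must equal the recompute-everything loop
    naive = {
        (i, o, m, l): evaluate_parameter_set(samples, db, i, o, m, l, truth)
        for i, o, m, l in grid.combinations()
    }
    for res in results:
        key = (res.min_identity, res.min_overlap, res.masking_percent, res.lod_percent)
        other = naive[key]
        assert res.counts == other.counts
        assert res.npv == other.npv
        assert res.sensitivity == other.sensitivity

    # exhaustive re-scoring confirms every top-ranked set removes the noise:
    # NPV is 1 only when identity >= 93 filters the B reads
    best_npv = max(r.npv for r in naive.values() if r.npv is not None)
    top = [r for r in results if r.npv == best_npv]
    assert top and all(r.min_identity >= 93 for r in top)

    # ranking is a total deterministic order
    again = run_grid(samples, db, grid, truth)
    assert [
        (r.min_identity, r.min_overlap, r.masking_percent, r.lod_percent) for r in again
    ] == [
        (r.min_identity, r.min_overlap, r.masking_percent, r.lod_percent) for r in results
    ]


def test_confusion_counts_partition_the_call_set(tmp_path):
    samples, db, truth = _grid_fixture(tmp_path)
    grid = ParameterGrid((85, 93), (30,), (0,), (0.01,))
    for res in run_grid(samples, db, grid, truth):
        assert res.counts.total == len(samples) * len(db.fecal_categories())
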