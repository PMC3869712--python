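import math

import numpy as np
import pytest

from barcodekit.distances import distance_matrix
from barcodekit.errors import AnalysisError
from barcodekit.identify import (
    IdOutcome,
    SweepRow,
    adhoc_threshold,
    asb_identify,
    bcm_identify,
    best_match,
    bm_identify,
    confusion_classify,
    threshold_sweep,
)
from barcodekit.synthetic import SimConfig, simulate_library

from conftest import make_alignment, mutate, random_sequence


def _library_with_tie(rng):
    """Query q sits at exactly 1 substitution from one conspecific and one
    heterospecific sequence."""
    s = random_sequence(rng, 100)
    return make_alignment(
        [
            ("q", "Sp x", "p", s),
            ("x1", "Sp x", "p", mutate(rng, s, [10])),
            ("y1", "Sp y", "p", mutate(rng, s, [20])),
            ("x2", "Sp x", "p", mutate(rng, s, [10, 30, 40])),
            ("y2", "Sp y", "p", mutate(rng, s, [20, 50, 60])),
        ]
    )


class TestBestMatch:
    def test_identical_conspecific(self, rng):
        s = random_sequence(rng, 80)
        aln = make_alignment(
            [("q", "Sp x", "p", s), ("a", "Sp x", "p", s), ("b", "Sp y", "p", mutate(rng, s, [0, 1]))]
        )
        dm = distance_matrix(aln)
        d, species, evidence = best_match("q", dm, aln.species_map())
        assert d == 0.0
        assert species == {"Sp x"}
        assert evidence[0].seq_id == "a"

    def test_tie_pools_species(self, rng):
        aln = _library_with_tie(rng)
        dm = distance_matrix(aln)
        d, species, _ = best_match("q", dm, aln.species_map())
        assert species == {"Sp x", "Sp y"}

    def test_matches_brute_force(self, rng):
        base = random_sequence(rng, 60)
        aln = make_alignment(
            [
                (f"s{k}", f"Sp {k % 3}", "p",
                 mutate(rng, base, rng.choice(60, size=k % 5 + 1, replace=False)))
                for k in range(10)
            ]
        )
        dm = distance_matrix(aln)
        for q in aln.ids:
            d, _, _ = best_match(q, dm, aln.species_map())
            assert d == min(dm.get(q, i) for i in aln.ids if i != q)


class TestBM:
    def test_well_separated_all_correct(self, two_species_library):
        dm = distance_matrix(two_species_library)
        outcomes, summary = bm_identify(dm, two_species_library.species_map())
        assert summary.counts["correct"] == 10
        assert summary.n_queries == 10

    def test_shared_haplotype_ambiguous(self, rng):
        s = random_sequence(rng, 80)
        aln = make_alignment(
            [
                ("q", "Sp x", "p", s),
                ("a", "Sp x", "p", s),  # haplotype shared by both species
                ("b", "Sp y", "p", s),
                ("c", "Sp y", "p", mutate(rng, s, [1])),
            ]
        )
        dm = distance_matrix(aln)
        outcomes, _ = bm_identify(dm, aln.species_map())
        verdict = {o.query_id: o.verdict for o in outcomes}["q"]
        assert verdict == "ambiguous"

    def test_singleton_species_excluded(self, rng):
        s = random_sequence(rng, 80)
        aln = make_alignment(
            [
                ("a1", "Sp x", "p", s),
                ("a2", "Sp x", "p", mutate(rng, s, [0])),
                ("lone", "Sp z", "p", mutate(rng, s, [1, 2])),
            ]
        )
        dm = distance_matrix(aln)
        outcomes, summary = bm_identify(dm, aln.species_map())
        assert summary.excluded == ("lone",)
        assert {o.query_id for o in outcomes} == {"a1", "a2"}

    def test_verdicts_invariant_to_record_order(self, rng):
        aln = _library_with_tie(rng)
        dm = distance_matrix(aln)
        base, _ = bm_identify(dm, aln.species_map())
        base_verdicts = {o.query_id: o.verdict for o in base}
        reordered = make_alignment(
            [(r.seq_id, r.species, r.population, r.sequence) for r in reversed(aln.records)]
        )
        dm2 = distance_matrix(reordered)
        again, _ = bm_identify(dm2, reordered.species_map())
        assert {o.query_id: o.verdict for o in again} == base_verdicts


class TestBCM:
    def test_no_match_beyond_threshold(self, two_species_library):
        dm = distance_matrix(two_species_library)
        outcomes, summary = bcm_identify(dm, two_species_library.species_map(), 1e-9)
        assert summary.counts["no_match"] == summary.n_queries

    def test_infinite_threshold_equals_bm(self, rng):
        aln = _library_with_tie(rng)
        dm = distance_matrix(aln)
        bm_out, _ = bm_identify(dm, aln.species_map())
        bcm_out, _ = bcm_identify(dm, aln.species_map(), math.inf)
        assert [o.verdict for o in bcm_out] == [o.verdict for o in bm_out]

    def test_threshold_at_max_best_equals_bm(self, rng):
        aln, _ = simulate_library(SimConfig(seed=42, n_true_species=3))
        dm = distance_matrix(aln)
        species = aln.species_map()
        bm_out, _ = bm_identify(dm, species)
        max_best = max(o.best_distance for o in bm_out)
        bcm_out, _ = bcm_identify(dm, species, max_best)
        assert [o.verdict for o in bcm_out] == [o.verdict for o in bm_out]


class TestASB:
    def test_exclusive_top_ranks_correct(self, two_species_library):
        dm = distance_matrix(two_species_library)
        outcomes, summary = asb_identify(dm, two_species_library.species_map(), 0.05)
        assert summary.counts["correct"] == summary.n_queries

    def test_interleaved_heterospecific_ambiguous(self, rng):
        # hand-built 6-sequence toy: a heterospecific barcode sits between
        # the query's conspecifics in the rank list
        s = random_sequence(rng, 200)
        aln = make_alignment(
            [
                ("q", "Sp x", "p", s),
                ("x1", "Sp x", "p", mutate(rng, s, [0])),  # rank 1
                ("y1", "Sp y", "p", mutate(rng, s, [1, 2])),  # rank 2: intruder
                ("x2", "Sp x", "p", mutate(rng, s, [3, 4, 5])),  # rank 3
                ("y2", "Sp y", "p", mutate(rng, s, list(range(10, 20)))),
                ("y3", "Sp y", "p", mutate(rng, s, list(range(20, 30)))),
            ]
        )
        dm = distance_matrix(aln)
        outcomes, _ = asb_identify(dm, aln.species_map(), 0.2)
        assert {o.query_id: o.verdict for o in outcomes}["q"] == "ambiguous"

    def test_no_match_when_conspecifics_beyond_threshold(self, two_species_library):
        dm = distance_matrix(two_species_library)
        outcomes, summary = asb_identify(
            dm, two_species_library.species_map(), 1e-9
        )
        assert summary.counts["no_match"] == summary.n_queries

    def test_species_below_three_excluded(self, rng):
        s = random_sequence(rng, 80)
        aln = make_alignment(
            [
                ("a1", "Sp x", "p", s),
                ("a2", "Sp x", "p", mutate(rng, s, [0])),
                ("b1", "Sp y", "p", mutate(rng, s, [10, 11])),
                ("b2", "Sp y", "p", mutate(rng, s, [10, 12])),
                ("b3", "Sp y", "p", mutate(rng, s, [10, 13])),
            ]
        )
        dm = distance_matrix(aln)
        outcomes, summary = asb_identify(dm, aln.species_map(), 0.1)
        assert set(summary.excluded) == {"a1", "a2"}
        assert {o.query_id for o in outcomes} == {"b1", "b2", "b3"}

    def test_asb_correct_implies_bcm_correct(self):
        # property over random libraries
        for seed in range(5):
            aln, _ = simulate_library(
                SimConfig(seed=seed, n_true_species=3, individuals_per_population=3)
            )
            dm = distance_matrix(aln)
            species = aln.species_map()
            thr = 0.04
            asb_out, _ = asb_identify(dm, species, thr)
            bcm_out, _ = bcm_identify(dm, species, thr)
            bcm_by_id = {o.query_id: o.verdict for o in bcm_out}
            for o in asb_out:
                if o.verdict == "correct":
                    assert bcm_by_id[o.query_id] == "correct"


def _outcome(query_id, verdict, best_distance, tied, truth, thr):
    return IdOutcome(
        query_id=query_id,
        protocol="BCM",
        verdict=verdict,
        best_distance=best_distance,
        best_match_species=frozenset(tied),
        true_species=truth,
        evidence=(),
        threshold=thr,
    )


class TestConfusion:
    def test_all_correct(self):
        outcomes = [
            _outcome(f"q{k}", "correct", 0.01, {"Sp x"}, "Sp x", 0.02) for k in range(5)
        ]
        row = confusion_classify(outcomes)
        assert (row.tp, row.fp, row.tn, row.fn) == (5, 0, 0, 0)
        assert row.accuracy == 1.0
        assert row.relative_id_error == 0.0

    def test_threshold_zero_all_discarded(self):
        outcomes = [
            _outcome(f"q{k}", "no_match", 0.01, {"Sp x"}, "Sp x", 0.0) for k in range(3)
        ]
        row = confusion_classify(outcomes)
        assert row.tp == 0 and row.fp == 0
        assert row.precision is None
        assert row.relative_id_error is None

    def test_hand_tally(self):
        outcomes = (
            [_outcome(f"c{k}", "correct", 0.01, {"A a"}, "A a", 0.02) for k in range(7)]
            + [_outcome(f"i{k}", "incorrect", 0.01, {"B b"}, "A a", 0.02) for k in range(2)]
            + [_outcome("d0", "no_match", 0.05, {"A a"}, "A a", 0.02)]
        )
        row = confusion_classify(outcomes)
        assert (row.tp, row.fp, row.fn, row.tn) == (7, 2, 1, 0)
        assert row.accuracy == pytest.approx(0.7)
        assert row.relative_id_error == pytest.approx(2 / 9)

    def test_mixed_thresholds_rejected(self):
        outcomes = [
            _outcome("a", "correct", 0.01, {"A a"}, "A a", 0.02),
            _outcome("b", "correct", 0.01, {"A a"}, "A a", 0.03),
        ]
        with pytest.raises(AnalysisError):
            confusion_classify(outcomes)


class TestSweep:
    @pytest.fixture
    def library(self):
        aln, _ = simulate_library(SimConfig(seed=7, n_true_species=4))
        return aln

    def test_top_row_nothing_discarded(self, library):
        dm = distance_matrix(library)
        rows = threshold_sweep(dm, library.species_map(), 30)
        top = rows[0]
        assert top.discarded == 0
        assert top.tp + top.fp == top.total

    def test_top_row_equals_bm_and_confusion_route(self, library):
        # dual route: sweep row vs confusion_classify over bcm_identify
        dm = distance_matrix(library)
        species = library.species_map()
        rows = threshold_sweep(dm, species, 30)
        bcm_out, _ = bcm_identify(dm, species, rows[0].threshold)
        via_confusion = confusion_classify(bcm_out)
        assert (rows[0].tp, rows[0].fp, rows[0].tn, rows[0].fn) == (
            via_confusion.tp, via_confusion.fp, via_confusion.tn, via_confusion.fn,
        )
        _, bm_summary = bm_identify(dm, species)
        assert rows[0].tp == bm_summary.counts["correct"]

    def test_discarded_monotone_and_conserved(self, library):
        dm = distance_matrix(library)
        rows = threshold_sweep(dm, library.species_map(), 30)
        assert len(rows) == 30
        total = rows[0].total
        for prev, cur in zip(rows, rows[1:]):
            assert cur.threshold < prev.threshold
            assert cur.discarded >= prev.discarded
            assert cur.total == total

    def test_bottom_row_zero_threshold(self, library):
        dm = distance_matrix(library)
        species = library.species_map()
        rows = threshold_sweep(dm, species, 30)
        bottom = rows[-1]
        assert bottom.threshold == 0.0
        # only zero-distance queries retained
        kept_expected = sum(
            1
            for q in dm.ids
            if min(dm.get(q, i) for i in dm.ids if i != q) == 0.0
        )
        assert bottom.tp + bottom.fp == kept_expected

    def test_custom_grid(self, library):
        dm = distance_matrix(library)
        rows = threshold_sweep(dm, library.species_map(), thresholds=[0.01, 0.05, 0.0])
        assert [r.threshold for r in rows] == [0.05, 0.01, 0.0]


def _row_with_relative_error(thr, rel, denom=1000):
    fp = round(rel * denom)
    return SweepRow(threshold=thr, tp=denom - fp, fp=fp, tn=0, fn=0)


class TestAdhoc:
    def test_two_point_line_unattainable(self):
        rows = [
            _row_with_relative_error(0.00, 0.06, denom=100),
            _row_with_relative_error(0.01, 0.08, denom=100),
        ]
        fit = adhoc_threshold(rows, target_error=0.05)
        assert fit.intercept == pytest.approx(0.06, abs=1e-12)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.threshold_at_target == pytest.approx(-0.005, abs=1e-12)
        assert not fit.attainable

    def test_negative_threshold_branch(self):
        # intercept 0.06, solution -0.02: impossible to apply
        rows = [
            _row_with_relative_error(0.00, 0.06, denom=200),
            _row_with_relative_error(0.02, 0.07, denom=200),
            _row_with_relative_error(0.04, 0.08, denom=200),
        ]
        fit = adhoc_threshold(rows)
        assert fit.intercept == pytest.approx(0.06, abs=1e-12)
        assert fit.threshold_at_target == pytest.approx(-0.02, abs=1e-12)
        assert not fit.attainable

    def test_noiseless_line_recovered(self):
        slope, intercept = 2.0, 0.01
        rows = [
            _row_with_relative_error(t, intercept + slope * t)
            for t in (0.0, 0.005, 0.01, 0.015, 0.02)
        ]
        fit = adhoc_threshold(rows, target_error=0.05)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.attainable
        assert fit.threshold_at_target == pytest.approx((0.05 - 0.01) / 2.0, abs=1e-9)
        # exact target value at the solution
        assert intercept + slope * fit.threshold_at_target == pytest.approx(0.05)

    def test_undefined_rows_excluded(self):
        rows = [
            SweepRow(threshold=0.0, tp=0, fp=0, tn=5, fn=5),  # undefined
            _row_with_relative_error(0.01, 0.02),
            _row_with_relative_error(0.02, 0.03),
        ]
        fit = adhoc_threshold(rows)
        assert fit.n_points == 2

    def test_all_undefined_raises(self):
        rows = [SweepRow(threshold=t, tp=0, fp=0, tn=5, fn=5) for t in (0.0, 0.01)]
        with pytest.raises(AnalysisError):
            adhoc_threshold(rows)
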