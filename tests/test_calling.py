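"""Run-rule deletion calling, flags, border refinement, gene intersection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from delscan import (
    BACKGROUND_POLYMORPHISM,
    CallerParams,
    DeletionCall,
    GeneModel,
    HomoeologyMap,
    call_deletions,
    deletion_size,
    flag_shared_calls,
    gene_content,
    intersect_homoeologues,
    refine_borders,
)
from delscan.calling import find_low_blocks

MB = 1_000_000


class TestCallDeletions:
    def test_minimal_qualifying_run(self, make_profile):
        cov = make_profile([1, 1, 0.05, 0.05, 0.05, 0.05, 1, 1, 1, 1])
        (call,) = call_deletions(cov, CallerParams())
        assert (call.start, call.end) == (2 * MB, 6 * MB)
        assert call.n_low_bins == 4
        assert call.method == "bin"

    def test_three_low_bins_not_called(self, make_profile):
        cov = make_profile([1, 0.05, 0.05, 0.05, 1, 1, 1, 1, 1])
        assert call_deletions(cov, CallerParams()) == []

    def test_interior_high_run_absorbed(self, make_profile):
        # interior 3-bin high run absorbed; trailing 4-bin high run terminates
        cov = make_profile([0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1])
        (call,) = call_deletions(cov, CallerParams())
        assert (call.start, call.end) == (0, 11 * MB)
        assert call.n_low_bins == 8

    def test_chromosome_end_terminates(self, make_profile):
        cov = make_profile([1, 1, 0.0, 0.0, 0.0, 0.0, 0.0])
        (call,) = call_deletions(cov, CallerParams())
        assert (call.start, call.end) == (2 * MB, 7 * MB)

    def test_masked_bins_are_neutral(self, make_profile):
        # masked bins interrupt neither the low run nor the high run
        nan = float("nan")
        cov = make_profile([1, 0.0, nan, 0.0, 0.0, 0.0, 1, nan, 1, 1, 1])
        (call,) = call_deletions(cov, CallerParams())
        assert (call.start, call.end) == (1 * MB, 6 * MB)
        assert call.n_low_bins == 4

    def test_empty_profile_is_empty_list(self, make_profile):
        assert call_deletions(make_profile([]), CallerParams()) == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CallerParams(low_fraction=1.5)
        with pytest.raises(ValueError):
            CallerParams(min_low_run=0)

    @given(st.lists(st.sampled_from([0.0, 0.05, 0.5, 1.0]), max_size=40),
           st.integers(1, 4), st.integers(1, 4))
    def test_matches_segment_oracle_on_random_profiles(self, values, min_low, min_high):
        from conftest import oracle_calls as oracle

        assert find_low_blocks(values, 0.1, min_low, min_high) == oracle(
            values, 0.1, min_low, min_high
        )

    @given(st.lists(st.floats(0, 1.5, allow_nan=False), max_size=30))
    def test_threshold_monotonicity(self, values):
        """Calls at a lower threshold are each contained in a call at a
        higher threshold; the number of low bins never decreases."""
        lo = find_low_blocks(values, 0.1, 2, 2)
        hi = find_low_blocks(values, 0.3, 2, 2)
        n_low_lo = sum(1 for v in values if v <= 0.1)
        n_low_hi = sum(1 for v in values if v <= 0.3)
        assert n_low_hi >= n_low_lo
        for s, e, _ in lo:
            assert any(hs <= s and e <= he for hs, he, _ in hi)


class TestFlagSharedCalls:
    def _call(self, line, chrom, start, end):
        return DeletionCall(line, chrom, start, end, n_low_bins=4)

    def test_identical_call_in_two_lines_flagged(self):
        calls = {
            "A1": [self._call("A1", "Chr6B", 258 * MB, 262 * MB)],
            "D4": [self._call("D4", "Chr6B", 258 * MB, 262 * MB)],
        }
        flagged = flag_shared_calls(calls)
        for line in ("A1", "D4"):
            assert BACKGROUND_POLYMORPHISM in flagged[line][0].flags

    def test_non_overlapping_calls_unflagged(self):
        calls = {
            "A1": [self._call("A1", "Chr6B", 0, 4 * MB)],
            "D4": [self._call("D4", "Chr6B", 10 * MB, 14 * MB)],
        }
        flagged = flag_shared_calls(calls)
        assert not flagged["A1"][0].flags and not flagged["D4"][0].flags

    def test_private_call_among_three_lines_unflagged(self):
        calls = {
            "A1": [self._call("A1", "Chr1B", 0, 4 * MB)],
            "D4": [],
            "X9": [],
        }
        assert not flag_shared_calls(calls)["A1"][0].flags

    def test_single_line_returned_unchanged(self):
        calls = {"A1": [self._call("A1", "Chr1B", 0, 4 * MB)]}
        assert flag_shared_calls(calls) == calls

    def test_no_call_is_removed(self):
        calls = {
            "A1": [self._call("A1", "Chr6B", 0, 4 * MB)],
            "D4": [self._call("D4", "Chr6B", 2 * MB, 6 * MB)],
        }
        flagged = flag_shared_calls(calls)
        assert len(flagged["A1"]) == 1 and len(flagged["D4"]) == 1


class TestDeletionSize:
    @pytest.mark.parametrize(
        "start,end,size",
        [
            (576_555_092, 600_555_092, 24_000_000),
            (562_939_364, 673_617_499, 110_678_135),
            (0, 21_516_171, 21_516_171),
        ],
    )
    def test_size_is_end_minus_start(self, start, end, size):
        call = DeletionCall("L", "chr", start, end, n_low_bins=4)
        assert deletion_size(call) == size == call.size


def _genes(intervals, chrom="chr1", covered=True):
    return [
        GeneModel(f"g{i + 1}", chrom, s, e, wildtype_covered=covered)
        for i, (s, e) in enumerate(intervals)
    ]


class TestRefineBorders:
    def test_direct_application(self):
        genes = _genes([(100, 200), (300, 400), (500, 600), (700, 800)])
        values = {"g1": 1.0, "g2": 0.0, "g3": 0.0, "g4": 1.0}
        call = DeletionCall("L", "chr1", 250, 650, n_low_bins=4)
        refined = refine_borders(call, genes, values)
        assert (refined.start, refined.end) == (300, 600)
        assert refined.method == "refined"
        assert refined.flank_upstream == "g1"
        assert refined.flank_downstream == "g4"

    def test_all_genes_covered_returns_unchanged(self):
        genes = _genes([(100, 200), (300, 400)])
        call = DeletionCall("L", "chr1", 0, 500, n_low_bins=4)
        refined = refine_borders(call, genes, {"g1": 1.0, "g2": 1.0})
        assert refined is call and refined.method == "bin"

    def test_uncovered_genes_ignored(self):
        genes = _genes([(100, 200)], covered=False)
        call = DeletionCall("L", "chr1", 0, 500, n_low_bins=4)
        assert refine_borders(call, genes, {"g1": 0.0}) is call

    def test_refined_may_exceed_bin_extent(self):
        # a low gene straddling the bin boundary extends the refined call
        genes = _genes([(900, 1100), (1200, 1300), (2000, 2100)])
        values = {"g1": 0.0, "g2": 0.0, "g3": 1.0}
        call = DeletionCall("L", "chr1", 1000, 1500, n_low_bins=4)
        refined = refine_borders(call, genes, values)
        assert (refined.start, refined.end) == (900, 1300)
        assert refined.size > 0

    def test_matches_exhaustive_scan_on_random_annotation(self):
        """On a synthetic chromosome the refined interval spans exactly the
        contiguous run of low-coverage genes, bounded by covered flanks."""
        rng = np.random.default_rng(19)
        length, planted = 200 * MB, (80 * MB, 120 * MB)
        starts = np.sort(rng.choice(np.arange(0, length - 5000, 10_000), 200, replace=False))
        genes = _genes([(int(s), int(s) + 3000) for s in starts])
        values = {
            g.gene_id: 0.0 if (g.start >= planted[0] and g.end <= planted[1]) else 1.0
            for g in genes
        }
        call = DeletionCall("L", "chr1", planted[0], planted[1], n_low_bins=40)
        refined = refine_borders(call, genes, values)
        low = [g for g in genes if values[g.gene_id] == 0.0]
        high_before = [g for g in genes if values[g.gene_id] > 0.1 and g.end <= planted[0]]
        high_after = [g for g in genes if values[g.gene_id] > 0.1 and g.start >= planted[1]]
        assert refined.start == min(g.start for g in low)
        assert refined.end == max(g.end for g in low)
        assert planted[0] <= refined.start and refined.end <= planted[1]
        assert refined.flank_upstream == high_before[-1].gene_id
        assert refined.flank_downstream == high_after[0].gene_id


class TestGeneContent:
    def test_partial_overlap_included(self):
        call = DeletionCall("L", "chr1", 0, 15, n_low_bins=4)
        assert len(gene_content(call, _genes([(10, 20)]))) == 1

    def test_half_open_boundary_excluded(self):
        call = DeletionCall("L", "chr1", 0, 20, n_low_bins=4)
        assert gene_content(call, _genes([(20, 30)])) == []

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        genes = _genes([(int(s), int(s) + 500) for s in rng.integers(0, 100_000, 50)])
        call = DeletionCall("L", "chr1", 20_000, 60_000, n_low_bins=4)
        expected = [g for g in genes if max(g.start, 20_000) < min(g.end, 60_000)]
        assert gene_content(call, genes) == expected


class TestIntersectHomoeologues:
    def test_disjoint_map_empty(self):
        a = _genes([(0, 10)], chrom="chr4A")
        b = _genes([(0, 10)], chrom="chr4D")
        assert intersect_homoeologues(a, b, HomoeologyMap()) == []

    def test_planted_pairs_recovered(self):
        a = _genes([(i * 100, i * 100 + 50) for i in range(5)], chrom="chr4A")
        b = [
            GeneModel(f"h{i + 1}", "chr4D", i * 100, i * 100 + 50) for i in range(5)
        ]
        pairs = [(f"g{i + 1}", f"h{i + 1}") for i in range(3)]
        out = intersect_homoeologues(a, b, HomoeologyMap(pairs))
        assert [(x.gene_id, y.gene_id) for x, y in out] == pairs

    def test_one_to_many_reports_first_by_coordinate(self):
        a = _genes([(0, 10)], chrom="chr4A")
        b = [GeneModel("h2", "chr4D", 100, 110), GeneModel("h1", "chr4D", 0, 10)]
        homo = HomoeologyMap([("g1", "h1"), ("g1", "h2")])
        out = intersect_homoeologues(a, b, homo)
        assert len(out) == 1 and out[0][1].gene_id == "h1"

    def test_each_gene_in_at_most_one_pair(self):
        a = _genes([(0, 10), (20, 30)], chrom="chr4A")
        b = [GeneModel("h1", "chr4D", 0, 10)]
        homo = HomoeologyMap([("g1", "h1"), ("g2", "h1")])
        out = intersect_homoeologues(a, b, homo)
        assert len(out) == 1 and out[0][0].gene_id == "g1"
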