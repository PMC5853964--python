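"""Synthetic-data generators: determinism, marginals, truth tables."""

import numpy as np
import pandas as pd
import pytest

from delscan import (
    CallerParams,
    HomoeologyMap,
    call_deletions,
    gene_content,
    infer_deletion_extent,
    intersect_homoeologues,
    normalize_coverage,
)
from delscan.calling import DeletionCall
from delscan.layouts import ANCHOR_MARKER, PANEL_4AL, line_a1_spec
from delscan.simulate import (
    ChromosomeSpec,
    CoverageSimParams,
    GenomeSpec,
    bin_grid,
    make_parts_map,
    simulate_coverage_pair,
    simulate_gene_models,
    simulate_granule_image,
    simulate_marker_table,
)

SMALL_SPEC = GenomeSpec(
    chromosomes=[ChromosomeSpec("chr1", 40_000_000)],
    deletions=[("chr1", 10_000_000, 16_000_000)],
    line_id="mut",
)


class TestCoveragePair:
    def test_deterministic_given_seed(self):
        p = CoverageSimParams(seed=77)
        a = simulate_coverage_pair(SMALL_SPEC, p)
        b = simulate_coverage_pair(SMALL_SPEC, p)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        pd.testing.assert_frame_equal(a[1].df, b[1].df)

    def test_zero_residual_zero_noise_gives_exact_zero_inside(self):
        p = CoverageSimParams(capture_efficiency_sd=0.0, residual_in_deletion=0.0, seed=1)
        mut, wt, truth = simulate_coverage_pair(SMALL_SPEC, p)
        df = mut.df
        inside = (df["start"] >= 10_000_000) & (df["end"] <= 16_000_000)
        assert (df.loc[inside, "count"] == 0).all()
        assert (df.loc[~inside, "count"] > 0).all()

    def test_marginal_mean_matches_model(self):
        """Empirical per-bin mean is within 3 SE of mean x efficiency."""
        spec = GenomeSpec([ChromosomeSpec("chr1", 10_000_000_000)], [], line_id="m")
        p = CoverageSimParams(mean_reads_per_bin=100, capture_efficiency_sd=0.3, seed=5)
        mut, wt, _ = simulate_coverage_pair(spec, p)
        n = len(wt.df)
        assert n == 10_000
        expected = 100 * np.exp(0.3**2 / 2)  # lognormal mean
        var = 100**2 * (np.exp(0.3**2) - 1) * np.exp(0.3**2) + expected
        se = np.sqrt(var / n)
        assert abs(wt.df["count"].mean() - expected) < 3 * se

    def test_truth_table_lists_planted_intervals(self):
        _, _, truth = simulate_coverage_pair(SMALL_SPEC, CoverageSimParams(seed=2))
        assert truth[["chrom", "start", "end"]].values.tolist() == [
            ["chr1", 10_000_000, 16_000_000]
        ]

    def test_parts_coordinates_round_trip_through_lift(self):
        from delscan import lift_parts_to_full

        spec = GenomeSpec(
            [ChromosomeSpec("chr1", 9_500_000, part1_length=4_300_000)],
            [("chr1", 5_300_000, 9_300_000)],
            line_id="m",
        )
        full_m, full_w, _ = simulate_coverage_pair(spec, CoverageSimParams(seed=3))
        part_m, part_w, _ = simulate_coverage_pair(
            spec, CoverageSimParams(seed=3), coordinates="parts"
        )
        assert set(part_m.df["chrom"]) == {"chr1_part1", "chr1_part2"}
        lifted = lift_parts_to_full(part_m, make_parts_map(spec))
        pd.testing.assert_frame_equal(
            lifted.df.reset_index(drop=True), full_m.df.reset_index(drop=True)
        )

    def test_grid_respects_parts_offsets(self):
        spec = GenomeSpec([ChromosomeSpec("c", 5_700_154, part1_length=2_720_154)], [])
        grid = bin_grid(spec)
        assert grid["start"].tolist() == [0, 1_000_000, 2_000_000, 2_720_154, 3_720_154, 4_720_154]
        assert grid["end"].tolist() == [1_000_000, 2_000_000, 2_720_154, 3_720_154, 4_720_154, 5_700_154]

    def test_overlapping_planted_deletions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GenomeSpec(
                [ChromosomeSpec("chr1", 10_000_000)],
                [("chr1", 0, 5_000_000), ("chr1", 4_000_000, 6_000_000)],
            )


class TestGeneModels:
    def test_density_and_non_overlap(self):
        spec = GenomeSpec([ChromosomeSpec("chr1", 10_000_000)], [])
        genes, _, _ = simulate_gene_models(spec, density=1.0, seed=4)
        assert 5 <= len(genes) <= 12
        ordered = sorted(genes, key=lambda g: g.start)
        assert all(a.end <= b.start for a, b in zip(ordered, ordered[1:]))

    def test_full_homoeology_identical_layouts_recovers_everything(self):
        spec = GenomeSpec(
            [ChromosomeSpec("chr4A", 50_000_000), ChromosomeSpec("chr4D", 50_000_000)],
            [("chr4A", 10_000_000, 30_000_000), ("chr4D", 10_000_000, 30_000_000)],
            line_id="m",
        )
        genes, homo, values = simulate_gene_models(
            spec, density=1.0, homoeology_fraction=1.0, seed=6,
            paired_chromosomes=("chr4A", "chr4D"),
        )
        call_a = DeletionCall("m", "chr4A", 10_000_000, 30_000_000, n_low_bins=20)
        call_d = DeletionCall("m", "chr4D", 10_000_000, 30_000_000, n_low_bins=20)
        in_a = gene_content(call_a, [g for g in genes if g.chromosome == "chr4A"])
        in_d = gene_content(call_d, [g for g in genes if g.chromosome == "chr4D"])
        pairs = intersect_homoeologues(in_a, in_d, homo)
        assert len(pairs) == len(in_a) == len(in_d) > 0

    def test_zero_fraction_empty_intersection(self):
        spec = GenomeSpec(
            [ChromosomeSpec("chr4A", 20_000_000), ChromosomeSpec("chr4D", 20_000_000)], []
        )
        genes, homo, _ = simulate_gene_models(
            spec, density=1.0, homoeology_fraction=0.0, seed=7,
            paired_chromosomes=("chr4A", "chr4D"),
        )
        a = [g for g in genes if g.chromosome == "chr4A"]
        d = [g for g in genes if g.chromosome == "chr4D"]
        assert intersect_homoeologues(a, d, homo) == []

    def test_truth_coverage_reflects_deletions(self):
        genes, _, values = simulate_gene_models(SMALL_SPEC, density=2.0, seed=8)
        for g in genes:
            if g.start >= 10_000_000 and g.end <= 16_000_000:
                assert values[g.gene_id] == 0.0
            elif g.end <= 10_000_000 or g.start >= 16_000_000:
                assert values[g.gene_id] == 1.0


class TestMarkerTable:
    def test_closes_loop_with_extent_inference(self):
        """Markers inside the planted group-4 deletion drop out; the anchor
        survives -> distal_not_including_anchor."""
        spec = line_a1_spec()
        obs = simulate_marker_table(spec, PANEL_4AL, "Chr4A", seed=9)
        hyp = infer_deletion_extent(PANEL_4AL, obs, ANCHOR_MARKER)
        assert hyp.classification == "distal_not_including_anchor"

    def test_no_deletion_all_present(self):
        spec = GenomeSpec([ChromosomeSpec("Chr4A", 744_588_157)], [])
        obs = simulate_marker_table(spec, PANEL_4AL, "Chr4A", seed=1)
        assert all(o.call == "present" for o in obs)

    def test_faint_rate_one_reports_faint_same_inference(self):
        spec = line_a1_spec()
        obs = simulate_marker_table(spec, PANEL_4AL, "Chr4A", faint_rate=1.0, seed=2)
        deleted_calls = {o.marker_id: o.call for o in obs}
        assert deleted_calls["TC37b"] == "faint"
        hyp = infer_deletion_extent(PANEL_4AL, obs, ANCHOR_MARKER)
        assert hyp.classification == "distal_not_including_anchor"


class TestGranuleImage:
    def test_deterministic(self):
        a, ta = simulate_granule_image(30, 0.5, seed=11)
        b, tb = simulate_granule_image(30, 0.5, seed=11)
        assert np.array_equal(a.pixels, b.pixels)
        pd.testing.assert_frame_equal(ta, tb)

    def test_exact_class_counts(self):
        _, truth = simulate_granule_image(40, 0.3, seed=12)
        assert (truth["class"] == "small").sum() == 12

    def test_zero_granules_blank(self):
        img, truth = simulate_granule_image(0, 0.5, seed=13, canvas_shape=(64, 64))
        assert truth.empty
        assert img.pixels.std() < 10  # noise only

    def test_canvas_too_small_raises(self):
        with pytest.raises(ValueError, match="canvas too small"):
            simulate_granule_image(50, 0.0, seed=14, canvas_shape=(80, 80))


class TestEndToEndRecovery:
    def test_planted_deletions_recovered_with_exact_boundaries(self):
        """At depth 100 with 2% residual signal, every planted deletion of at
        least four bins is recovered at exact bin boundaries in >=99% of
        seeded replicates; no sub-threshold run is called noise-free."""
        params = CallerParams()
        exact = 0
        n_rep = 50
        for seed in range(n_rep):
            mut, wt, truth = simulate_coverage_pair(
                SMALL_SPEC, CoverageSimParams(mean_reads_per_bin=100, seed=seed)
            )
            calls = call_deletions(normalize_coverage(mut, wt), params)
            if [(c.chromosome, c.start, c.end) for c in calls] == [
                ("chr1", 10_000_000, 16_000_000)
            ]:
                exact += 1
        assert exact >= 0.99 * n_rep

    def test_short_runs_never_called_noise_free(self):
        spec = GenomeSpec(
            [ChromosomeSpec("chr1", 40_000_000)],
            [("chr1", 10_000_000, 13_000_000)],  # 3 bins < min_low_run
        )
        p = CoverageSimParams(capture_efficiency_sd=0.0, residual_in_deletion=0.0, seed=1)
        mut, wt, _ = simulate_coverage_pair(spec, p)
        assert call_deletions(normalize_coverage(mut, wt), CallerParams()) == []
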