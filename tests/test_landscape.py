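"""Coverage statistics against per-base oracles; genome tabulation arithmetic."""

import numpy as np
import pytest

from telandscape.datasets import flax_te_counts, flax_te_superfamily_order
from telandscape.intervals import GenomicInterval
from telandscape.landscape import (
    binned_coverage,
    genome_te_table,
    proportional_coverage,
    scaffold_correlation,
    superfamily_tracks,
)
from telandscape.model import TEAnnotation


def brute_coverage(spans, region_start, region_end):
    hit = np.zeros(region_end - region_start, dtype=bool)
    for s, e in spans:
        lo, hi = max(s, region_start), min(e, region_end)
        if lo < hi:
            hit[lo - region_start : hi - region_start] = True
    return hit.sum() / (region_end - region_start)


def _ivs(spans, scaffold="s"):
    return [GenomicInterval(scaffold, s, e) for s, e in spans]


class TestProportionalCoverage:
    def test_half_covered_region(self):
        region = GenomicInterval("s", 0, 100)
        assert proportional_coverage(_ivs([(0, 50)]), region) == 0.5

    def test_overlapping_intervals_are_union_merged(self):
        region = GenomicInterval("s", 0, 100)
        assert proportional_coverage(_ivs([(10, 30), (20, 50)]), region) == 0.40

    def test_no_intervals_zero(self):
        assert proportional_coverage([], GenomicInterval("s", 0, 10)) == 0.0

    def test_nested_duplicated_intervals_never_exceed_one(self):
        region = GenomicInterval("s", 0, 50)
        spans = _ivs([(0, 50), (0, 50), (10, 20), (5, 45)])
        assert proportional_coverage(spans, region) == 1.0

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 10))
            spans = [
                (int(s), int(s + l))
                for s, l in zip(rng.integers(0, 900, n), rng.integers(1, 200, n))
            ]
            start = int(rng.integers(0, 500))
            end = start + int(rng.integers(1, 500))
            got = proportional_coverage(_ivs(spans), GenomicInterval("s", start, end))
            assert got == pytest.approx(brute_coverage(spans, start, end))


class TestBinnedCoverage:
    def test_one_mb_scaffold_has_twenty_50kb_bins(self):
        track = binned_coverage([], "s", 1_000_000)
        assert len(track.values) == 20

    def test_partial_final_bin_normalized_by_true_length(self):
        # 120 kb scaffold: bins 50k, 50k, 20k; last bin half covered
        track = binned_coverage(
            _ivs([(110_000, 120_000)]), "s", 120_000
        )
        assert len(track.values) == 3
        assert track.values[2] == pytest.approx(10_000 / 20_000)

    def test_bin_values_times_lengths_conserve_union_bp(self, rng):
        spans = [
            (int(s), int(s + l))
            for s, l in zip(
                rng.integers(0, 140_000, 30), rng.integers(100, 9_000, 30)
            )
        ]
        spans = [(s, min(e, 145_000)) for s, e in spans]
        track = binned_coverage(_ivs(spans), "s", 145_000)
        union_bp = brute_coverage(spans, 0, 145_000) * 145_000
        assert track.covered_bp() == pytest.approx(union_bp)

    def test_uniform_planting_keeps_every_bin_near_target(self, rng):
        spans = []
        for bin_start in range(0, 500_000, 1_000):
            if rng.random() < 0.10:
                spans.append((bin_start, bin_start + 1_000))
        track = binned_coverage(_ivs(spans), "s", 500_000)
        assert all(0.02 <= v <= 0.22 for v in track.values)

    def test_superfamily_tracks_share_one_bin_grid(self, small_genome):
        assembly, truth = small_genome
        scaffold_id = next(iter(assembly.scaffolds))
        tracks = superfamily_tracks(
            truth.te_annotations(), scaffold_id, assembly.scaffolds[scaffold_id]
        )
        lengths = {len(t.values) for t in tracks.values()}
        assert len(lengths) == 1


class TestScaffoldCorrelation:
    def test_collinear_pairs_give_minus_one(self):
        result = scaffold_correlation([0.1, 0.5, 0.9], [0.9, 0.5, 0.1])
        assert result.r == pytest.approx(-1.0)

    def test_complementary_planting_strongly_negative(self, rng):
        te = rng.random(20)
        gene = 0.9 - te * 0.8 + rng.normal(0, 0.02, 20)
        result = scaffold_correlation(gene, te)
        assert result.r < -0.8

    def test_shuffled_pairing_destroys_correlation(self, rng):
        te = np.linspace(0, 1, 60)
        gene = 1 - te
        shuffled = rng.permutation(gene)
        result = scaffold_correlation(shuffled, te)
        assert abs(result.r) < 0.35

    def test_degenerate_inputs_not_computable(self):
        assert not scaffold_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]).computable
        assert not scaffold_correlation([0.1, 0.2], [0.2, 0.1]).computable


class TestGenomeTable:
    def test_share_percentages_from_counts(self):
        counts = {"Copia": (89_951, 29_594_882), "Gypsy": (72_626, 25_123_127)}
        # shares computed within this two-superfamily universe
        table = genome_te_table(None, 318_250_901, counts=counts).set_index(
            "superfamily"
        )
        total_n = 89_951 + 72_626
        assert table.loc["Copia", "pct_of_matches"] == round(
            100 * 89_951 / total_n, 2
        )
        assert table.loc["Copia", "pct_of_genome"] == 9.30
        assert table.loc["Gypsy", "pct_of_genome"] == 7.89

    def test_full_flax_counts_reproduce_published_percentages(self):
        counts, assembly_bp = flax_te_counts()
        table = genome_te_table(
            None, assembly_bp, counts=counts,
            superfamily_order=flax_te_superfamily_order(),
        ).set_index("superfamily")
        assert table.loc["Copia", "pct_of_matches"] == 38.31
        assert table.loc["Copia", "pct_of_te_bp"] == 40.08
        assert table.loc["Gypsy", "pct_of_te_bp"] == 34.02
        assert table.loc["L1", "pct_of_matches"] == 11.77
        assert table.loc["TOTAL", "n_matches"] == 234_783
        assert table.loc["TOTAL", "bp_occupied"] == 73_842_114

    def test_empty_superfamily_keeps_zero_row(self):
        counts = {"Copia": (10, 1000)}
        table = genome_te_table(
            None, 10_000, counts=counts, superfamily_order=["Copia", "Gypsy"]
        ).set_index("superfamily")
        assert table.loc["Gypsy", "n_matches"] == 0
        assert table.loc["Gypsy", "pct_of_matches"] == 0.00

    def test_annotation_input_union_merges_nested_hits(self):
        tes = [
            TEAnnotation(GenomicInterval("s", 0, 100), "Copia"),
            TEAnnotation(GenomicInterval("s", 10, 50), "Copia"),
        ]
        table = genome_te_table(tes, 1_000).set_index("superfamily")
        assert table.loc["Copia", "bp_occupied"] == 100
        assert table.loc["Copia", "n_matches"] == 2
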