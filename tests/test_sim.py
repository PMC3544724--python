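"""Synthetic-genome generator: determinism, truth completeness, K2P process."""

import numpy as np
import pytest

from telandscape.align import count_substitution_types, pairwise_identity
from telandscape.dating import analyze_ltr_pair
from telandscape.sim import (
    RegimeSpec,
    build_te_library,
    default_regime,
    mutate_ltr_pair,
    plant_sequences,
    random_sequence,
    sample_ests,
    simulate_genome,
    simulate_ltr_cohort,
    simulate_scaffold,
)


class TestLibrary:
    def test_ltr_template_length_is_5_3_kb_at_defaults(self):
        lib = build_te_library(4, {"Copia": 1.0}, seed=0)
        for template in lib.values():
            assert template.length == 2 * 400 + 4500 == 5300
            assert template.is_ltr
            # left and right LTR blocks identical at construction
            assert template.sequence[:400] == template.sequence[-400:]

    def test_same_seed_identical_library(self):
        a = build_te_library(8, seed=5)
        b = build_te_library(8, seed=5)
        assert {f: t.sequence for f, t in a.items()} == {
            f: t.sequence for f, t in b.items()
        }

    def test_families_within_a_superfamily_are_far_below_80pct_identity(self):
        lib = build_te_library(3, {"Copia": 1.0}, ltr_length=100,
                               internal_length=400, seed=7)
        seqs = [t.sequence for t in lib.values()]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) < 0.8

    def test_non_positive_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_te_library(2, ltr_length=0)


class TestK2PProcess:
    def test_zero_divergence_gives_identical_copies(self):
        tpl = random_sequence(500, np.random.default_rng(1))
        left, right = mutate_ltr_pair(tpl, 0.0, seed=2)
        assert left == right == tpl

    def test_planted_distance_recovered_within_sampling_error(self):
        """K estimates over 30 replicate 4-kb pairs centre on the planted
        0.03 within 3 standard errors of the replicate mean."""
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(30):
            tpl = random_sequence(4_000, rng)
            left, right = mutate_ltr_pair(tpl, 0.03, seed=rng)
            k2p, _ = analyze_ltr_pair(left, right)
            estimates.append(k2p.K)
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 0.03) < 3 * se

    def test_kappa_2_yields_equal_transition_transversion_counts(self):
        """With rate ratio kappa=2 but two transversion channels, observed
        transition and transversion counts are approximately equal."""
        rng = np.random.default_rng(3)
        tpl = random_sequence(60_000, rng)
        left, right = mutate_ltr_pair(tpl, 0.1, kappa=2.0, seed=rng)
        ts, tv, _ = count_substitution_types(list(zip(left, right)))
        assert 0.8 < ts / tv < 1.25

    def test_saturating_divergence_raises(self):
        tpl = random_sequence(100, np.random.default_rng(0))
        with pytest.raises(ValueError, match="[Ss]atur"):
            mutate_ltr_pair(tpl, 10.0, seed=1)


class TestScaffoldSimulation:
    def test_gene_rich_realizes_te_target_within_tolerance(self):
        lib = build_te_library(6, seed=21)
        spec = RegimeSpec("gene_rich", 1_000_000, 0.05, 0.60)
        _, truth = simulate_scaffold(spec, lib, seed=22)
        te_bp = sum(r.annotation.interval.length for r in truth.te_records)
        assert 0.04 <= te_bp / 1_000_000 <= 0.06

    def test_gypsy_heavy_mix_dominates_truth_bp(self):
        lib = build_te_library(4, {"Gypsy": 0.8, "Copia": 0.2}, seed=3)
        spec = RegimeSpec(
            "te_rich", 400_000, 0.5, 0.05,
            superfamily_mix={"Gypsy": 0.8, "Copia": 0.2},
        )
        _, truth = simulate_scaffold(spec, lib, seed=4)
        bp = truth.te_bp_by_superfamily()
        assert bp["Gypsy"] > bp["Copia"]

    def test_zero_te_coverage_emits_no_te(self, small_library):
        spec = RegimeSpec("gene_rich", 50_000, 0.0, 0.2)
        _, truth = simulate_scaffold(spec, small_library, seed=5)
        assert truth.te_records == []

    def test_infeasible_combined_coverage_rejected(self):
        with pytest.raises(ValueError):
            RegimeSpec("balanced", 100_000, 0.6, 0.5)

    def test_genes_never_overlap_genes_and_tes_never_overlap_tes(self, small_genome):
        _, truth = small_genome
        for records, key in [
            (truth.gene_records, "gene"),
            (truth.te_records, "te"),
        ]:
            by_scaffold = {}
            for rec in records:
                iv = rec.annotation.interval
                by_scaffold.setdefault(iv.scaffold_id, []).append(iv)
            for ivs in by_scaffold.values():
                ivs.sort()
                for a, b in zip(ivs, ivs[1:]):
                    assert a.end <= b.start, f"{key} intervals overlap"

    def test_determinism_identical_seed_identical_genome(self, small_library):
        regimes = [default_regime("balanced", 80_000)]
        a1, t1 = simulate_genome(regimes, te_library=small_library, seed=77)
        a2, t2 = simulate_genome(regimes, te_library=small_library, seed=77)
        assert a1.sequences == a2.sequences
        assert [r.family_id for r in t1.te_records] == [
            r.family_id for r in t2.te_records
        ]

    def test_truth_table_complete(self, small_genome):
        _, truth = small_genome
        assert len(truth.te_annotations()) == len(truth.te_records)
        assert len(truth.gene_annotations()) == len(truth.gene_records)


class TestESTs:
    def test_ests_are_exact_substrings_of_their_sources(
        self, small_genome_with_ests, small_library
    ):
        assembly, truth, ests = small_genome_with_ests
        gene_seqs = {}
        for rec in truth.gene_records:
            iv = rec.annotation.interval
            gene_seqs[rec.annotation.gene_id] = assembly.sequences[iv.scaffold_id][
                iv.start : iv.end
            ]
        for est_id, est_seq in ests.items():
            source = truth.est_origin[est_id]
            source_seq = gene_seqs.get(source) or small_library[source].sequence
            assert est_seq in source_seq

    def test_ests_come_only_from_expressed_features(self, small_genome_with_ests):
        _, truth, ests = small_genome_with_ests
        expressed_genes = truth.expressed_feature_ids()
        for est_id in ests:
            origin = truth.est_origin[est_id]
            if origin.endswith(tuple(f"gene{i:04d}" for i in range(10000))):
                assert origin in expressed_genes

    def test_zero_expressed_fraction_gives_empty_pool(
        self, small_genome, small_library
    ):
        assembly, truth = small_genome
        ests = sample_ests(
            truth, assembly, small_library, expressed_fraction=0.0,
            n_ests=10, seed=1,
        )
        assert ests == {}


class TestLTRCohort:
    def test_planted_age_zero_elements_have_identical_ltrs(self):
        elements, ages = simulate_ltr_cohort([0.0], 3, ltr_length=200,
                                             internal_length=100, seed=6)
        for el in elements:
            assert el.left_ltr_seq == el.right_ltr_seq
            assert ages[el.element_id] == 0.0

    def test_truth_map_covers_every_element(self):
        elements, ages = simulate_ltr_cohort([1.0, 2.0], 4, ltr_length=100,
                                             internal_length=100, seed=8)
        assert len(elements) == 8
        assert {e.element_id for e in elements} == set(ages)


class TestPlanting:
    def test_planted_copies_recoverable_verbatim(self, rng):
        insert = random_sequence(800, rng)
        seq, placements = plant_sequences(
            30_000, [("el1", insert, 3)], seed=rng
        )
        assert len(placements) == 3
        for _, iv in placements:
            assert seq[iv.start : iv.end] == insert
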