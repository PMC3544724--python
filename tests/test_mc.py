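"""Sequential Monte-Carlo machinery: statistic oracle, stopping rule, nulls."""

import numpy as np
import pytest

from telandscape.intervals import GenomicInterval
from telandscape.mc import (
    McUnit,
    mcfdr_schedule,
    overlap_statistic,
    randomize_tes,
    sequential_mc_pvalue,
)
from telandscape.model import GeneAnnotation, TEAnnotation


def _tes(spans, scaffold="s"):
    return [
        TEAnnotation(GenomicInterval(scaffold, s, e), "Copia") for s, e in spans
    ]


def _genes(spans, scaffold="s"):
    return [
        GeneAnnotation(GenomicInterval(scaffold, s, e), f"g{i}")
        for i, (s, e) in enumerate(spans)
    ]


class TestOverlapStatistic:
    UNIT = GenomicInterval("s", 0, 1_000)

    def test_disjoint_tracks_zero(self):
        assert overlap_statistic(_tes([(0, 100)]), _genes([(500, 600)]), self.UNIT) == 0

    def test_simple_overlap(self):
        assert overlap_statistic(_tes([(0, 100)]), _genes([(50, 150)]), self.UNIT) == 50

    def test_matches_per_base_and_count(self, rng):
        for _ in range(200):
            te_spans = [
                (int(s), int(s + l))
                for s, l in zip(rng.integers(0, 900, 6), rng.integers(1, 150, 6))
            ]
            gene_spans = [
                (int(s), int(s + l))
                for s, l in zip(rng.integers(0, 900, 6), rng.integers(1, 150, 6))
            ]
            te_hit = np.zeros(1000, dtype=bool)
            gene_hit = np.zeros(1000, dtype=bool)
            for s, e in te_spans:
                te_hit[s:min(e, 1000)] = True
            for s, e in gene_spans:
                gene_hit[s:min(e, 1000)] = True
            expected = int((te_hit & gene_hit).sum())
            got = overlap_statistic(_tes(te_spans), _genes(gene_spans), self.UNIT)
            assert got == expected


class TestRandomization:
    def test_lengths_preserved_and_inside_unit(self, rng):
        unit = GenomicInterval("s", 0, 10_000)
        tes = _tes([(0, 500), (600, 2_000), (9_000, 9_100)])
        placed = randomize_tes(tes, unit, seed=5)
        assert sorted(iv.length for iv in placed) == [100, 500, 1_400]
        for iv in placed:
            assert 0 <= iv.start and iv.end <= 10_000

    def test_unit_length_te_forced_to_origin(self):
        unit = GenomicInterval("s", 0, 500)
        (placed,) = randomize_tes(_tes([(0, 500)]), unit, seed=1)
        assert (placed.start, placed.end) == (0, 500)

    def test_te_longer_than_unit_rejected(self):
        unit = GenomicInterval("s", 0, 100)
        with pytest.raises(ValueError):
            randomize_tes(_tes([(0, 500)]), unit, seed=1)

    def test_same_seed_identical_draw(self):
        unit = GenomicInterval("s", 0, 10_000)
        tes = _tes([(0, 500), (600, 700)])
        assert randomize_tes(tes, unit, seed=9) == randomize_tes(tes, unit, seed=9)

    def test_null_mean_matches_uniform_placement_expectation(self, rng):
        """E[null overlap] = sum(te_len) * gene_coverage for TEs short
        relative to the unit, within 3 SE over 10,000 draws."""
        unit = GenomicInterval("s", 0, 100_000)
        genes = _genes([(0, 30_000)])  # gene coverage 0.3
        tes = _tes([(0, 100), (200, 350), (400, 480)])  # 330 bp total
        te_lens = [100, 150, 80]
        unit_obj = McUnit.from_tracks("u", tes, genes, unit)
        draws = np.array([unit_obj.sampler(rng) for _ in range(10_000)])
        approx = sum(l * 0.3 for l in te_lens)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - approx) < max(3 * se, 0.02 * approx)


class TestSequentialStopping:
    def test_stopping_rule_and_add_one_estimator(self):
        """A sampler engineered to produce its 20th exceedance on draw 137
        stops there with p = 21/138."""
        exceed_on = set(list(range(1, 20)) + [137])  # 1-based draw indices
        state = {"i": 0}

        def sampler(rng):
            state["i"] += 1
            return 1.0 if state["i"] in exceed_on else -1.0

        result = sequential_mc_pvalue(0.5, sampler, min_samples=100,
                                      exceedance_threshold=20, max_samples=10_000)
        assert result.n_samples == 137
        assert result.n_exceedances == 20
        assert result.stop_reason == "exceedance_threshold"
        assert result.p_estimate == pytest.approx(21 / 138)

    def test_cap_with_zero_exceedances_gives_floor_p(self):
        result = sequential_mc_pvalue(
            10.0, lambda rng: 0.0, min_samples=100,
            exceedance_threshold=20, max_samples=1_000,
        )
        assert result.n_exceedances == 0
        assert result.stop_reason == "cap"
        assert result.p_estimate == pytest.approx(1 / 1001)
        assert 0 < result.p_estimate <= 1

    def test_p_monotone_in_observed_statistic(self, rng):
        draws = rng.normal(size=4_000)
        def make_sampler():
            it = iter(np.tile(draws, 10))
            return lambda _rng: next(it)
        p_low = sequential_mc_pvalue(0.0, make_sampler(), max_samples=4_000).p_estimate
        p_high = sequential_mc_pvalue(1.5, make_sampler(), max_samples=4_000).p_estimate
        assert p_high <= p_low


class TestMcfdr:
    def _null_units(self, n_units, rng):
        units = []
        for i in range(n_units):
            observed = float(rng.normal())
            units.append(
                McUnit(f"u{i}", observed, lambda r: float(r.normal()))
            )
        return units

    def test_single_unit_degenerates_to_sequential_pvalue(self, rng):
        unit = McUnit("u0", 0.0, lambda r: float(r.normal()))
        (result,) = mcfdr_schedule([unit], max_samples=500, seed=3)
        assert result.p_estimate == (result.n_exceedances + 1) / (result.n_samples + 1)
        assert result.p_estimate > 0

    def test_planted_enrichment_rejected_among_null_units(self, rng):
        units = self._null_units(19, rng)
        units.append(McUnit("planted", 50.0, lambda r: float(r.normal())))
        results = mcfdr_schedule(units, max_samples=2_000, seed=7)
        by_id = {r.unit_id: r for r in results}
        assert by_id["planted"].rejected
        n_false = sum(r.rejected for r in results) - 1
        assert n_false <= 1

    def test_all_null_set_rarely_rejects(self, rng):
        results = mcfdr_schedule(
            self._null_units(30, rng), max_samples=1_000, seed=11
        )
        assert sum(r.rejected for r in results) <= 3
        for r in results:
            assert 0 < r.p_estimate <= 1
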