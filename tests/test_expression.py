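"""EST coverage rules and expression summaries."""

import numpy as np
import pytest

from telandscape.expression import (
    ExpressionCall,
    est_hit_positive,
    expression_calls,
    expression_te_correlation,
    match_ests_to_features,
    scaffold_gene_expression,
    superfamily_expression_table,
)
from telandscape.intervals import GenomicInterval
from telandscape.model import AlignmentHit, GeneAnnotation


def _hit(matched, est_len=200, feature="fam1", est="est1"):
    return AlignmentHit(feature, est, matched, 5000, est_len)


class TestCoverageRule:
    def test_70pct_boundary(self):
        assert est_hit_positive(_hit(140))
        assert not est_hit_positive(_hit(139))

    def test_full_length_match_positive_at_any_threshold(self):
        for threshold in (0.1, 0.5, 1.0):
            assert est_hit_positive(_hit(200), est_coverage_threshold=threshold)

    def test_zero_est_length_rejected(self):
        hit = AlignmentHit("f", "e", 0, 100, 0)
        with pytest.raises(ValueError):
            est_hit_positive(hit)

    def test_lowering_threshold_never_decreases_expressed_count(self):
        hits = [
            _hit(matched, est=f"e{i}")
            for i, matched in enumerate([100, 120, 139, 140, 160, 200])
        ]
        previous = -1
        for threshold in (1.0, 0.9, 0.7, 0.5, 0.3):
            calls = expression_calls(["fam1"], hits, est_coverage_threshold=threshold)
            count = calls["fam1"].est_hits
            assert count >= previous
            previous = count


class TestCalls:
    def test_distinct_ests_counted_once_each(self):
        hits = [_hit(200, est="e1"), _hit(200, est="e1"), _hit(200, est="e2")]
        calls = expression_calls(["fam1"], hits)
        assert calls["fam1"].est_hits == 2
        assert calls["fam1"].expressed

    def test_invariant_expressed_iff_hits(self):
        with pytest.raises(ValueError):
            ExpressionCall("f", 0, True)
        with pytest.raises(ValueError):
            ExpressionCall("f", 2, False)


class TestSuperfamilyTable:
    def test_proportions_to_two_decimals(self):
        mapping = {f"c{i}": "Copia" for i in range(819)}
        mapping.update({f"g{i}": "Gypsy" for i in range(263)})
        calls = {}
        for i, fid in enumerate(sorted(f for f in mapping if f.startswith("c"))):
            hits = 1 if i < 77 else 0
            calls[fid] = ExpressionCall(fid, hits, hits >= 1)
        for i, fid in enumerate(sorted(f for f in mapping if f.startswith("g"))):
            hits = 1 if i < 20 else 0
            calls[fid] = ExpressionCall(fid, hits, hits >= 1)
        table = superfamily_expression_table(mapping, calls).set_index("superfamily")
        assert table.loc["Copia", "pct_expressed"] == 9.40
        assert table.loc["Gypsy", "pct_expressed"] == 7.60

    def test_zero_expressed_gives_zero_percent(self):
        mapping = {"a": "Mutator", "b": "Mutator"}
        calls = {fid: ExpressionCall(fid, 0, False) for fid in mapping}
        table = superfamily_expression_table(mapping, calls)
        assert table["pct_expressed"].tolist() == [0.00]

    def test_pure_function_of_calls_under_permutation(self):
        mapping = {"a": "Copia", "b": "Copia", "c": "Gypsy"}
        calls = {
            "a": ExpressionCall("a", 1, True),
            "b": ExpressionCall("b", 0, False),
            "c": ExpressionCall("c", 3, True),
        }
        t1 = superfamily_expression_table(mapping, calls)
        reordered = dict(reversed(list(mapping.items())))
        t2 = superfamily_expression_table(reordered, calls)
        assert t1.equals(t2)


class TestScaffoldExpression:
    def _genes(self, scaffold, n):
        return [
            GeneAnnotation(
                GenomicInterval(scaffold, i * 1000, i * 1000 + 500), f"{scaffold}_g{i}"
            )
            for i in range(n)
        ]

    def test_fraction_of_expressed_genes(self):
        genes = self._genes("s1", 10)
        calls = {
            g.gene_id: ExpressionCall(g.gene_id, 1 if i < 4 else 0, i < 4)
            for i, g in enumerate(genes)
        }
        assert scaffold_gene_expression(genes, calls) == {"s1": 0.4}

    def test_constructed_anticorrelation_detected(self, rng):
        """Expression planted only on low-TE scaffolds gives a strongly
        negative correlation across 20 scaffolds."""
        gene_expr = {}
        te_cov = {}
        for i in range(20):
            te = i / 20
            te_cov[f"s{i}"] = te
            gene_expr[f"s{i}"] = (0.8 if te < 0.4 else 0.1) + rng.normal(0, 0.03)
        result = expression_te_correlation(gene_expr, te_cov)
        assert result.computable
        assert result.r < -0.5

    def test_zero_variance_reported_not_computable(self):
        gene_expr = {f"s{i}": 1.0 for i in range(5)}
        te_cov = {f"s{i}": i / 5 for i in range(5)}
        result = expression_te_correlation(gene_expr, te_cov)
        assert not result.computable
        assert result.r is None


class TestEndToEndRecovery:
    def test_exact_substring_ests_recover_truth_expression_exactly(
        self, small_library
    ):
        """Precision and recall of expression calls are both 1 on an
        error-free EST pool: called expressed sets equal truth for genes and
        families with sampled ESTs. TE-gene overlap is disabled so no
        feature shares sequence with another (a TE inside a gene would make
        an EST from either legitimately hit both)."""
        from telandscape.sim import default_regime, sample_ests, simulate_genome

        regimes = [default_regime(k, 120_000) for k in ("balanced", "gene_rich")]
        assembly, truth = simulate_genome(
            regimes, te_library=small_library, seed=41,
            allow_te_gene_overlap=False,
        )
        ests = sample_ests(
            truth, assembly, small_library, expressed_fraction=0.4,
            n_ests=60, length_range=(150, 400), seed=43,
        )
        feature_seqs = {
            fid: t.sequence for fid, t in small_library.items()
        }
        for rec in truth.gene_records:
            iv = rec.annotation.interval
            feature_seqs[rec.annotation.gene_id] = assembly.sequences[
                iv.scaffold_id
            ][iv.start : iv.end]
        hits = match_ests_to_features(feature_seqs, ests)
        calls = expression_calls(feature_seqs, hits)
        called = {fid for fid, c in calls.items() if c.expressed}
        with_est = set(truth.est_origin.values())
        # recall: every feature an EST was sampled from is called expressed
        assert with_est <= called
        # precision: no called feature lacks a sampled EST, except features
        # that legitimately contain an EST substring (duplicated library
        # segments do not occur: templates are independent random sequences)
        assert called == with_est
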