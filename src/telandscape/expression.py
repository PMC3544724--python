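"""EST-based expression proxies for TE families and genes.

An EST hit against a feature counts as positive only when at least 70% of
the *EST* sequence is matched (coverage is measured on the EST, not on the
feature it hits). A feature is putatively expressed when at least one
distinct EST hits it positively; multiple hits of one EST to one feature
are deduplicated by EST id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import find_copies
from .landscape import CorrelationResult, scaffold_correlation
from .model import AlignmentHit, GeneAnnotation

logger = logging.getLogger(__name__)

EST_COVERAGE_THRESHOLD = 0.70


@dataclass
class ExpressionCall:
    feature_id: str
    est_hits: int
    expressed: bool

    def __post_init__(self) -> None:
        if self.est_hits < 0:
            raise ValueError("est_hits must be >= 0")
        if self.expressed != (self.est_hits >= 1):
            raise ValueError("expressed must equal (est_hits >= 1)")


def est_hit_positive(
    hit: AlignmentHit,
    est_coverage_threshold: float = EST_COVERAGE_THRESHOLD,
    est_side: str = "target",
) -> bool:
    """Positive iff matched bases cover ≥ threshold of the EST length.

    ``est_side`` names the side of the hit holding the EST ("target" by
    default: feature-vs-EST-pool searches put the EST in the target slot).
    """
    est_length = hit.target_length if est_side == "target" else hit.query_length
    if est_length <= 0:
        raise ValueError("EST length must be positive")
    return hit.matched_bases >= est_coverage_threshold * est_length


def expression_calls(
    feature_ids: Iterable[str],
    hits: Iterable[AlignmentHit],
    est_coverage_threshold: float = EST_COVERAGE_THRESHOLD,
    est_side: str = "target",
    dedupe_ests: bool = True,
) -> dict[str, ExpressionCall]:
    """One call per feature from a feature-vs-EST hit table.

    The feature is the non-EST side of each hit. Each distinct EST counts
    once per feature (configurable).
    """
    per_feature: dict[str, set[str] | list[str]] = {
        fid: set() if dedupe_ests else [] for fid in feature_ids
    }
    for hit in hits:
        feature = hit.query_id if est_side == "target" else hit.target_id
        est = hit.target_id if est_side == "target" else hit.query_id
        if feature not in per_feature:
            continue
        if est_hit_positive(hit, est_coverage_threshold, est_side):
            if dedupe_ests:
                per_feature[feature].add(est)
            else:
                per_feature[feature].append(est)
    return {
        fid: ExpressionCall(fid, len(ests), len(ests) >= 1)
        for fid, ests in per_feature.items()
    }


def match_ests_to_features(
    feature_sequences: dict[str, str],
    ests: dict[str, str],
    k: int = 15,
) -> list[AlignmentHit]:
    """Feature-vs-EST hits via the internal seed-and-extend matcher.

    Each EST is searched inside each feature sequence; hits are emitted
    with the feature as query and the EST as target (so matched bases are
    measured along the EST, ready for the 70% coverage rule).
    """
    hits: list[AlignmentHit] = []
    for feature_id, feature_seq in feature_sequences.items():
        for est_id, est_seq in ests.items():
            for sub in find_copies(
                est_seq, feature_seq, target_id=feature_id, query_id=est_id, k=k
            ):
                hits.append(
                    AlignmentHit(
                        query_id=feature_id,
                        target_id=est_id,
                        matched_bases=sub.matched_bases,
                        query_length=len(feature_seq),
                        target_length=len(est_seq),
                        gap_count=sub.gap_count,
                        mismatch_count=sub.mismatch_count,
                    )
                )
    return hits


def superfamily_expression_table(
    family_superfamilies: dict[str, str],
    calls: dict[str, ExpressionCall],
) -> pd.DataFrame:
    """Per-superfamily expression summary.

    Rows: superfamily, number of families, number expressed, proportion
    expressed as a percentage to 2 decimals. Superfamilies without families
    are omitted (with a warning) since a proportion is undefined there.
    Output is invariant to input ordering.
    """
    rows = []
    superfamilies = sorted(set(family_superfamilies.values()))
    for sf in superfamilies:
        members = sorted(
            fid for fid, s in family_superfamilies.items() if s == sf
        )
        if not members:
            logger.warning("superfamily %s has no families; row omitted", sf)
            continue
        missing = [fid for fid in members if fid not in calls]
        if missing:
            raise ValueError(f"families without expression calls: {missing}")
        n_expressed = sum(1 for fid in members if calls[fid].expressed)
        rows.append(
            {
                "superfamily": sf,
                "n_families": len(members),
                "n_expressed": n_expressed,
                "pct_expressed": round(100.0 * n_expressed / len(members), 2),
            }
        )
    return pd.DataFrame(rows)


def scaffold_gene_expression(
    genes: Sequence[GeneAnnotation],
    calls: dict[str, ExpressionCall],
) -> dict[str, float]:
    """Fraction of genes called expressed, per scaffold.

    Scaffolds without genes simply produce no entry (logged upstream when a
    caller expects one)."""
    per_scaffold: dict[str, list[str]] = {}
    for gene in genes:
        per_scaffold.setdefault(gene.interval.scaffold_id, []).append(gene.gene_id)
    out = {}
    for scaffold_id, gene_ids in per_scaffold.items():
        called = [calls[g].expressed for g in gene_ids if g in calls]
        if not called:
            logger.warning("scaffold %s: no genes with calls; excluded", scaffold_id)
            continue
        out[scaffold_id] = sum(called) / len(called)
    return out


def expression_te_correlation(
    gene_expression_fraction: dict[str, float],
    te_coverage: dict[str, float],
) -> CorrelationResult:
    """Pearson correlation of per-scaffold gene-expression fraction against
    TE proportional coverage (the expression-vs-TE landscape statistic)."""
    scaffolds = sorted(set(gene_expression_fraction) & set(te_coverage))
    return scaffold_correlation(
        [gene_expression_fraction[s] for s in scaffolds],
        [te_coverage[s] for s in scaffolds],
    )


def calls_to_frame(calls: dict[str, ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"feature_id": c.feature_id, "est_hits": c.est_hits, "expressed": c.expressed}
            for c in sorted(calls.values(), key=lambda c: c.feature_id)
        ]
    )
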