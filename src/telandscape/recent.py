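"""Recent LTR insertions: selection, exact re-mapping, and gene proximity.

Elements whose two LTRs are 100% identical inserted too recently to have
accumulated substitutions; mapping them back to the assembly at full-length
perfect identity (no gaps, no mismatches) locates the population of recent
insertion sites, and the distance of each site to its nearest predicted
gene summarises how recent activity relates to coding regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .model import AlignmentHit, GeneAnnotation, LTRElement

logger = logging.getLogger(__name__)

RELAXED_COVERAGE = 0.80
DISTANCE_BINS = (
    ("0-1000", 0, 1_000),
    ("1001-2000", 1_001, 2_000),
    ("2001-3000", 2_001, 3_000),
    ("3001-4000", 3_001, 4_000),
    ("4001-5000", 4_001, 5_000),
    (">5000", 5_001, None),
)


def select_recent(elements: Iterable[LTRElement]) -> list[LTRElement]:
    """Elements with exactly 100% intra-element LTR similarity."""
    selected = []
    for element in elements:
        if element.ltr_similarity_pct is None:
            raise ValueError(
                f"element {element.element_id} has no LTR similarity computed"
            )
        if element.ltr_similarity_pct == 100.0:
            selected.append(element)
    return selected


def recent_counts_by_class(elements: Iterable[LTRElement]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for element in elements:
        counts[element.internal_class] = counts.get(element.internal_class, 0) + 1
    return counts


def map_exact_copies(
    query_length: int,
    hits: Iterable[AlignmentHit],
    relaxed: bool = False,
    relaxed_coverage: float = RELAXED_COVERAGE,
) -> list[AlignmentHit]:
    """Filter element-vs-assembly hits to insertion sites.

    Exact mode keeps only full-length perfect hits (matched bases equal to
    the query length, zero gaps, zero mismatches). Relaxed mode keeps hits
    whose matched bases cover at least ``relaxed_coverage`` of the query,
    so the exact site set is always a subset of the relaxed one.
    """
    sites = []
    for hit in hits:
        if relaxed:
            if hit.matched_bases >= relaxed_coverage * query_length:
                sites.append(hit)
        elif (
            hit.matched_bases == query_length
            and hit.gap_count == 0
            and hit.mismatch_count == 0
        ):
            sites.append(hit)
    return sites


def nearest_gene_distance(
    site: GenomicInterval, genes: Sequence[GeneAnnotation]
) -> Optional[int]:
    """Gap bp to the nearest gene on the site's scaffold (0 when
    overlapping); None when the scaffold carries no gene."""
    best = None
    for gene in genes:
        if gene.interval.scaffold_id != site.scaffold_id:
            continue
        d = site.distance_bp(gene.interval)
        if best is None or d < best:
            best = d
    return best


def bin_of_distance(distance: int) -> str:
    for label, lo, hi in DISTANCE_BINS:
        if hi is None or distance <= hi:
            return label
    raise AssertionError("unreachable")


@dataclass
class SiteRecord:
    element_id: str
    site: GenomicInterval
    distance_bp: Optional[int]
    bin: str


def site_records(
    sites: Iterable[AlignmentHit], genes: Sequence[GeneAnnotation]
) -> list[SiteRecord]:
    records = []
    for hit in sites:
        if hit.target_interval is None:
            raise ValueError(f"site hit {hit.query_id} lacks a target interval")
        distance = nearest_gene_distance(hit.target_interval, genes)
        if distance is None:
            logger.warning(
                "scaffold %s has no genes; site %s assigned to the >5000 bin",
                hit.target_interval.scaffold_id, hit.query_id,
            )
            label = ">5000"
        else:
            label = bin_of_distance(distance)
        records.append(SiteRecord(hit.query_id, hit.target_interval, distance, label))
    return records


def nearest_gene_bins(counts_or_records) -> pd.DataFrame:
    """Distance-bin frequency table with proportions to 2 decimals.

    Accepts either a list of :class:`SiteRecord` or a sequence of bin
    counts in canonical bin order. Proportions sum to 100 within rounding.
    """
    labels = [label for label, _, _ in DISTANCE_BINS]
    counts_or_records = list(counts_or_records)
    if not counts_or_records:
        counts_or_records = [0] * len(labels)
    if all(isinstance(x, SiteRecord) for x in counts_or_records):
        counts = {label: 0 for label in labels}
        for record in counts_or_records:
            counts[record.bin] += 1
        values = [counts[label] for label in labels]
    else:
        values = list(counts_or_records)
        if len(values) != len(labels):
            raise ValueError(f"expected {len(labels)} bin counts, got {len(values)}")
    total = sum(values)
    return pd.DataFrame(
        {
            "distance_bin": labels,
            "n_elements": values,
            "pct_of_elements": [
                round(100.0 * v / total, 2) if total else 0.0 for v in values
            ],
        }
    )
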