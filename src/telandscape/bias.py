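"""Superfamily-specific insertion-bias tests around genes.

A TE is assigned to a region by the midpoint rule: the element counts as
"in" the region iff the midpoint of its interval (start + floor(length/2),
half-open containment) lies inside it. Regions are:

* ``gene_body`` — the union of gene intervals;
* ``flank_1kb`` / ``flank_5kb`` — up to 1 kb (5 kb) upstream and downstream
  of each gene, union-merged across neighbouring genes and with gene bodies
  excluded. The 5-kb flank is the full 0–5,000 bp zone and therefore
  contains the 1-kb zone.

For each superfamily, a 2×2 Pearson chi-square (df = 1, no continuity
correction) compares its in-region fraction against all other TEs pooled.
Significance tiers follow the conventional Bonferroni-corrected display
thresholds p < 5e-3 (single) and p < 5e-4 (double).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, subtract_merged
from .model import GeneAnnotation, TEAnnotation

REGION_KINDS = ("gene_body", "flank_1kb", "flank_5kb")
SINGLE_TIER_P = 5e-3
DOUBLE_TIER_P = 5e-4


def region_spans(
    genes: Iterable[GeneAnnotation],
    region_kind: str,
    scaffold_length: int | None = None,
    flank_bp: int | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Merged region spans per scaffold for one region kind."""
    if region_kind not in REGION_KINDS and flank_bp is None:
        raise ValueError(f"unknown region kind {region_kind!r}")
    if flank_bp is None:
        flank_bp = {"gene_body": 0, "flank_1kb": 1_000, "flank_5kb": 5_000}[region_kind]

    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        iv = gene.interval
        by_scaffold.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))

    out = {}
    for scaffold_id, spans in by_scaffold.items():
        bodies = merge_intervals(spans)
        if region_kind == "gene_body":
            out[scaffold_id] = bodies
            continue
        flanks = []
        for start, end in bodies:
            lo = max(0, start - flank_bp)
            hi = end + flank_bp
            if scaffold_length is not None:
                hi = min(hi, scaffold_length)
            flanks.append((lo, hi))
        out[scaffold_id] = subtract_merged(merge_intervals(flanks), bodies)
    return out


def _midpoint_in_spans(midpoint: int, spans: list[tuple[int, int]]) -> bool:
    starts = [s for s, _ in spans]
    idx = np.searchsorted(starts, midpoint, side="right") - 1
    return idx >= 0 and spans[idx][0] <= midpoint < spans[idx][1]


def count_hits_in_region(
    tes: Iterable[TEAnnotation],
    genes: Iterable[GeneAnnotation],
    region_kind: str,
    flank_bp: int | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Midpoint counts per superfamily: ``(in_region, total)`` maps.

    Totals count every TE on the analysed scaffolds; in-region counts the
    subset whose midpoint lies in the region. Midpoints partition: summing
    ``in_region`` over superfamilies gives the total number of TEs in the
    region.
    """
    spans = region_spans(genes, region_kind, flank_bp=flank_bp)
    in_region: dict[str, int] = {}
    totals: dict[str, int] = {}
    for te in tes:
        sf = te.superfamily
        totals[sf] = totals.get(sf, 0) + 1
        scaffold_spans = spans.get(te.interval.scaffold_id, [])
        if scaffold_spans and _midpoint_in_spans(te.interval.midpoint, scaffold_spans):
            in_region[sf] = in_region.get(sf, 0) + 1
    return in_region, totals


@dataclass
class BiasResult:
    superfamily: str
    region: str
    in_region: int
    total: int
    others_in_region: int
    others_total: int
    chi2: Optional[float]
    p: Optional[float]
    tier: str  # ns | single | double | not-computable
    direction: str  # over | under | none

    @property
    def pct_of_region_hits(self) -> float:
        region_total = self.in_region + self.others_in_region
        return 100.0 * self.in_region / region_total if region_total else 0.0

    @property
    def pct_of_genome_hits(self) -> float:
        genome_total = self.total + self.others_total
        return 100.0 * self.total / genome_total if genome_total else 0.0


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for ``[[a, b], [c, d]]``, df = 1, uncorrected."""
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bias_chi_square(
    superfamily: str,
    region: str,
    in_region: int,
    total: int,
    others_in_region: int,
    others_total: int,
) -> BiasResult:
    """Test one superfamily's in-region fraction against all other TEs.

    A zero margin (no TE of the superfamily, no other TEs, or an empty /
    saturated region overall) yields a not-computable result rather than a
    division error.
    """
    a, b = in_region, total - in_region
    c, d = others_in_region, others_total - others_in_region
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        return BiasResult(
            superfamily, region, in_region, total, others_in_region, others_total,
            chi2=None, p=None, tier="not-computable", direction="none",
        )
    chi2, p = chi2_2x2(a, b, c, d)
    own_fraction = a / (a + b)
    other_fraction = c / (c + d)
    direction = "over" if own_fraction > other_fraction else (
        "under" if own_fraction < other_fraction else "none"
    )
    tier = "double" if p < DOUBLE_TIER_P else ("single" if p < SINGLE_TIER_P else "ns")
    return BiasResult(
        superfamily, region, in_region, total, others_in_region, others_total,
        chi2=chi2, p=p, tier=tier, direction=direction,
    )


def proximity_bias_table(
    tes: Sequence[TEAnnotation],
    genes: Sequence[GeneAnnotation],
    regions: Sequence[str] = REGION_KINDS,
) -> list[BiasResult]:
    """All superfamily × region bias tests on one annotation set."""
    results = []
    for region in regions:
        in_region, totals = count_hits_in_region(tes, genes, region)
        all_in = sum(in_region.values())
        all_total = sum(totals.values())
        for sf in sorted(totals):
            results.append(
                bias_chi_square(
                    sf,
                    region,
                    in_region.get(sf, 0),
                    totals[sf],
                    all_in - in_region.get(sf, 0),
                    all_total - totals[sf],
                )
            )
    return results


def bias_to_frame(results: Iterable[BiasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "superfamily": r.superfamily,
                "region": r.region,
                "in_region": r.in_region,
                "total": r.total,
                "pct_of_region_hits": round(r.pct_of_region_hits, 2),
                "pct_of_genome_hits": round(r.pct_of_genome_hits, 2),
                "chi2": r.chi2,
                "p": r.p,
                "tier": r.tier,
                "direction": r.direction,
            }
            for r in results
        ]
    )
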