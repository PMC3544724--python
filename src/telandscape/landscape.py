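"""Windowed and per-scaffold proportional coverage, correlations, and
genome-wide TE tabulation.

Proportional coverage of a feature set over a region is the fraction of the
region's bases covered by the *union* of the feature intervals — overlapping
or nested annotations are merged first, so a fraction can never exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, merge_intervals, total_bp
from .model import Assembly, TEAnnotation
from .taxonomy import class_of, order_of

#: Window size for binned coverage tracks (bp).
DEFAULT_BIN_SIZE = 50_000
#: Minimum scaffold length admitted to cross-scaffold correlation analyses.
DEFAULT_MIN_SCAFFOLD_BP = 1_000_000


def _intervals_of(features: Iterable) -> list[GenomicInterval]:
    out = []
    for f in features:
        out.append(f if isinstance(f, GenomicInterval) else f.interval)
    return out


def proportional_coverage(features: Iterable, region: GenomicInterval) -> float:
    """Fraction of ``region`` covered by the union of the features.

    Features on other scaffolds are ignored; a zero-length region is a
    caller error (GenomicInterval already forbids it, but a plain tuple
    region would not be).
    """
    if region.length <= 0:
        raise ValueError("coverage of a zero-length region is undefined")
    clipped = []
    for iv in _intervals_of(features):
        if iv.scaffold_id != region.scaffold_id:
            continue
        lo = max(iv.start, region.start)
        hi = min(iv.end, region.end)
        if lo < hi:
            clipped.append((lo, hi))
    return total_bp(merge_intervals(clipped)) / region.length


@dataclass
class WindowTrack:
    """Per-bin proportional coverage along one scaffold."""

    scaffold_id: str
    bin_size: int
    values: list[float]
    feature_set: str = ""
    scaffold_length: int = 0

    def __post_init__(self) -> None:
        expected = -(-self.scaffold_length // self.bin_size) if self.scaffold_length else len(self.values)
        if self.scaffold_length and len(self.values) != expected:
            raise ValueError(
                f"{self.scaffold_id}: {len(self.values)} bins but "
                f"ceil({self.scaffold_length}/{self.bin_size}) = {expected}"
            )
        for v in self.values:
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"bin coverage {v} outside [0, 1]")

    def bin_interval(self, index: int) -> GenomicInterval:
        start = index * self.bin_size
        end = min(start + self.bin_size, self.scaffold_length or (start + self.bin_size))
        return GenomicInterval(self.scaffold_id, start, end)

    def covered_bp(self) -> float:
        """Sum over bins of value × true bin length (equals union coverage bp)."""
        return sum(
            v * self.bin_interval(i).length for i, v in enumerate(self.values)
        )


def binned_coverage(
    features: Iterable,
    scaffold_id: str,
    scaffold_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    feature_set: str = "",
) -> WindowTrack:
    """Proportional coverage in fixed windows; the final partial bin is
    normalised by its true (shorter) length."""
    merged = merge_intervals(
        [
            iv
            for iv in _intervals_of(features)
            if iv.scaffold_id == scaffold_id
        ]
    )
    n_bins = -(-scaffold_length // bin_size)
    edges = [min(i * bin_size, scaffold_length) for i in range(n_bins + 1)]
    covered = np.zeros(n_bins)
    starts = np.array([s for s, _ in merged], dtype=float)
    ends = np.array([e for _, e in merged], dtype=float)
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        if len(starts):
            clip = np.minimum(ends, hi) - np.maximum(starts, lo)
            covered[i] = np.clip(clip, 0, None).sum()
    values = [
        covered[i] / (edges[i + 1] - edges[i]) for i in range(n_bins)
    ]
    return WindowTrack(
        scaffold_id=scaffold_id,
        bin_size=bin_size,
        values=values,
        feature_set=feature_set,
        scaffold_length=scaffold_length,
    )


@dataclass
class CorrelationResult:
    r: Optional[float]
    p: Optional[float]
    n: int
    computable: bool = True
    reason: str = ""


def scaffold_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Pearson product-moment correlation across paired scaffold fractions.

    Degenerate inputs (fewer than 3 pairs, zero variance) are reported as a
    not-computable result rather than NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        return CorrelationResult(None, None, len(x), False, "fewer than 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(None, None, len(x), False, "zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def per_scaffold_coverage(
    features: Iterable,
    assembly: Assembly,
    min_scaffold_bp: int = 0,
) -> dict[str, float]:
    """Whole-scaffold proportional coverage for every (large enough) scaffold."""
    by_scaffold: dict[str, list[GenomicInterval]] = {}
    for iv in _intervals_of(features):
        by_scaffold.setdefault(iv.scaffold_id, []).append(iv)
    out = {}
    for scaffold_id, length in assembly.scaffolds.items():
        if length < min_scaffold_bp:
            continue
        region = GenomicInterval(scaffold_id, 0, length)
        out[scaffold_id] = proportional_coverage(
            by_scaffold.get(scaffold_id, []), region
        )
    return out


def gene_te_correlation(
    genes: Iterable,
    tes: Iterable,
    assembly: Assembly,
    min_scaffold_bp: int = DEFAULT_MIN_SCAFFOLD_BP,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Per-scaffold gene vs TE coverage and their Pearson correlation."""
    gene_cov = per_scaffold_coverage(genes, assembly, min_scaffold_bp)
    te_cov = per_scaffold_coverage(tes, assembly, min_scaffold_bp)
    scaffolds = sorted(gene_cov)
    table = pd.DataFrame(
        {
            "scaffold_id": scaffolds,
            "gene_coverage": [gene_cov[s] for s in scaffolds],
            "te_coverage": [te_cov[s] for s in scaffolds],
        }
    )
    result = scaffold_correlation(
        table["gene_coverage"].to_numpy(), table["te_coverage"].to_numpy()
    )
    return result, table


def genome_te_table(
    te_annotations: Iterable[TEAnnotation] | None,
    assembly_bp: int,
    counts: dict[str, tuple[int, int]] | None = None,
    superfamily_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genome-wide TE tabulation: matches, bp and the three percentage columns.

    Input is either a list of annotations (counted and summed per
    superfamily; bp are union-merged per superfamily and scaffold so nested
    hits are not double-counted) or a precomputed ``superfamily -> (n, bp)``
    map (e.g. a published annotation table). Percentages are

    * % of matches   = 100·n / Σn
    * % of TE bp     = 100·bp / Σbp
    * % of genome    = 100·bp / assembly_bp  (denominator includes N/X runs)

    all rounded to 2 decimals, with a TOTAL row holding the column sums.
    """
    if counts is None:
        counts = {}
        spans: dict[str, dict[str, list]] = {}
        for ann in te_annotations or []:
            sf = ann.superfamily
            spans.setdefault(sf, {}).setdefault(
                ann.interval.scaffold_id, []
            ).append(ann.interval)
            n, bp = counts.get(sf, (0, 0))
            counts[sf] = (n + 1, bp)
        for sf, per_scaffold in spans.items():
            bp = sum(
                total_bp(merge_intervals(ivs)) for ivs in per_scaffold.values()
            )
            counts[sf] = (counts[sf][0], bp)

    order = list(superfamily_order) if superfamily_order else sorted(counts)
    for sf in counts:
        if sf not in order:
            order.append(sf)
    total_n = sum(n for n, _ in counts.values())
    total_te_bp = sum(bp for _, bp in counts.values())

    rows = []
    for sf in order:
        n, bp = counts.get(sf, (0, 0))
        rows.append(
            {
                "te_class": class_of(sf),
                "order": order_of(sf),
                "superfamily": sf,
                "n_matches": n,
                "pct_of_matches": round(100.0 * n / total_n, 2) if total_n else 0.0,
                "bp_occupied": bp,
                "pct_of_te_bp": round(100.0 * bp / total_te_bp, 2) if total_te_bp else 0.0,
                "pct_of_genome": round(100.0 * bp / assembly_bp, 2) if assembly_bp else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    # Total percentages are recomputed from the column totals (100.00 by
    # definition for the two share columns) rather than by summing rounded
    # rows, so rounding drift never leaks into the totals row.
    total_row = {
        "te_class": "TOTAL",
        "order": "",
        "superfamily": "TOTAL",
        "n_matches": total_n,
        "pct_of_matches": 100.0 if total_n else 0.0,
        "bp_occupied": total_te_bp,
        "pct_of_te_bp": 100.0 if total_te_bp else 0.0,
        "pct_of_genome": round(100.0 * total_te_bp / assembly_bp, 2) if assembly_bp else 0.0,
    }
    return pd.concat([table, pd.DataFrame([total_row])], ignore_index=True)


def superfamily_tracks(
    tes: Iterable[TEAnnotation],
    scaffold_id: str,
    scaffold_length: int,
    superfamilies: Sequence[str] = ("Copia", "Gypsy", "L1", "Mutator"),
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, WindowTrack]:
    """Heat-map-style per-superfamily coverage tracks on one shared bin grid."""
    tes = list(tes)
    return {
        sf: binned_coverage(
            [t for t in tes if t.superfamily == sf],
            scaffold_id,
            scaffold_length,
            bin_size,
            feature_set=sf,
        )
        for sf in superfamilies
    }


def tracks_to_frame(tracks: Iterable[WindowTrack]) -> pd.DataFrame:
    """One row per bin per track, for TSV export."""
    rows = []
    for track in tracks:
        for i, v in enumerate(track.values):
            iv = track.bin_interval(i)
            rows.append(
                {
                    "scaffold_id": track.scaffold_id,
                    "feature_set": track.feature_set,
                    "bin_index": i,
                    "bin_start": iv.start,
                    "bin_end": iv.end,
                    "coverage": v,
                }
            )
    return pd.DataFrame(rows)
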