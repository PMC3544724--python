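"""Sequential Monte-Carlo test of TE–gene overlap, with an MCFDR-style
stopping scheme across many analysis units (scaffolds or 50-kb bins).

The observed statistic for a unit is the number of base pairs shared by the
union of TE intervals and the union of gene intervals. The null model keeps
gene positions and every TE length fixed and re-places each TE independently
and uniformly along the unit (TE–TE overlap is allowed in the null). The
p-value uses the add-one permutation estimator ``p = (k + 1) / (n + 1)``
with ``k`` exceedances (null statistic ≥ observed) among ``n`` samples, so
it can never be exactly zero.

Per unit, sampling stops once at least ``min_samples`` draws have been made
and ``exceedance_threshold`` exceedances observed (at which point the
p estimate has a stable relative error), or at the sample cap. Across
units, sampling proceeds round-robin; after each round a Benjamini–Hochberg
step at the target FDR classifies the current estimates, and only units
whose status is still undecided keep sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    intersect_merged,
    merge_intervals,
    total_bp,
)

DEFAULT_MIN_SAMPLES = 100
DEFAULT_EXCEEDANCE_THRESHOLD = 20
DEFAULT_MAX_SAMPLES = 10_000
DEFAULT_ALPHA = 0.05


def overlap_statistic(tes: Iterable, genes: Iterable, unit: GenomicInterval) -> int:
    """Base pairs in (union of TEs) ∩ (union of genes), clipped to ``unit``."""

    def clipped(features):
        spans = []
        for f in features:
            iv = f if isinstance(f, GenomicInterval) else f.interval
            if iv.scaffold_id != unit.scaffold_id:
                continue
            lo, hi = max(iv.start, unit.start), min(iv.end, unit.end)
            if lo < hi:
                spans.append((lo, hi))
        return merge_intervals(spans)

    return total_bp(intersect_merged(clipped(tes), clipped(genes)))


def count_statistic(tes: Iterable, genes: Iterable, unit: GenomicInterval) -> int:
    """Alternative statistic: number of TEs overlapping any gene by ≥ 1 bp."""
    gene_spans = merge_intervals(
        [
            (max(g.interval.start, unit.start), min(g.interval.end, unit.end))
            for g in genes
            if g.interval.scaffold_id == unit.scaffold_id
            and g.interval.start < unit.end
            and g.interval.end > unit.start
        ]
    )
    if not gene_spans:
        return 0
    starts = np.array([s for s, _ in gene_spans])
    ends = np.array([e for _, e in gene_spans])
    n = 0
    for te in tes:
        iv = te if isinstance(te, GenomicInterval) else te.interval
        if iv.scaffold_id != unit.scaffold_id:
            continue
        idx = np.searchsorted(starts, iv.end)
        if idx > 0 and ends[idx - 1] > iv.start:
            n += 1
        elif idx < len(starts) and starts[idx] < iv.end:
            n += 1
    return n


def randomize_te_starts(
    te_lengths: np.ndarray, unit_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent uniform starts preserving every TE length."""
    if np.any(te_lengths > unit_length):
        raise ValueError("a TE is longer than the analysis unit")
    high = unit_length - te_lengths + 1
    return (rng.random(len(te_lengths)) * high).astype(np.int64)


def randomize_tes(
    tes: Sequence, unit: GenomicInterval, seed: int | np.random.Generator = 0
) -> list[GenomicInterval]:
    """Uniformly repositioned TE intervals within ``unit`` (lengths kept)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.array(
        [
            (t if isinstance(t, GenomicInterval) else t.interval).length
            for t in tes
        ],
        dtype=np.int64,
    )
    starts = randomize_te_starts(lengths, unit.length, rng) + unit.start
    return [
        GenomicInterval(unit.scaffold_id, int(s), int(s + l))
        for s, l in zip(starts, lengths)
    ]


def _null_overlap(
    te_lengths: np.ndarray,
    gene_spans: list[tuple[int, int]],
    unit_length: int,
    rng: np.random.Generator,
) -> int:
    starts = randomize_te_starts(te_lengths, unit_length, rng)
    order = np.argsort(starts)
    te_spans = merge_intervals(
        list(zip(starts[order].tolist(), (starts[order] + te_lengths[order]).tolist()))
    )
    return total_bp(intersect_merged(te_spans, gene_spans))


@dataclass
class McResult:
    unit_id: str
    observed_stat: float
    n_samples: int
    n_exceedances: int
    stop_reason: str  # exceedance_threshold | fdr_decided | cap
    rejected: bool = False

    @property
    def p_estimate(self) -> float:
        return (self.n_exceedances + 1) / (self.n_samples + 1)


@dataclass
class McUnit:
    """One analysis unit: its observed statistic plus a null sampler."""

    unit_id: str
    observed: float
    sampler: Callable[[np.random.Generator], float]

    @classmethod
    def from_tracks(
        cls, unit_id: str, tes: Sequence, genes: Sequence, unit: GenomicInterval
    ) -> "McUnit":
        observed = overlap_statistic(tes, genes, unit)
        # TEs straddling the unit boundary enter the null with their clipped
        # length, so every null length fits inside the unit.
        clipped_lengths = []
        for t in tes:
            iv = t if isinstance(t, GenomicInterval) else t.interval
            if iv.scaffold_id != unit.scaffold_id:
                continue
            span = min(iv.end, unit.end) - max(iv.start, unit.start)
            if span > 0:
                clipped_lengths.append(span)
        te_lengths = np.array(clipped_lengths, dtype=np.int64)
        gene_spans = merge_intervals(
            [
                (max(g.interval.start, unit.start) - unit.start,
                 min(g.interval.end, unit.end) - unit.start)
                for g in genes
                if g.interval.scaffold_id == unit.scaffold_id
                and g.interval.start < unit.end
                and g.interval.end > unit.start
            ]
        )
        unit_length = unit.length

        def sampler(rng: np.random.Generator) -> float:
            if len(te_lengths) == 0 or not gene_spans:
                return 0.0
            return _null_overlap(te_lengths, gene_spans, unit_length, rng)

        return cls(unit_id=unit_id, observed=observed, sampler=sampler)


def sequential_mc_pvalue(
    observed: float,
    null_sampler: Callable[[np.random.Generator], float],
    min_samples: int = DEFAULT_MIN_SAMPLES,
    exceedance_threshold: int = DEFAULT_EXCEEDANCE_THRESHOLD,
    max_samples: int = DEFAULT_MAX_SAMPLES,
    seed: int | np.random.Generator = 0,
    unit_id: str = "unit",
) -> McResult:
    """Draw null samples until the stopping rule fires.

    Stops when ``n >= min_samples`` and ``k >= exceedance_threshold``
    (enough exceedances for a stable estimate), else at ``max_samples``.
    An exceedance is ``null_stat >= observed`` (ties count, conservative).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = k = 0
    while True:
        if n >= min_samples and k >= exceedance_threshold:
            reason = "exceedance_threshold"
            break
        if n >= max_samples:
            reason = "cap"
            break
        if null_sampler(rng) >= observed:
            k += 1
        n += 1
    return McResult(
        unit_id=unit_id,
        observed_stat=observed,
        n_samples=n,
        n_exceedances=k,
        stop_reason=reason,
    )


def _bh_reject(p_values: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg rejection mask."""
    m = len(p_values)
    order = np.argsort(p_values)
    thresholds = alpha * (np.arange(1, m + 1)) / m
    passed = p_values[order] <= thresholds
    mask = np.zeros(m, dtype=bool)
    if passed.any():
        cutoff = np.max(np.nonzero(passed)[0])
        mask[order[: cutoff + 1]] = True
    return mask


def mcfdr_schedule(
    units: Sequence[McUnit],
    alpha: float = DEFAULT_ALPHA,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    exceedance_threshold: int = DEFAULT_EXCEEDANCE_THRESHOLD,
    max_samples: int = DEFAULT_MAX_SAMPLES,
    chunk: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[McResult]:
    """Round-robin sequential MC with an FDR stopping criterion.

    Each round adds ``chunk`` null samples to every still-active unit; a
    unit retires once its exceedance count reaches the threshold (its
    p estimate is then stable regardless of the other units). After each
    round, Benjamini–Hochberg at ``alpha`` is applied to the current
    estimates; when no active unit remains, or all active units are
    currently rejected and at their cap, the schedule stops. Final
    rejection calls come from one last BH pass.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = np.zeros(len(units), dtype=np.int64)
    k = np.zeros(len(units), dtype=np.int64)
    active = np.ones(len(units), dtype=bool)
    reason = ["cap"] * len(units)

    while active.any():
        for i in np.nonzero(active)[0]:
            unit = units[i]
            for _ in range(chunk):
                if k[i] >= exceedance_threshold and n[i] >= min_samples:
                    break
                if n[i] >= max_samples:
                    break
                if unit.sampler(rng) >= unit.observed:
                    k[i] += 1
                n[i] += 1
        p = (k + 1) / (n + 1)
        rejected = _bh_reject(p, alpha)
        for i in range(len(units)):
            if not active[i]:
                continue
            if k[i] >= exceedance_threshold and n[i] >= min_samples:
                active[i] = False
                reason[i] = "exceedance_threshold"
            elif n[i] >= max_samples:
                active[i] = False
                reason[i] = "cap" if not rejected[i] else "fdr_decided"

    p = (k + 1) / (n + 1)
    rejected = _bh_reject(p, alpha)
    return [
        McResult(
            unit_id=units[i].unit_id,
            observed_stat=units[i].observed,
            n_samples=int(n[i]),
            n_exceedances=int(k[i]),
            stop_reason=reason[i],
            rejected=bool(rejected[i]),
        )
        for i in range(len(units))
    ]


def results_to_frame(results: Iterable[McResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "observed_bp": r.observed_stat,
                "n_samples": r.n_samples,
                "n_exceedances": r.n_exceedances,
                "p_estimate": r.p_estimate,
                "stop_reason": r.stop_reason,
                "rejected": r.rejected,
            }
            for r in results
        ]
    )


def units_from_annotations(
    tes: Sequence,
    genes: Sequence,
    assembly,
    bin_size: int | None = None,
    min_scaffold_bp: int = 0,
) -> list[McUnit]:
    """Build analysis units per scaffold, or per fixed-size bin when
    ``bin_size`` is given."""
    units = []
    for scaffold_id, length in assembly.scaffolds.items():
        if length < min_scaffold_bp:
            continue
        if bin_size is None:
            unit_iv = GenomicInterval(scaffold_id, 0, length)
            units.append(McUnit.from_tracks(scaffold_id, tes, genes, unit_iv))
        else:
            n_bins = -(-length // bin_size)
            for b in range(n_bins):
                lo = b * bin_size
                hi = min(lo + bin_size, length)
                unit_iv = GenomicInterval(scaffold_id, lo, hi)
                units.append(
                    McUnit.from_tracks(f"{scaffold_id}:bin{b:04d}", tes, genes, unit_iv)
                )
    return units
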