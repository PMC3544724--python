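"""Curation of candidate repeats from de novo repeat finders.

Three rules turn a raw candidate library into an annotated TE library:

* low-copy filtering — candidates with fewer than 10 hits against the
  genome are dropped (they are more likely gene families or pseudogenes
  than mobile elements);
* database voting — a candidate is assigned to a TE superfamily only when
  at least two *distinct* reference databases agree on the label with hits
  at E ≤ 1e-5 ("at least 1e-5" read as a significance floor, so the
  boundary value passes);
* redundancy removal — greedy longest-first clustering collapses
  candidates that are ≥ 90% globally identical to an already retained
  representative.

The homology searches themselves (BLAST-family runs against Repbase-style
databases) are consumed as 12-column tabular hit files; the contribution
here is the filtering and voting logic, not the search.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import make_aligner, pairwise_identity

logger = logging.getLogger(__name__)

MIN_GENOME_HITS = 10
E_VALUE_MAX = 1e-5
DEDUPE_IDENTITY = 0.90
KNOWN_DATABASES = ("repbase", "plant_repeat_db", "repeat_peps", "nr")
LOW_COMPLEXITY_ENTROPY_BITS = 1.5


@dataclass
class RepeatCandidate:
    repeat_id: str
    sequence: str
    source_algorithm: str = "other"  # PILER | RepeatScout | LTR_finder | LTR_STRUC | other
    genome_hit_count: int = 0
    superfamily: Optional[str] = None
    low_complexity_flag: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"candidate {self.repeat_id!r} has an empty sequence")
        if self.genome_hit_count < 0:
            raise ValueError("genome_hit_count must be >= 0")


@dataclass
class DbHit:
    repeat_id: str
    database: str
    annotation_label: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


def filter_low_copy(
    candidates: Iterable[RepeatCandidate], min_hits: int = MIN_GENOME_HITS
) -> list[RepeatCandidate]:
    """Retain candidates with at least ``min_hits`` genome hits."""
    retained = [c for c in candidates if c.genome_hit_count >= min_hits]
    if not retained:
        logger.warning("low-copy filter removed every candidate")
    return retained


def assign_superfamily(
    candidate: RepeatCandidate,
    hits: Sequence[DbHit],
    e_max: float = E_VALUE_MAX,
) -> str:
    """Database-voting superfamily assignment.

    A label wins iff hits carrying it, at E ≤ ``e_max``, occur in at least
    two distinct databases. Among multiple winning labels the one with the
    smallest best E-value is chosen (lexicographic id as the final
    tie-break, logged). Order of the hit list never matters.
    """
    own_hits = [
        h for h in hits if h.repeat_id == candidate.repeat_id and h.e_value <= e_max
    ]
    label_dbs: dict[str, set[str]] = {}
    best_e: dict[str, float] = {}
    for h in own_hits:
        label_dbs.setdefault(h.annotation_label, set()).add(h.database)
        best_e[h.annotation_label] = min(
            best_e.get(h.annotation_label, math.inf), h.e_value
        )
    winners = sorted(
        (label for label, dbs in label_dbs.items() if len(dbs) >= 2),
        key=lambda label: (best_e[label], label),
    )
    if not winners:
        return "unclassified"
    if len(winners) > 1:
        logger.info(
            "candidate %s: multiple superfamilies satisfy the voting rule %s; "
            "keeping %s (smallest best E-value, then lexicographic)",
            candidate.repeat_id, winners, winners[0],
        )
    return winners[0]


def annotate_candidates(
    candidates: Iterable[RepeatCandidate],
    hits: Sequence[DbHit],
    e_max: float = E_VALUE_MAX,
) -> list[RepeatCandidate]:
    """Assign a superfamily to every candidate (in place; returns the list)."""
    by_repeat: dict[str, list[DbHit]] = {}
    for h in hits:
        by_repeat.setdefault(h.repeat_id, []).append(h)
    out = []
    for c in candidates:
        c.superfamily = assign_superfamily(c, by_repeat.get(c.repeat_id, []), e_max)
        out.append(c)
    return out


def dedupe_sequences(
    candidates: Sequence[RepeatCandidate],
    identity_threshold: float = DEDUPE_IDENTITY,
    aligner=None,
) -> list[RepeatCandidate]:
    """Greedy longest-first redundancy removal.

    Candidates are visited longest-first; each joins the first retained
    representative it matches at ``identity_threshold`` global identity,
    otherwise becomes a representative itself. Returns representatives in
    input order.
    """
    if not candidates:
        return []
    if aligner is None:
        aligner = make_aligner()
    order = sorted(candidates, key=lambda c: (-len(c.sequence), c.repeat_id))
    representatives: list[RepeatCandidate] = []
    for candidate in order:
        if not any(
            pairwise_identity(candidate.sequence, rep.sequence, aligner)
            >= identity_threshold
            for rep in representatives
        ):
            representatives.append(candidate)
    input_rank = {c.repeat_id: i for i, c in enumerate(candidates)}
    representatives.sort(key=lambda c: input_rank[c.repeat_id])
    return representatives


def shannon_entropy_bits(sequence: str) -> float:
    """Shannon entropy of the base composition, in bits per symbol."""
    counts = Counter(sequence.upper())
    n = sum(counts.values())
    return -sum(
        (c / n) * math.log2(c / n) for c in counts.values() if c
    )


def flag_low_complexity(
    candidates: Iterable[RepeatCandidate],
    entropy_bits: float = LOW_COMPLEXITY_ENTROPY_BITS,
) -> list[RepeatCandidate]:
    """Mark (never remove) candidates with whole-sequence entropy below the
    threshold — a lightweight screen for simple repeats."""
    out = []
    for c in candidates:
        c.low_complexity_flag = shannon_entropy_bits(c.sequence) < entropy_bits
        out.append(c)
    return out


def curate(
    candidates: Sequence[RepeatCandidate],
    hits: Sequence[DbHit],
    min_hits: int = MIN_GENOME_HITS,
    e_max: float = E_VALUE_MAX,
    identity_threshold: float = DEDUPE_IDENTITY,
) -> list[RepeatCandidate]:
    """Full curation: low-copy filter → annotation voting → dedupe → flags."""
    retained = filter_low_copy(candidates, min_hits)
    annotated = annotate_candidates(retained, hits, e_max)
    unique = dedupe_sequences(annotated, identity_threshold)
    return flag_low_complexity(unique)


def curation_report(candidates: Iterable[RepeatCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "repeat_id": c.repeat_id,
                "source_algorithm": c.source_algorithm,
                "length_bp": len(c.sequence),
                "genome_hit_count": c.genome_hit_count,
                "superfamily": c.superfamily or "unclassified",
                "low_complexity_flag": c.low_complexity_flag,
            }
            for c in candidates
        ]
    )
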