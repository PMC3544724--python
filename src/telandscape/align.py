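"""Pairwise alignment utilities.

Two kinds of alignment are needed at desk scale:

* Global pairwise alignment (family identity, LTR-pair divergence), done
  with Biopython's :class:`Bio.Align.PairwiseAligner`. Identity is defined
  as matched columns over all alignment columns, gap columns counting as
  non-matches.
* Copy mapping of a short query against an assembly, done with an exact
  k-mer seeding (k = 15) + gapless extension search. This is sufficient for
  locating planted/substituted copies in synthetic scaffolds and keeps the
  pipeline self-contained; externally produced PSL hit tables can be used
  in its place at genome scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .intervals import GenomicInterval
from .model import AlignmentHit

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_OPEN_GAP = -5.0
DEFAULT_EXTEND_GAP = -1.0

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_UNAMBIGUOUS = {"A", "C", "G", "T"}


def make_aligner(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    open_gap: float = DEFAULT_OPEN_GAP,
    extend_gap: float = DEFAULT_EXTEND_GAP,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def global_alignment(a: str, b: str, aligner: Align.PairwiseAligner | None = None):
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    return aligner.align(a.upper(), b.upper())[0]


@dataclass
class AlignmentSummary:
    identities: int
    mismatches: int
    gap_columns: int

    @property
    def columns(self) -> int:
        return self.identities + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        return self.identities / self.columns

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identity


def summarize_alignment(alignment) -> AlignmentSummary:
    counts = alignment.counts()
    return AlignmentSummary(
        identities=counts.identities,
        mismatches=counts.mismatches,
        gap_columns=counts.gaps,
    )


def pairwise_identity(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Global-alignment identity in [0, 1]: matches / alignment columns.

    Co-optimal alignments can differ in their match/gap composition, and the
    aligner reports them in an argument-order-dependent order; the pair is
    therefore canonicalised (shorter/lexicographically-smaller first) so the
    result is exactly symmetric.
    """
    if (len(a), a) > (len(b), b):
        a, b = b, a
    return summarize_alignment(global_alignment(a, b, aligner)).identity


def aligned_column_pairs(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> list[tuple[str, str]]:
    """Gap-free aligned base pairs from a global alignment.

    Columns containing a gap are excluded here; ambiguous-base filtering is
    the caller's concern (see :func:`count_substitution_types`).
    """
    alignment = global_alignment(a, b, aligner)
    a_seq, b_seq = alignment[0], alignment[1]
    return [
        (x, y) for x, y in zip(a_seq, b_seq) if x != "-" and y != "-"
    ]


def count_substitution_types(
    pairs: list[tuple[str, str]],
) -> tuple[int, int, int]:
    """Return ``(transitions, transversions, compared_sites)``.

    Pairs with an ambiguous base (anything outside ACGT) are excluded from
    the comparison entirely, as is standard for distance estimation.
    """
    transitions = transversions = compared = 0
    for x, y in pairs:
        if x not in _UNAMBIGUOUS or y not in _UNAMBIGUOUS:
            continue
        compared += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or (
            x in _PYRIMIDINES and y in _PYRIMIDINES
        ):
            transitions += 1
        else:
            transversions += 1
    return transitions, transversions, compared


# ---------------------------------------------------------------------------
# k-mer seed-and-extend copy search
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _base in enumerate("ACGT"):
    _ENCODE[ord(_base)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; windows containing N/X get code −1."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = enc[j : j + n]
        codes = codes * 4 + np.where(window < 4, window, 0)
        invalid |= window >= 4
    codes[invalid] = -1
    return codes


def find_copies(
    query: str,
    target: str,
    target_id: str = "target",
    query_id: str = "query",
    k: int = 15,
    min_coverage: float = 0.0,
    min_seed_votes: int = 1,
) -> list[AlignmentHit]:
    """Locate gapless copies of ``query`` in ``target``.

    Exact k-mer matches vote for a diagonal (target offset − query offset);
    each supported diagonal is evaluated by a direct base-by-base comparison
    of the query against the co-linear target span. Overlapping hits are
    reduced by greedy non-maximum suppression on matched bases. Hits with
    query coverage below ``min_coverage`` are dropped.
    """
    query = query.upper()
    target = target.upper()
    if len(query) < k or len(target) < k:
        return []
    q_enc = _encode(query)
    t_enc = _encode(target)
    q_codes = _kmer_codes(q_enc, k)
    t_codes = _kmer_codes(t_enc, k)

    code_to_qpos: dict[int, list[int]] = {}
    for qpos, code in enumerate(q_codes):
        if code >= 0:
            code_to_qpos.setdefault(int(code), []).append(qpos)

    mask = np.isin(t_codes, np.fromiter(code_to_qpos, dtype=np.int64, count=len(code_to_qpos)))
    t_positions = np.nonzero(mask)[0]
    offsets = []
    for tpos in t_positions:
        for qpos in code_to_qpos[int(t_codes[tpos])]:
            offsets.append(int(tpos) - qpos)
    if not offsets:
        return []
    uniq, votes = np.unique(np.asarray(offsets), return_counts=True)

    candidates = []
    for offset, vote in zip(uniq, votes):
        if vote < min_seed_votes:
            continue
        q_lo = max(0, -offset)
        q_hi = min(len(query), len(target) - offset)
        if q_hi - q_lo < k:
            continue
        t_lo, t_hi = q_lo + offset, q_hi + offset
        equal = q_enc[q_lo:q_hi] == t_enc[t_lo:t_hi]
        matches = int(np.count_nonzero(equal))
        if matches < min_coverage * len(query):
            continue
        candidates.append((matches, int(t_lo), int(t_hi), q_hi - q_lo))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    hits: list[AlignmentHit] = []
    taken: list[tuple[int, int]] = []
    for matches, t_lo, t_hi, span in candidates:
        if any(min(t_hi, hi) - max(t_lo, lo) > 0.5 * span for lo, hi in taken):
            continue
        taken.append((t_lo, t_hi))
        hits.append(
            AlignmentHit(
                query_id=query_id,
                target_id=target_id,
                matched_bases=matches,
                query_length=len(query),
                target_length=len(target),
                gap_count=0,
                mismatch_count=span - matches,
                target_interval=GenomicInterval(target_id, t_lo, t_hi),
            )
        )
    hits.sort(key=lambda h: h.target_interval.start)
    return hits
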