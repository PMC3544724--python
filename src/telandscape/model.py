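"""Domain records shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import GenomicInterval
from .taxonomy import UNCLASSIFIED, class_of, order_of


@dataclass
class TEAnnotation:
    """A classified transposable-element interval.

    ``order`` and ``te_class`` are derived from the superfamily through the
    taxonomy table when not given, so a record can never carry a
    superfamily/order combination the taxonomy does not allow.
    """

    interval: GenomicInterval
    superfamily: str = UNCLASSIFIED
    order: str = ""
    te_class: str = ""
    family_id: Optional[str] = None
    source: str = ""

    def __post_init__(self) -> None:
        expected_order = order_of(self.superfamily)
        expected_class = class_of(self.superfamily)
        if not self.order:
            self.order = expected_order
        if not self.te_class:
            self.te_class = expected_class
        if self.order != expected_order or self.te_class != expected_class:
            raise ValueError(
                f"superfamily {self.superfamily!r} implies order {expected_order!r} "
                f"/ class {expected_class!r}, got {self.order!r} / {self.te_class!r}"
            )


@dataclass
class GeneAnnotation:
    interval: GenomicInterval
    gene_id: str


@dataclass
class Assembly:
    """Scaffold lengths, optionally with sequence.

    Sequences use the alphabet {A, C, G, T, N, X}; N/X runs count toward
    scaffold length (and hence toward any whole-genome denominator).
    """

    scaffolds: dict[str, int] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    _ALPHABET = frozenset("ACGTNX")

    def add(self, scaffold_id: str, length: int = 0, sequence: str | None = None):
        if sequence is not None:
            sequence = sequence.upper()
            extra = set(sequence) - self._ALPHABET
            if extra:
                raise ValueError(
                    f"scaffold {scaffold_id!r} contains letters outside "
                    f"ACGTNX: {sorted(extra)}"
                )
            if length and length != len(sequence):
                raise ValueError(
                    f"scaffold {scaffold_id!r}: declared length {length} != "
                    f"sequence length {len(sequence)}"
                )
            length = len(sequence)
            self.sequences[scaffold_id] = sequence
        if length <= 0:
            raise ValueError(f"scaffold {scaffold_id!r} needs a positive length")
        self.scaffolds[scaffold_id] = length

    @property
    def total_bp(self) -> int:
        return sum(self.scaffolds.values())

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def length_of(self, scaffold_id: str) -> int:
        return self.scaffolds[scaffold_id]


@dataclass
class AlignmentHit:
    """A generic query-vs-target alignment summary.

    ``matched_bases`` is the number of identically aligned bases — the PSL
    ``matches`` column. Coverage rules (70% of an EST, 80% of a family
    representative, 100% for exact re-mapping) are all expressed in terms of
    this field relative to a sequence length.
    """

    query_id: str
    target_id: str
    matched_bases: int
    query_length: int
    target_length: int
    gap_count: int = 0
    mismatch_count: int = 0
    target_interval: Optional[GenomicInterval] = None
    e_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.matched_bases < 0 or self.gap_count < 0 or self.mismatch_count < 0:
            raise ValueError("alignment counts must be non-negative")
        if self.matched_bases > min(self.query_length, self.target_length):
            raise ValueError(
                f"matched_bases {self.matched_bases} exceeds both sequence lengths "
                f"({self.query_length}, {self.target_length})"
            )

    def query_coverage(self) -> float:
        return self.matched_bases / self.query_length

    def target_coverage(self) -> float:
        return self.matched_bases / self.target_length


@dataclass
class LTRElement:
    """A full-length LTR retroelement: left LTR + internal region + right LTR."""

    element_id: str
    element_interval: GenomicInterval
    left_ltr_seq: str
    right_ltr_seq: str
    left_ltr_interval: Optional[GenomicInterval] = None
    right_ltr_interval: Optional[GenomicInterval] = None
    internal_class: str = "undetermined"  # copia / gypsy / undetermined / other-TE-bearing
    ltr_similarity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.left_ltr_interval and self.right_ltr_interval:
            if self.left_ltr_interval.start >= self.right_ltr_interval.start:
                raise ValueError("left LTR must precede right LTR")
            outer = self.element_interval
            for ltr in (self.left_ltr_interval, self.right_ltr_interval):
                if ltr.start < outer.start or ltr.end > outer.end:
                    raise ValueError("LTR interval falls outside the element span")

    @property
    def sequence_available(self) -> bool:
        return bool(self.left_ltr_seq and self.right_ltr_seq)
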