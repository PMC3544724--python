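"""Insertion dating of full-length LTR retroelements.

At insertion time an element's two LTRs are identical; substitutions
accumulate independently in each copy afterwards, so the pairwise distance
between them measures twice the time since insertion. The distance is the
Kimura 2-parameter estimate

    K = -1/2 · ln((1 - 2P - Q) · sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over gap-free,
unambiguous aligned columns. Age follows from ``t = K / (2r)`` with ``r``
the per-site per-year substitution rate (default 1.5e-8, a plant nuclear
rate commonly used for retroelement dating).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .align import (
    aligned_column_pairs,
    count_substitution_types,
    global_alignment,
    summarize_alignment,
)
from .model import LTRElement

logger = logging.getLogger(__name__)

DEFAULT_RATE = 1.5e-8  # substitutions / site / year
MIN_LTR_LENGTH_WARN = 50


class SaturationError(ValueError):
    """K2P distance undefined: 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0."""


@dataclass
class K2PResult:
    P: float
    Q: float
    compared_sites: int
    K: float

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1:
            raise ValueError("P and Q must be non-negative with P + Q <= 1")


@dataclass
class InsertionAge:
    element_id: str
    K: float
    r: float
    t_mya: float
    internal_class: str = "undetermined"
    ltr_similarity_pct: Optional[float] = None


def k2p_distance(P: float, Q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated divergence (P={P:.4f}, Q={Q:.4f}): K2P distance undefined"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_age(K: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age in Mya via ``t = K / 2r`` (r in substitutions/site/year)."""
    if K < 0:
        raise ValueError("K must be >= 0")
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    return K / (2.0 * r) / 1e6


def analyze_ltr_pair(left: str, right: str, aligner=None) -> tuple[K2PResult, float]:
    """Align an LTR pair and return ``(K2PResult, similarity_pct)``.

    Alignment columns with a gap or an ambiguous base are excluded from the
    P/Q proportions; similarity is matches over *all* alignment columns
    (gaps counting as non-matches), consistent with the family-clustering
    identity definition.
    """
    if not left or not right:
        raise ValueError("cannot analyse an empty LTR sequence")
    if min(len(left), len(right)) < MIN_LTR_LENGTH_WARN:
        logger.warning(
            "LTR shorter than %d bp; divergence estimate will be noisy",
            MIN_LTR_LENGTH_WARN,
        )
    alignment = global_alignment(left, right, aligner)
    similarity_pct = summarize_alignment(alignment).identity_pct
    pairs = [
        (x, y)
        for x, y in zip(alignment[0], alignment[1])
        if x != "-" and y != "-"
    ]
    transitions, transversions, compared = count_substitution_types(pairs)
    if compared == 0:
        raise ValueError("no comparable (gap-free, unambiguous) columns")
    P = transitions / compared
    Q = transversions / compared
    K = k2p_distance(P, Q)
    return K2PResult(P=P, Q=Q, compared_sites=compared, K=K), similarity_pct


def date_elements(
    elements: Iterable[LTRElement],
    rate: float = DEFAULT_RATE,
    aligner=None,
) -> tuple[list[InsertionAge], list[str]]:
    """Date every element with sequence; saturated elements are excluded.

    Returns ``(ages, excluded_element_ids)``; exclusions are logged. The
    per-element similarity is written back onto the element record.
    """
    ages: list[InsertionAge] = []
    excluded: list[str] = []
    for element in elements:
        try:
            k2p, similarity = analyze_ltr_pair(
                element.left_ltr_seq, element.right_ltr_seq, aligner
            )
        except SaturationError:
            logger.info("element %s excluded: saturated LTR divergence", element.element_id)
            excluded.append(element.element_id)
            continue
        element.ltr_similarity_pct = similarity
        ages.append(
            InsertionAge(
                element_id=element.element_id,
                K=k2p.K,
                r=rate,
                t_mya=insertion_age(k2p.K, rate),
                internal_class=element.internal_class,
                ltr_similarity_pct=similarity,
            )
        )
    return ages, excluded


def age_distribution(
    ages: Iterable[InsertionAge],
    bin_width_mya: float = 0.5,
    max_mya: float = 15.0,
) -> pd.DataFrame:
    """Left-closed age histogram per internal class.

    Elements older than ``max_mya`` are tallied in a separate
    ``older_than_max`` row per class rather than being folded into the last
    bin."""
    ages = list(ages)
    classes = sorted({a.internal_class for a in ages})
    n_bins = int(math.ceil(max_mya / bin_width_mya))
    rows = []
    for cls in classes:
        cls_ages = np.array([a.t_mya for a in ages if a.internal_class == cls])
        for b in range(n_bins):
            lo = b * bin_width_mya
            hi = lo + bin_width_mya
            count = int(np.count_nonzero((cls_ages >= lo) & (cls_ages < hi)))
            rows.append(
                {
                    "internal_class": cls,
                    "bin_start_mya": lo,
                    "bin_end_mya": hi,
                    "count": count,
                }
            )
        rows.append(
            {
                "internal_class": cls,
                "bin_start_mya": max_mya,
                "bin_end_mya": math.inf,
                "count": int(np.count_nonzero(cls_ages >= max_mya)),
            }
        )
    return pd.DataFrame(rows)


def ages_to_frame(ages: Iterable[InsertionAge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_id": a.element_id,
                "internal_class": a.internal_class,
                "K": a.K,
                "rate": a.r,
                "t_mya": a.t_mya,
                "ltr_similarity_pct": a.ltr_similarity_pct,
            }
            for a in ages
        ]
    )
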