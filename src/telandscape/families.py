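"""TE family construction under the Wicker 80%-similarity rule.

Within each superfamily, sequences are grouped so that *every* pair inside
a family shares at least the similarity threshold — the complete-linkage
reading of the 80% rule. A greedy CD-HIT-style mode (longest-first,
join-first-representative) is available for scale; it relaxes the
every-pair guarantee to representative-vs-member similarity.

Identity is matches over alignment columns of a global alignment, gap
columns counting as mismatches. Copy number counts assembly hits covering
at least 80% of the family representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import find_copies, make_aligner, pairwise_identity
from .model import AlignmentHit

FAMILY_IDENTITY_THRESHOLD = 0.80
COPY_COVERAGE_THRESHOLD = 0.80
COPY_BINS = ("1-10", "11-20", ">20")


@dataclass
class TEFamily:
    family_id: str
    superfamily: str
    member_ids: list[str]
    representative_id: str
    copy_number: int = 0

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a family member")


def _representative(member_ids: Sequence[str], sequences: dict[str, str]) -> str:
    """Longest member; ties broken lexicographically by id."""
    return min(member_ids, key=lambda m: (-len(sequences[m]), m))


def cluster_families(
    sequences_by_superfamily: dict[str, dict[str, str]],
    threshold: float = FAMILY_IDENTITY_THRESHOLD,
    method: str = "complete",
    aligner=None,
) -> list[TEFamily]:
    """Partition each superfamily's sequences into families.

    ``method="complete"`` (default) performs complete-linkage hierarchical
    clustering on pairwise distance 1 − identity cut at 1 − threshold, so
    every intra-family pair meets the threshold. ``method="greedy"``
    processes sequences longest-first and joins a sequence to the first
    existing family whose representative it matches at the threshold.
    """
    if aligner is None:
        aligner = make_aligner()
    families: list[TEFamily] = []
    for superfamily in sorted(sequences_by_superfamily):
        seqs = sequences_by_superfamily[superfamily]
        ids = sorted(seqs)
        if not ids:
            continue
        if len(ids) == 1:
            groups = [[ids[0]]]
        elif method == "complete":
            n = len(ids)
            dist = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d = 1.0 - pairwise_identity(seqs[ids[i]], seqs[ids[j]], aligner)
                    dist[i, j] = dist[j, i] = d
            labels = fcluster(
                linkage(squareform(dist), method="complete"),
                t=1.0 - threshold,
                criterion="distance",
            )
            groups = [
                [ids[i] for i in range(n) if labels[i] == lab]
                for lab in sorted(set(labels))
            ]
        elif method == "greedy":
            order = sorted(ids, key=lambda m: (-len(seqs[m]), m))
            reps: list[str] = []
            members: dict[str, list[str]] = {}
            for sid in order:
                for rep in reps:
                    if pairwise_identity(seqs[sid], seqs[rep], aligner) >= threshold:
                        members[rep].append(sid)
                        break
                else:
                    reps.append(sid)
                    members[sid] = [sid]
            groups = [members[rep] for rep in reps]
        else:
            raise ValueError(f"unknown clustering method {method!r}")

        for idx, group in enumerate(
            sorted(groups, key=lambda g: sorted(g)[0])
        ):
            rep = _representative(group, seqs)
            families.append(
                TEFamily(
                    family_id=f"{superfamily.replace('/', '-')}_F{idx:03d}",
                    superfamily=superfamily,
                    member_ids=sorted(group),
                    representative_id=rep,
                )
            )
    return families


def copy_number(
    query_length: int,
    hits: Iterable[AlignmentHit],
    coverage_threshold: float = COPY_COVERAGE_THRESHOLD,
) -> int:
    """Count hits covering ≥ ``coverage_threshold`` of the representative."""
    return sum(
        1 for h in hits if h.matched_bases >= coverage_threshold * query_length
    )


def copy_numbers_from_assembly(
    families: list[TEFamily],
    sequences: dict[str, str],
    assembly,
    coverage_threshold: float = COPY_COVERAGE_THRESHOLD,
    k: int = 15,
) -> None:
    """Fill ``copy_number`` by searching each representative against the
    assembly with the internal seed-and-extend matcher (in place)."""
    for family in families:
        rep_seq = sequences[family.representative_id]
        hits: list[AlignmentHit] = []
        for scaffold_id, seq in assembly.sequences.items():
            hits.extend(
                find_copies(
                    rep_seq,
                    seq,
                    target_id=scaffold_id,
                    query_id=family.representative_id,
                    k=k,
                    min_coverage=coverage_threshold,
                )
            )
        family.copy_number = copy_number(len(rep_seq), hits, coverage_threshold)


def copy_histogram(families: Iterable[TEFamily]) -> pd.DataFrame:
    """Families per superfamily in copy-number bins 1–10 / 11–20 / >20."""
    rows: dict[str, dict[str, int]] = {}
    for family in families:
        sf = family.superfamily
        rows.setdefault(sf, {b: 0 for b in COPY_BINS})
        if family.copy_number <= 10:
            rows[sf]["1-10"] += 1
        elif family.copy_number <= 20:
            rows[sf]["11-20"] += 1
        else:
            rows[sf][">20"] += 1
    return pd.DataFrame(
        [
            {"superfamily": sf, **bins}
            for sf, bins in sorted(rows.items())
        ]
    )


def families_to_frame(families: Iterable[TEFamily]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "superfamily": f.superfamily,
                "n_members": len(f.member_ids),
                "representative_id": f.representative_id,
                "copy_number": f.copy_number,
            }
            for f in families
        ]
    )


def partition_check(families: Sequence[TEFamily], all_ids: Iterable[str]) -> bool:
    """True iff every input sequence appears in exactly one family."""
    seen: list[str] = []
    for family in families:
        seen.extend(family.member_ids)
    return sorted(seen) == sorted(all_ids)
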