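"""Bundled example datasets.

Small published summary tables from the flax (*Linum usitatissimum*) WGS
assembly's TE annotation, shipped as plain TSV. They serve as worked-example
inputs for the tabulation functions (genome TE table, family expression
proportions, nearest-gene distance bins); all percentages are recomputed
from these raw counts at run time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

FLAX_ASSEMBLY_BP = 318_250_901


def _read(name: str) -> pd.DataFrame:
    with resources.files("telandscape.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t", comment="#")


def flax_te_counts() -> tuple[dict[str, tuple[int, int]], int]:
    """Per-superfamily ``(n_matches, bp_occupied)`` plus the assembly size."""
    frame = _read("flax_te_annotation_counts.tsv")
    counts = {
        row.superfamily: (int(row.n_matches), int(row.bp_occupied))
        for row in frame.itertuples(index=False)
    }
    return counts, FLAX_ASSEMBLY_BP


def flax_te_superfamily_order() -> list[str]:
    return list(_read("flax_te_annotation_counts.tsv")["superfamily"])


def flax_family_expression_counts() -> dict[str, tuple[int, int]]:
    """Per-superfamily ``(n_families, n_expressed)``."""
    frame = _read("flax_family_expression_counts.tsv")
    return {
        row.superfamily: (int(row.n_families), int(row.n_expressed))
        for row in frame.itertuples(index=False)
    }


def flax_recent_distance_counts() -> tuple[list[int], list[int]]:
    """Recent-insertion distance-bin counts: (scaffolds ≥ 1 Mb, all scaffolds)."""
    frame = _read("flax_recent_ltr_distance_counts.tsv")
    return (
        [int(v) for v in frame["n_scaffolds_over_1mb"]],
        [int(v) for v in frame["n_all_scaffolds"]],
    )
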