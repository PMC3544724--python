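"""Wicker-style transposable-element taxonomy.

TEs are organised as class (retrotransposon vs DNA transposon), order
(LTR, DIRS, PLE, LINE, SINE, TIR, Helitron) and superfamily (Copia, Gypsy,
L1, Mutator, ...). The mapping from free-text annotation labels — GFF3
types, RepeatMasker class/family strings — to this hierarchy is shipped as
an editable table (``data/taxonomy.tsv``) so that project-specific labels
can be added without touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

UNCLASSIFIED = "unclassified"

TE_CLASSES = ("retrotransposon", "DNA-transposon", UNCLASSIFIED)
TE_ORDERS = ("LTR", "DIRS", "PLE", "LINE", "SINE", "TIR", "Helitron", UNCLASSIFIED)


@lru_cache(maxsize=1)
def _load_table() -> tuple[dict[str, tuple[str, str]], dict[str, str]]:
    """Return (superfamily -> (order, class), alias(lower) -> superfamily)."""
    hierarchy: dict[str, tuple[str, str]] = {}
    aliases: dict[str, str] = {}
    text = resources.files("telandscape.data").joinpath("taxonomy.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"malformed taxonomy row: {line!r}")
        superfamily, order, te_class, alias_field = fields
        hierarchy[superfamily] = (order, te_class)
        aliases[superfamily.lower()] = superfamily
        for alias in alias_field.split("|"):
            aliases[alias.strip().lower()] = superfamily
    return hierarchy, aliases


def known_superfamilies() -> list[str]:
    return list(_load_table()[0])


def order_of(superfamily: str) -> str:
    hierarchy, _ = _load_table()
    return hierarchy.get(superfamily, (UNCLASSIFIED, UNCLASSIFIED))[0]


def class_of(superfamily: str) -> str:
    hierarchy, _ = _load_table()
    return hierarchy.get(superfamily, (UNCLASSIFIED, UNCLASSIFIED))[1]


def classify_label(label: str) -> tuple[str, str, str]:
    """Map a free-text repeat label to ``(superfamily, order, te_class)``.

    Tries the full label first (e.g. ``LTR/Copia``), then the part after a
    ``/`` (RepeatMasker convention), then the part before. Unknown labels map
    to the unclassified superfamily rather than raising: downstream
    statistics treat unclassified as its own category, mirroring how genome
    annotation tables report repeats the databases could not place.
    """
    _, aliases = _load_table()
    candidates = [label]
    if "/" in label:
        head, _, tail = label.partition("/")
        candidates.extend([tail, head])
    for candidate in candidates:
        superfamily = aliases.get(candidate.strip().lower())
        if superfamily is not None:
            return superfamily, order_of(superfamily), class_of(superfamily)
    return UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED
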