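"""Synthetic assemblies with known TE content, ages and expression.

The generator emulates the study conditions the downstream statistics were
designed for:

* multi-scaffold assemblies in three density regimes — TE-rich, gene-rich,
  and balanced;
* TE insertions drawn from a library of family templates labelled with
  Wicker superfamilies (Copia-dominated mix by default, matching the
  genome-wide superfamily proportions of a Copia-rich eudicot assembly);
* full-length LTR retroelements whose two LTRs diverge under a Kimura
  2-parameter substitution process, so the planted pairwise divergence (and
  hence insertion age at a given substitution rate) is known exactly;
* EST pools sampled as exact substrings of a known expressed subset of
  genes and TE families.

Background sequence is i.i.d. uniform over {A, C, G, T}; gene placements
never overlap each other, TE placements never overlap each other (nesting
can be enabled for stress tests), and TEs may overlap genes. Every emitted
annotation is logged in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .intervals import GenomicInterval, merge_intervals, total_bp
from .model import Assembly, GeneAnnotation, LTRElement, TEAnnotation
from .taxonomy import order_of

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default superfamily weights for TE placement (fractions of TE copies).
DEFAULT_SUPERFAMILY_MIX: dict[str, float] = {
    "Copia": 0.40,
    "Gypsy": 0.34,
    "L1": 0.09,
    "Mutator": 0.09,
    "hAT": 0.03,
    "En-Spm/CACTA": 0.03,
    "Helitron": 0.01,
    "Harbinger": 0.01,
}


@dataclass
class RegimeSpec:
    """Density regime for one synthetic scaffold."""

    regime: str  # te_rich | gene_rich | balanced
    scaffold_length: int = 1_000_000
    target_te_coverage: float = 0.25
    target_gene_coverage: float = 0.25
    superfamily_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPERFAMILY_MIX)
    )
    gene_length_range: tuple[int, int] = (1_000, 5_000)

    def __post_init__(self) -> None:
        for name, value in (
            ("target_te_coverage", self.target_te_coverage),
            ("target_gene_coverage", self.target_gene_coverage),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.target_te_coverage + self.target_gene_coverage > 0.95:
            raise ValueError("combined target coverage above 0.95 is not packable")
        weight_sum = sum(self.superfamily_mix.values())
        if self.superfamily_mix and abs(weight_sum - 1.0) > 1e-6:
            raise ValueError(f"superfamily weights must sum to 1, got {weight_sum}")


def default_regime(kind: str, scaffold_length: int = 1_000_000) -> RegimeSpec:
    """Canonical parameterisations of the three density regimes."""
    presets = {
        "te_rich": (0.55, 0.10),
        "balanced": (0.25, 0.25),
        "gene_rich": (0.05, 0.55),
    }
    if kind not in presets:
        raise ValueError(f"unknown regime {kind!r}; choose from {sorted(presets)}")
    te_cov, gene_cov = presets[kind]
    return RegimeSpec(
        regime=kind,
        scaffold_length=scaffold_length,
        target_te_coverage=te_cov,
        target_gene_coverage=gene_cov,
    )


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

@dataclass
class TETruth:
    annotation: TEAnnotation
    family_id: str
    age_mya: Optional[float] = None


@dataclass
class GeneTruth:
    annotation: GeneAnnotation
    expressed: bool = False


@dataclass
class TruthTable:
    te_records: list[TETruth] = field(default_factory=list)
    gene_records: list[GeneTruth] = field(default_factory=list)
    est_origin: dict[str, str] = field(default_factory=dict)

    def extend(self, other: "TruthTable") -> None:
        self.te_records.extend(other.te_records)
        self.gene_records.extend(other.gene_records)
        self.est_origin.update(other.est_origin)

    def te_annotations(self) -> list[TEAnnotation]:
        return [rec.annotation for rec in self.te_records]

    def gene_annotations(self) -> list[GeneAnnotation]:
        return [rec.annotation for rec in self.gene_records]

    def expressed_feature_ids(self) -> set[str]:
        return {rec.annotation.gene_id for rec in self.gene_records if rec.expressed}

    def te_bp_by_superfamily(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.te_records:
            sf = rec.annotation.superfamily
            out[sf] = out.get(sf, 0) + rec.annotation.interval.length
        return out


# ---------------------------------------------------------------------------
# TE family library
# ---------------------------------------------------------------------------

@dataclass
class FamilyTemplate:
    family_id: str
    superfamily: str
    sequence: str
    ltr_length: Optional[int] = None  # set for LTR-order families

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_ltr(self) -> bool:
        return self.ltr_length is not None


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def build_te_library(
    n_families: int,
    superfamily_mix: dict[str, float] | None = None,
    ltr_length: int = 400,
    internal_length: int = 4_500,
    seed: int | np.random.Generator = 0,
    non_ltr_length_range: tuple[int, int] = (800, 3_000),
) -> dict[str, FamilyTemplate]:
    """Random family templates, allocated across superfamilies by weight.

    LTR-order families get identical left/right LTR blocks flanking an
    internal block (total length ``2*ltr_length + internal_length``, 5.3 kb
    at the defaults — a typical full-length Copia element). Independent
    random templates share ~25% identity, so two families of one superfamily
    are far below any clustering threshold by construction.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if ltr_length <= 0 or internal_length <= 0:
        raise ValueError("ltr_length and internal_length must be positive")
    mix = dict(superfamily_mix or DEFAULT_SUPERFAMILY_MIX)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    superfamilies = sorted(mix)
    weights = np.array([mix[sf] for sf in superfamilies], dtype=float)
    weights = weights / weights.sum()
    counts = np.maximum(1, np.round(weights * n_families).astype(int))
    # trim/grow largest allocations until totals match n_families
    while counts.sum() > max(n_families, len(superfamilies)):
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_families:
        counts[np.argmax(weights)] += 1

    library: dict[str, FamilyTemplate] = {}
    for sf, count in zip(superfamilies, counts):
        for idx in range(count):
            family_id = f"{sf.replace('/', '-')}_fam{idx:03d}"
            if order_of(sf) == "LTR":
                ltr = random_sequence(ltr_length, rng)
                internal = random_sequence(internal_length, rng)
                template = FamilyTemplate(family_id, sf, ltr + internal + ltr, ltr_length)
            else:
                length = int(rng.integers(*non_ltr_length_range))
                template = FamilyTemplate(family_id, sf, random_sequence(length, rng))
            library[family_id] = template
    return library


# ---------------------------------------------------------------------------
# K2P substitution process
# ---------------------------------------------------------------------------

def k2p_event_probabilities(distance: float, kappa: float) -> tuple[float, float]:
    """Expected (transition, transversion) proportions at a K2P distance.

    Rates are normalised to one substitution per unit distance, with
    transition:transversion *rate* ratio ``kappa`` (two transversion
    channels, so instantaneous ts:tv flux is ``kappa : 2``).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    p = 0.25 + 0.25 * np.exp(-4 * beta * distance) - 0.5 * np.exp(
        -2 * (alpha + beta) * distance
    )
    q = 0.5 - 0.5 * np.exp(-4 * beta * distance)
    return float(p), float(q)


def _evolve(enc: np.ndarray, distance: float, kappa: float, rng: np.random.Generator):
    """One branch of K2P evolution on an encoded (A0 C1 G2 T3) sequence."""
    p, q = k2p_event_probabilities(distance, kappa)
    u = rng.random(len(enc))
    out = enc.copy()
    transition = (u >= 1 - p - q) & (u < 1 - q)
    tv1 = (u >= 1 - q) & (u < 1 - q / 2)
    tv2 = u >= 1 - q / 2
    out[transition] ^= 2  # A<->G, C<->T
    out[tv1] ^= 1
    out[tv2] ^= 3
    return out


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def mutate_ltr_pair(
    template_ltr: str,
    K_true: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """Derive a diverged LTR pair from one template.

    Each copy evolves along an independent branch of length ``K_true / 2``,
    so the expected pairwise K2P distance between the two copies is
    ``K_true`` (the process is time-reversible and additive). Raises when
    the requested divergence is saturated (expected ``1 − 2P − Q ≤ 0``).
    """
    if K_true < 0:
        raise ValueError("K_true must be >= 0")
    # In expectation 1-2P-Q = exp(-2(alpha+beta)·K) stays positive for any
    # finite K, but once it nears zero, sampling noise routinely drives the
    # realized proportions past the singularity and the distance becomes
    # uninvertible. Refuse divergences past that practical floor.
    p_pair, q_pair = k2p_event_probabilities(K_true, kappa)
    if 1 - 2 * p_pair - q_pair <= 0.05 or 1 - 2 * q_pair <= 0.05:
        raise ValueError(
            f"K_true={K_true} saturates the K2P process "
            "(expected 1-2P-Q at or below the invertibility floor); "
            "use a lower divergence"
        )
    if K_true == 0:
        return template_ltr, template_ltr
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    enc = _CODE[np.frombuffer(template_ltr.upper().encode("ascii"), dtype=np.uint8)]
    left = _evolve(enc, K_true / 2, kappa, rng)
    right = _evolve(enc, K_true / 2, kappa, rng)
    decode = lambda arr: _DECODE[arr.astype(np.intp)].tobytes().decode("ascii")
    return decode(left), decode(right)


# ---------------------------------------------------------------------------
# Scaffold simulation
# ---------------------------------------------------------------------------

class PackingError(RuntimeError):
    """Raised when target coverage cannot be packed after bounded retries."""


def _place_nonoverlapping(
    length: int,
    element_length: int,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
    max_tries: int = 2_000,
) -> int:
    """Uniform random start that avoids all ``occupied`` spans (same track)."""
    if element_length > length:
        raise PackingError(f"element of {element_length} bp exceeds scaffold")
    for _ in range(max_tries):
        start = int(rng.integers(0, length - element_length + 1))
        end = start + element_length
        if all(min(end, e) - max(start, s) <= 0 for s, e in occupied):
            return start
    raise PackingError(
        f"could not place a {element_length} bp element after {max_tries} tries"
    )


def simulate_scaffold(
    spec: RegimeSpec,
    te_library: dict[str, FamilyTemplate],
    seed: int | np.random.Generator = 0,
    scaffold_id: str = "scaffold_1",
    allow_te_nesting: bool = False,
    allow_te_gene_overlap: bool = True,
) -> tuple[str, TruthTable]:
    """Build one scaffold sequence plus its truth-table fragment.

    Returns ``(sequence, truth)``. Genes never overlap genes; TEs never
    overlap TEs unless ``allow_te_nesting``; TEs may overlap genes. Realized
    coverage stops at the first element crossing the target, so it lands
    within one element length of the target (well inside ±20% relative for
    megabase scaffolds).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = spec.scaffold_length
    seq = bytearray(random_sequence(length, rng), "ascii")
    truth = TruthTable()

    # When TEs must avoid genes, the larger TE elements are placed first and
    # the (smaller) genes packed around them; otherwise genes go first and
    # TEs land independently, overlapping genes at the rate chance dictates.
    te_spans: list[tuple[int, int]] = []
    if not allow_te_gene_overlap:
        _place_tes(spec, te_library, seq, te_spans, [], truth, scaffold_id,
                   rng, allow_te_nesting)

    # --- genes ---
    gene_spans: list[tuple[int, int]] = []
    gene_target_bp = spec.target_gene_coverage * length
    placed_bp = 0
    gene_idx = 0
    while placed_bp < gene_target_bp:
        gene_len = int(rng.integers(*spec.gene_length_range))
        occupied = gene_spans if allow_te_gene_overlap else gene_spans + te_spans
        start = _place_nonoverlapping(length, gene_len, occupied, rng)
        gene_spans.append((start, start + gene_len))
        placed_bp += gene_len
        annotation = GeneAnnotation(
            interval=GenomicInterval(scaffold_id, start, start + gene_len, "+"),
            gene_id=f"{scaffold_id}_gene{gene_idx:04d}",
        )
        truth.gene_records.append(GeneTruth(annotation))
        gene_idx += 1

    # --- TEs (when they may overlap genes) ---
    if allow_te_gene_overlap:
        _place_tes(spec, te_library, seq, te_spans, [], truth, scaffold_id,
                   rng, allow_te_nesting)

    return seq.decode("ascii"), truth


def _place_tes(
    spec: RegimeSpec,
    te_library: dict[str, FamilyTemplate],
    seq: bytearray,
    te_spans: list[tuple[int, int]],
    forbidden: list[tuple[int, int]],
    truth: TruthTable,
    scaffold_id: str,
    rng: np.random.Generator,
    allow_te_nesting: bool,
) -> None:
    length = spec.scaffold_length
    families = sorted(te_library)
    sf_of = {fid: te_library[fid].superfamily for fid in families}
    weights = np.array(
        [spec.superfamily_mix.get(sf_of[fid], 0.0) for fid in families], dtype=float
    )
    te_target_bp = spec.target_te_coverage * length
    if te_target_bp <= 0:
        return
    if weights.sum() == 0:
        raise ValueError("superfamily_mix assigns zero weight to every library family")
    # weight families so that each superfamily's *copy* share follows the mix
    per_family = weights.copy()
    for sf in set(sf_of.values()):
        members = [i for i, fid in enumerate(families) if sf_of[fid] == sf]
        for i in members:
            per_family[i] = weights[i] / len(members)
    per_family = per_family / per_family.sum()
    placed_bp = 0
    while placed_bp < te_target_bp:
        fid = families[int(rng.choice(len(families), p=per_family))]
        template = te_library[fid]
        occupied = list(forbidden) if allow_te_nesting else list(te_spans) + forbidden
        start = _place_nonoverlapping(length, template.length, occupied, rng)
        end = start + template.length
        seq[start:end] = template.sequence.encode("ascii")
        te_spans.append((start, end))
        placed_bp = total_bp(merge_intervals(te_spans))
        annotation = TEAnnotation(
            interval=GenomicInterval(scaffold_id, start, end, "+"),
            superfamily=template.superfamily,
            family_id=fid,
            source="sim",
        )
        truth.te_records.append(TETruth(annotation, family_id=fid))


def simulate_genome(
    regimes: list[RegimeSpec],
    te_library: dict[str, FamilyTemplate] | None = None,
    n_families: int = 20,
    seed: int = 0,
    allow_te_gene_overlap: bool = True,
) -> tuple[Assembly, TruthTable]:
    """Simulate one scaffold per regime spec into a single assembly."""
    rng = np.random.default_rng(seed)
    if te_library is None:
        te_library = build_te_library(n_families, seed=rng)
    assembly = Assembly()
    truth = TruthTable()
    for idx, spec in enumerate(regimes, start=1):
        scaffold_id = f"scaffold_{idx:03d}_{spec.regime}"
        sequence, fragment = simulate_scaffold(
            spec, te_library, seed=rng, scaffold_id=scaffold_id,
            allow_te_gene_overlap=allow_te_gene_overlap,
        )
        assembly.add(scaffold_id, sequence=sequence)
        truth.extend(fragment)
    return assembly, truth


# ---------------------------------------------------------------------------
# EST sampling
# ---------------------------------------------------------------------------

def sample_ests(
    truth: TruthTable,
    assembly: Assembly,
    te_library: dict[str, FamilyTemplate],
    expressed_fraction: float = 0.3,
    n_ests: int = 500,
    length_range: tuple[int, int] = (200, 600),
    seed: int | np.random.Generator = 0,
    error_rate: float = 0.0,
) -> dict[str, str]:
    """Sample an EST pool from a randomly chosen expressed subset.

    Marks ``expressed_fraction`` of genes (in the truth table, in place) and
    of TE families as expressed, then draws ESTs as exact substrings of
    expressed features — gene sequences are read from the assembly, family
    ESTs from the family template. ``error_rate`` optionally applies uniform
    base errors for robustness testing; the default pool is error-free so
    coverage rules behave deterministically. Returns ``est_id -> sequence``
    and records each EST's source feature in ``truth.est_origin``.
    """
    if not 0.0 <= expressed_fraction <= 1.0:
        raise ValueError("expressed_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_genes = len(truth.gene_records)
    expressed_gene_idx = set(
        rng.choice(n_genes, size=int(round(expressed_fraction * n_genes)), replace=False)
        .tolist()
    ) if n_genes else set()
    for i, rec in enumerate(truth.gene_records):
        rec.expressed = i in expressed_gene_idx

    family_ids = sorted(te_library)
    n_expr_fam = int(round(expressed_fraction * len(family_ids)))
    expressed_families = sorted(
        rng.choice(len(family_ids), size=n_expr_fam, replace=False).tolist()
    )
    expressed_family_ids = [family_ids[i] for i in expressed_families]

    sources: list[tuple[str, str]] = []  # (feature_id, sequence)
    for i in sorted(expressed_gene_idx):
        annotation = truth.gene_records[i].annotation
        iv = annotation.interval
        seq = assembly.sequences[iv.scaffold_id][iv.start : iv.end]
        sources.append((annotation.gene_id, seq))
    for fid in expressed_family_ids:
        sources.append((fid, te_library[fid].sequence))

    ests: dict[str, str] = {}
    if not sources:
        return ests
    for est_idx in range(n_ests):
        feature_id, seq = sources[int(rng.integers(0, len(sources)))]
        lo, hi = length_range
        if lo > len(seq):
            raise ValueError(
                f"EST length range {length_range} exceeds source length {len(seq)}"
            )
        est_len = int(rng.integers(lo, min(hi, len(seq)) + 1))
        start = int(rng.integers(0, len(seq) - est_len + 1))
        est = seq[start : start + est_len]
        if error_rate > 0:
            enc = _CODE[np.frombuffer(est.encode("ascii"), dtype=np.uint8)]
            hit = rng.random(len(enc)) < error_rate
            shift = rng.integers(1, 4, size=len(enc))
            enc = np.where(hit, (enc + shift) % 4, enc)
            est = _DECODE[enc.astype(np.intp)].tobytes().decode("ascii")
        est_id = f"est_{est_idx:05d}"
        ests[est_id] = est
        truth.est_origin[est_id] = feature_id
    return ests


# ---------------------------------------------------------------------------
# LTR cohorts of known age
# ---------------------------------------------------------------------------

def simulate_ltr_cohort(
    ages_mya: list[float],
    n_per_age: int,
    ltr_length: int = 1_000,
    internal_length: int = 3_000,
    rate: float = 1.5e-8,
    kappa: float = 2.0,
    internal_class: str = "copia",
    seed: int | np.random.Generator = 0,
) -> tuple[list[LTRElement], dict[str, float]]:
    """Full-length LTR elements with LTR pairs diverged to known ages.

    The planted pairwise divergence for age ``t`` (Mya) at substitution rate
    ``r`` (per site per year) is ``K = 2 r t·1e6``, inverting the dating
    relation ``t = K / 2r``. Each element gets an independent template.
    Returns the elements and a truth map ``element_id -> age_mya``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    elements: list[LTRElement] = []
    truth_ages: dict[str, float] = {}
    for age in ages_mya:
        K_true = 2.0 * rate * age * 1e6
        for i in range(n_per_age):
            element_id = f"ltr_{internal_class}_{age:g}mya_{i:03d}"
            template_ltr = random_sequence(ltr_length, rng)
            internal = random_sequence(internal_length, rng)
            left, right = mutate_ltr_pair(template_ltr, K_true, kappa, rng)
            total = 2 * ltr_length + internal_length
            elements.append(
                LTRElement(
                    element_id=element_id,
                    element_interval=GenomicInterval(element_id, 0, total),
                    left_ltr_seq=left,
                    right_ltr_seq=right,
                    internal_class=internal_class,
                )
            )
            truth_ages[element_id] = age
    return elements, truth_ages


def element_sequence(element: LTRElement, internal: str | None = None) -> str:
    """Concatenated element sequence (random internal filler if none stored)."""
    if internal is None:
        internal = ""
    return element.left_ltr_seq + internal + element.right_ltr_seq


def plant_sequences(
    scaffold_length: int,
    inserts: list[tuple[str, str, int]],
    seed: int | np.random.Generator = 0,
    scaffold_id: str = "scaffold_planted",
) -> tuple[str, list[tuple[str, GenomicInterval]]]:
    """Plant verbatim copies of sequences into a random background.

    ``inserts`` is a list of ``(insert_id, sequence, n_copies)``. Copies
    never overlap one another. Returns the scaffold sequence and the list of
    ``(insert_id, interval)`` placements.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = bytearray(random_sequence(scaffold_length, rng), "ascii")
    occupied: list[tuple[int, int]] = []
    placements: list[tuple[str, GenomicInterval]] = []
    for insert_id, insert_seq, n_copies in inserts:
        for _ in range(n_copies):
            start = _place_nonoverlapping(scaffold_length, len(insert_seq), occupied, rng)
            end = start + len(insert_seq)
            seq[start:end] = insert_seq.encode("ascii")
            occupied.append((start, end))
            placements.append((insert_id, GenomicInterval(scaffold_id, start, end)))
    return seq.decode("ascii"), placements
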