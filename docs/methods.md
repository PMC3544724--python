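# Methods

This note documents the models, rules and numerical choices behind
`telandscape`, in the order the pipeline applies them.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open `[start, end)`; GFF3 I/O
converts from/to 1-based inclusive at the file boundary. Interval length is
always `end − start`. The midpoint of an interval is
`start + floor(length/2)`; for even lengths this rounds down, a fixed
convention so the midpoint rule used by the proximity tests is
deterministic. Strand is parsed and round-tripped but ignored by every
spatial statistic. Coverage, overlap and flank construction all run on
merged (union) span lists; nested or duplicated annotations therefore never
push a coverage fraction above 1 or double-count overlap bases.

## Repeat curation

Candidate repeats from de novo finders are filtered and annotated, never
re-discovered: the homology searches are consumed as 12-column tabular hit
files. Rules:

* **Low-copy filter** — a candidate needs ≥ 10 hits against the genome
  (`min_hits`, configurable); fewer hits suggest a gene family or
  pseudogene rather than a mobile element. The boundary (exactly 10)
  passes.
* **Database voting** — a superfamily label is accepted only when hits
  carrying it at E ≤ 1e-5 occur in at least two distinct databases.
  "At least 1e-5" is read as a significance floor, so E = 1e-5 itself
  votes. When several labels satisfy the rule the one with the smallest
  best E-value wins, then lexicographic order; both tie-breaks are logged.
  The decision is invariant to hit-list order.
* **Redundancy removal** — greedy longest-first clustering at 90% global
  identity (the threshold is not standardised; it is configurable).
* **Low-complexity screen** — a whole-sequence Shannon-entropy flag
  (< 1.5 bits/symbol) marks suspicious candidates but never removes them;
  dedicated tandem/low-complexity maskers are out of scope.

## Family clustering and copy number

Within each superfamily, sequences are partitioned into families so that
*every* intra-family pair shares ≥ 80% identity — the strict reading of the
Wicker 80% rule, implemented as complete-linkage hierarchical clustering on
distance 1 − identity cut at 0.20. A greedy longest-first mode
(representative-vs-member similarity only, CD-HIT-like) is available for
larger inputs. Identity is matches over all alignment columns of a global
alignment (match +1, mismatch −1, gap open −5, gap extend −1 by default),
with gap columns counting as non-matches; this "aligned-columns"
denominator is a documented choice where conventions differ. Because
co-optimal global alignments can differ in match/gap composition, the
identity function canonicalises its argument order so it is exactly
symmetric.

The family representative is the longest member (ties broken by id). Copy
number counts assembly hits covering ≥ 80% of the representative. Hits come
either from PSL files or from the internal search: exact 15-mer seeding on
a rolling 2-bit hash, diagonal voting, gapless extension, and greedy
non-maximum suppression of overlapping hits. The internal matcher is
gapless by design — sufficient for locating planted or substituted copies
at desk scale; genome-scale projects would feed BLAT/RepeatMasker output
instead.

## Expression proxies

An EST hit is positive when matched bases cover ≥ 70% of the **EST**
(never the feature it hits); a feature is putatively expressed with at
least one positive EST, each distinct EST counting once per feature
(deduplication by EST id — the alternative, counting every hit, is a
flag). Per-superfamily summaries report families, expressed families and
the percentage to two decimals. Per-scaffold gene-expression fractions
pair with TE proportional coverage for the expression-vs-TE correlation;
degenerate inputs (zero variance, < 3 scaffolds) produce an explicit
not-computable result rather than NaN.

## Landscape statistics

Proportional coverage of a feature set over a region is union bp /
region length. Windowed tracks use 50-kb bins; the final partial bin is
normalised by its true length, so bin value × bin length sums exactly to
union coverage bp. Correlations are ordinary Pearson product-moment
coefficients (scipy), restricted by default to scaffolds ≥ 1 Mb for real
assemblies (configurable; synthetic runs use 0). The genome TE table
reports, per superfamily: match count, % of matches, occupied bp, % of TE
bp, and % of genome, each rounded to two decimals. The genome denominator
deliberately includes N/X runs. The totals row recomputes its percentages
from the column totals (hence 100.00 for the two share columns) rather
than summing rounded rows, so rounding drift cannot leak into totals.

## Monte-Carlo overlap testing

The test statistic per analysis unit (a scaffold, or a 50-kb bin) is the
number of base pairs in (union of TEs) ∩ (union of genes); a count-based
statistic (number of TEs touching a gene) exists behind a flag. The null
model fixes gene positions and every TE length, placing each TE
independently and uniformly within the unit; TE–TE overlap is allowed in
the null, and TEs straddling a bin boundary enter with their clipped
length. The p-value is the add-one permutation estimator
`p = (k+1)/(n+1)`, strictly in (0, 1]; exceedance is `null ≥ observed`
(ties count, conservative).

Sampling per unit stops when at least 100 samples have been drawn **and**
20 exceedances observed (20 exceedances bound the relative error of the
estimate regardless of p), or at a sample cap. Across units the schedule is
round-robin; after each chunk a Benjamini–Hochberg pass at FDR 0.05
classifies the current estimates, units retire at their exceedance
threshold or cap, and a final BH pass produces the rejection calls. Under
a global null this yields approximately uniform p-values (checked by
Kolmogorov–Smirnov on 200 simulated units) and almost never rejects.

## Proximity bias

A TE belongs to a region iff its midpoint lies inside it (half-open: a
midpoint at a gene start is inside, at a gene end is outside). Regions are
gene bodies (merged), and 1-kb / 5-kb flanks — built by extending merged
gene bodies, merging across neighbouring genes, and subtracting the bodies;
the 5-kb flank is the full 0–5,000 bp zone and contains the 1-kb zone.
Midpoints partition, so per-superfamily in-region counts sum to the
region's total.

Each superfamily is tested one-vs-rest with a 2×2 Pearson chi-square
(df = 1, no continuity correction); direction comes from the sign of
observed − expected, and significance tiers use the conventional
Bonferroni-corrected display thresholds p < 5e-3 (single) and p < 5e-4
(double), applied as given. Zero-margin tables return a not-computable
result. Note an inherent property of the one-vs-rest design: when one
strongly biased superfamily makes up a large share of all elements, the
complementary superfamilies legitimately register as under-represented;
calibration is therefore assessed on all-null placements.

## LTR insertion dating

An element's two LTRs are identical at insertion; divergence between them
accumulates at twice the per-copy rate. The pipeline globally aligns the
pair (same scoring as family identity; for two sequences a pairwise global
alignment is equivalent in result class to running a multiple aligner on
two sequences), excludes columns with a gap or an ambiguous base from the
substitution counts (standard distance practice; a documented choice where
conventions differ), and computes the Kimura 2-parameter distance

    K = −½ · ln((1 − 2P − Q) · √(1 − 2Q))

from transition (P) and transversion (Q) proportions. `1−2P−Q ≤ 0` or
`1−2Q ≤ 0` is a saturation error; saturated elements are excluded from
dating with a log entry. Age is `t = K / 2r` with `r = 1.5e-8`
substitutions/site/year by default (a plant nuclear rate widely used for
retroelement dating; `--rate` overrides). Intra-element LTR similarity is
matches over all alignment columns (gaps count against it), consistent
with the clustering identity, so similarity = 100% ⟺ P = Q = 0 ⟺ t = 0.
Age histograms are left-closed with a configurable bin width; elements
older than the display maximum (15 Mya default) are tallied separately
rather than folded into the last bin.

Recent elements are exactly those with 100.0% similarity. Exact
re-mapping keeps only full-length perfect hits (matched bases = query
length, zero gaps, zero mismatches); relaxed mode keeps hits covering
≥ 80% of the query, so exact sites ⊆ relaxed sites. Nearest-gene distances
(0 when overlapping a gene) are binned 0–1000 / 1001–2000 / … / >5000 with
inclusive upper bounds (distance 1000 is in the first bin) and proportions
to two decimals.

## The synthetic-data generator

`telandscape.sim` emulates the study conditions the statistics were built
for:

* **Regimes** — one scaffold per regime; defaults are TE-rich (55% TE /
  10% gene), balanced (25% / 25%) and gene-rich (5% / 55%) target
  coverages, spanning the density spectrum a real assembly's scaffolds
  exhibit. Realized coverage stops at the first element crossing the
  target, i.e. within one element length.
* **TE library** — per-family random templates; LTR-order families are
  two identical 400-bp LTRs flanking a 4.5-kb internal region (5.3 kb
  total, a typical full-length Copia element); other orders draw lengths
  from 0.8–3 kb. The default superfamily mix (Copia 0.40, Gypsy 0.34,
  L1 0.09, Mutator 0.09, hAT 0.03, CACTA 0.03, Helitron 0.01,
  Harbinger 0.01) follows the genome-wide proportions of a Copia-dominated
  eudicot assembly. Independent random templates share ~25% identity, so
  distinct families are far below the 80% threshold by construction.
* **Placement** — genes (1–5 kb, uniform) never overlap genes; TEs never
  overlap TEs (nesting available behind a flag for stress tests); TEs may
  overlap genes by default. With `allow_te_gene_overlap=False` the larger
  TEs are placed first and genes packed around them (gene-rich regimes are
  otherwise unpackable for 5.3-kb elements); that mode is used when
  expression truth must be unambiguous, because a TE copy inside a gene
  makes an EST from either feature legitimately match both.
* **LTR divergence** — each LTR copy evolves along an independent branch
  of length K/2 under a K2P process with transition:transversion rate
  ratio κ = 2 (rates normalised to one substitution per unit distance;
  per-branch substitution types sampled from the exact K2P transition
  probabilities), so the expected pairwise distance is exactly the planted
  K = 2·r·t. Because the expectation of 1−2P−Q decays as exp(−2(α+β)K)
  but never reaches zero, the generator refuses divergences where that
  expectation drops to ≤ 0.05 — beyond it, sampling noise routinely
  crosses the estimator's singularity. No indels, solo-LTR formation or
  recombination are simulated.
* **ESTs** — exact substrings (150–600 bp) of a randomly chosen expressed
  subset of genes and family templates, origins recorded; an optional
  uniform error rate exists for robustness tests.

What the generator does **not** emulate — realistic base composition
(background is i.i.d. uniform), TE nesting by default, truncated/decayed
copies, sequencing error in ESTs, poly-A selection bias — bounds what
passing tests show: they validate the statistical machinery and the
published arithmetic, not performance on real, noisy annotations.

## Sizes, determinism, limitations

Everything is deterministic under a master seed (NumPy `default_rng`;
stage seeds derived from it). Default desk-scale sizes: 100–200 kb
scaffolds (2–6 per run), 8–12 families, 60–150 ESTs, 200 Monte-Carlo
units for calibration, 50-unit FDR runs, 100-element dating cohorts with
1-kb LTRs, 1,000 random fixtures for the coverage oracle; the full test
suite runs in well under a minute. The end-to-end pipeline lowers the
low-copy curation threshold to 2 because synthetic genomes plant only a
few copies per family; the module default remains 10, the value
appropriate to a genome-scale candidate library.

Known limitations: the internal copy matcher is gapless (use external PSL
hits when indel-diverged copies matter); complete-linkage clustering is
quadratic in family-member count per superfamily; the one-vs-rest bias
test is a composition, not an absolute enrichment, statistic; and dating
assumes equal rates in both LTRs and no gene conversion between them.
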