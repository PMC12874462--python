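# Methods

## Data model and coordinate conventions

All upstream annotations are reduced to one row per element: a 1-based
inclusive interval on a contig with one of five categories (BGC,
defense system, CRISPR array, Cas cluster, prophage), a free-text subtype
and a source tag.  1-based inclusive is the native convention of GFF3 and
of the printed locus spans the package reproduces; BED input is converted
on ingest (0-based half-open → 1-based inclusive) and back on egest.
Anti-defense systems are stored as defense systems with an `anti:` subtype
prefix and count as defensive elements for island membership.  Hybrid BGCs
are one physical locus whose subtype is a comma-joined sorted list of
product classes.  Strand is carried but ignored by clustering: island
membership is a property of physical position, not orientation.  Within a
contig, features are totally ordered by `(start, end, feature_id)`;
identical spans tie-break lexicographically on id, which makes member order
and island ids reproducible.

## Island detection

**Gap.** The intervening distance between two intervals is the number of
bases strictly between their spans, `max(0, b.start − a.end − 1)`.
Overlapping or abutting elements (next start = previous end + 1) have gap 0
and always chain.  The threshold test is `gap ≤ max_gap_bp` with a default
of 50,000 bp — a locus-interaction range within which functionally linked
defense elements are commonly found.  The arithmetic convention is one
design choice among off-by-one variants; every reference locus passes under
all of them, and the threshold is configurable.

**Chaining.** Clusters are the connected components of the pairwise
relation `gap ≤ max_gap_bp` (single linkage).  The implementation is a
sweep over the sorted features that tracks the running maximum end and
breaks whenever the next start lies more than the threshold past it.  This
is exactly the transitive closure: a later feature's start is ≥ the break
point, so nothing can link back across a break; and within a run, each
feature is within threshold of whichever earlier feature achieved the
maximum end.  The sweep matters when a long element (a prophage, a large
BGC) fully contains shorter ones — the naive "gap to the immediately
preceding feature" rule would split chains the closure keeps together.
Each island's `gaps_bp` records, for every member after the first, its
intervening distance beyond the region chained so far; for non-nested
members this equals the adjacent-pair gap, and every recorded gap is ≤ the
threshold by construction.

**Classification.** An island needs a metabolic anchor (≥ 1 BGC) and at
least one non-metabolic element; clusters failing this (BGC-only runs,
defense-only runs, lone prophages) are reported separately as non-island
clusters.  The label is a pure function of the member category set,
subtyping the defensive component:

| categories present (besides BGC) | label |
|---|---|
| defense system only | defense-metabolite |
| CRISPR array only | CRISPR-metabolite |
| Cas cluster only | Cas-metabolite |
| CRISPR + Cas (± defense) | combined CRISPR-Cas-defense-metabolite |
| CRISPR + defense (no Cas) | CRISPR-defense-metabolite |
| Cas + defense (no CRISPR) | Cas-defense-metabolite |
| prophage only | prophage-metabolite |
| prophage + any defensive | prophage-defensive-metabolic |

The two compound labels cover category combinations the reference survey
never exhibited; they keep the function total and deterministic on unseen
inputs.  Overlapping members are recorded pairwise with the relation taken
from the sort-order-first feature's viewpoint (`contains`, `contained_by`,
`identical`, `partial`) and the overlap width in bp.

## Prophage triage

Completeness scores triage into incomplete (< 70), questionable
(70–90 inclusive) and intact (> 90); records without a score are `unscored`
rather than rejected, since some predictors emit only CheckV-style
completeness/contamination estimates.  The high-quality gate takes the
wording "more than 90 % completeness and less than 5 % contamination"
literally: both inequalities are strict, so 90.0/5.0 fail.  Users can relax
this through `Thresholds`.  Summary statistics are plain arithmetic means
and extrema, reported at full precision; published figures appear truncated
(56.366 → "56.36"), so comparisons in the tests use ±0.01.  An optional
coordinate-overlap collapse utility deduplicates calls from different
predictors at a default 50 % reciprocal-of-shorter overlap; that default is
pragmatic, not survey-derived.

## Spacer screening

A hit is a perfect, full-length, zero-mismatch occurrence of the spacer on
either strand of the target; under this rule an alignment e-value filter
cannot reject any hit on realistic sequence sizes, so the e-value threshold
is documented in `Thresholds` but never computed.  Matching is literal
string scanning (overlapping occurrences all reported); positions are
1-based on the target's forward strand for both strands.  `N` never matches
on either side — conservative, and the cheapest rule that can only lose
hits, never invent them.  A palindromic spacer (equal to its reverse
complement) matches both strands over the same window; it is reported once,
on the forward strand.

## Synthetic data generator

The generator emulates only the spatial and statistical structure the
pipeline consumes — not gene content, BGC architecture or phage evolution.
Per genome it plants island chains with exact member gaps, then background
features, all separated by more than the chaining threshold (default
threshold + 10 kb) so nothing chains unintentionally.  Placement walks a
per-contig cursor, so a fixed seed yields byte-identical files; an island
longer than every contig is an error before any output.  The default
planting mix mirrors the reference survey's architectures: mostly
two-member defense-metabolite pairs (the dominant class there), the
published gap arithmetic for the prophage-metabolite pair (39,414 bp) and
the combined quartet (78/10,303/24,980 bp), an embedded defense system
inside a BGC (negative planted gap), a pair at exactly the threshold, and
decoys — a pair one base over the threshold and a BGC-only pair — that must
*not* be detected.  Decoy specs are validated at generation time: the
fragments they split into must not themselves qualify as islands, so the
manifest's expected set is exact.

Prophage sequences (default 8 per dataset, 36–61 kb, GC drawn from
40–66 % — the ranges of the eight curated prophages) are i.i.d. base draws
at the target GC; at these lengths realised GC is within ±1 % of target.
Protospacers (32 nt, a typical spacer length) are embedded verbatim,
forward or reverse-complement, and re-drawn in the astronomically rare case
the spacer occurs elsewhere; decoy spacers are verified absent everywhere.
Quality records cycle through the four triage classes with scores drawn
inside each class's range, visit completeness/contamination corners around
the 90 %/5 % gates, and always include the literal boundary scores 69, 70,
90 and 91.  The manifest records planted islands (members, expected class,
detectability), planted hits (position and strand) and expected triage
outcomes.

What passing recovery tests shows: the detector and screen are exact on
data whose generative structure matches their assumptions.  What it does
not show: robustness to annotation noise (wrong category calls, imprecise
boundaries), cross-contig islands broken by assembly, or compositional
signals — real surveys inherit those limitations from their upstream tools.

## Problem sizes and numerical choices

The test suite uses 1,000 random ≤ 25-feature contigs for the
chaining-vs-brute-force closure oracle, 100 synthetic genomes (20 seeds × 5
genomes) for planted-island recovery, and 200 random ≤ 5 kb targets for the
spacer oracle; the whole suite runs in a few seconds on one CPU.  All
randomness flows from explicit integer seeds through `numpy` generators.
Percent displays round half away from zero to two decimals; share
comparisons against truncated published values use ±0.01.  Degenerate
inputs fail loudly: empty summaries, empty clusters, invalid spans,
non-IUPAC characters and out-of-range percentages are errors with the
offending line or value named.

## Known limitations

* Island detection trusts upstream categories; no sequence-based inference
  or horizontal-transfer evidence (GC skew, codon bias) is used.
* The 23-island census of the reference survey is not reproducible without
  its unreleased genomes; the package substitutes exact recovery guarantees
  on synthetic data plus the three printed worked examples.
* Deduplication across prophage predictors is heuristic and off by default.
* The TTA codon tally counts a fixed frame on the given strand
  representation; it does not find ORFs.
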