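"""Spatial-proximity detection of multi-functional genomic islands.

An island is a same-contig chain of annotated elements in which no element
is separated from the region chained so far by more than ``max_gap_bp``
intervening bases (default 50 kb), and whose members include at least one
biosynthetic gene cluster (the metabolic anchor) plus at least one
defensive or prophage element.  Chaining is single linkage: the clusters
are exactly the connected components of the pairwise relation
``gap(a, b) <= max_gap_bp``.

The intervening distance between two intervals is the number of bases
strictly between their spans, ``max(0, b.start - a.end - 1)``; overlapping
or abutting elements have gap 0 and always chain.

Island class labels subtype the defensive component: a CRISPR array, a Cas
operon, and any other defense system each leave a distinct mark, so a
cluster of {CRISPR array, Cas operon, Hachiman, BGC} is the fully combined
CRISPR-Cas-defense-metabolite architecture while {BGC, prophage} is a
prophage-metabolite island.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .model import (
    AnnotationSet,
    Category,
    FeatureError,
    GenomicFeature,
    Thresholds,
    DEFAULT_THRESHOLDS,
)

__all__ = [
    "gap_bp",
    "chain_contig",
    "classify_island",
    "detect_overlaps",
    "detect_islands",
    "Island",
    "OverlapRecord",
    "ISLAND_CLASSES",
    "islands_to_tsv",
    "islands_to_gff3",
    "islands_to_json",
]

# Closed label vocabulary.  The three architecture models (metabolic +
# defensive, metabolic + prophage + defensive, metabolic + prophage) are
# refined by which defensive subtypes are present.
DEFENSE_METABOLITE = "defense-metabolite"
CRISPR_METABOLITE = "CRISPR-metabolite"
CAS_METABOLITE = "Cas-metabolite"
CRISPR_DEFENSE_METABOLITE = "CRISPR-defense-metabolite"
CAS_DEFENSE_METABOLITE = "Cas-defense-metabolite"
COMBINED_CRISPR_CAS_DEFENSE_METABOLITE = "combined CRISPR-Cas-defense-metabolite"
PROPHAGE_METABOLITE = "prophage-metabolite"
PROPHAGE_DEFENSIVE_METABOLIC = "prophage-defensive-metabolic"

ISLAND_CLASSES = (
    DEFENSE_METABOLITE,
    CRISPR_METABOLITE,
    CAS_METABOLITE,
    CRISPR_DEFENSE_METABOLITE,
    CAS_DEFENSE_METABOLITE,
    COMBINED_CRISPR_CAS_DEFENSE_METABOLITE,
    PROPHAGE_METABOLITE,
    PROPHAGE_DEFENSIVE_METABOLIC,
)

JSON_SCHEMA_VERSION = "islandkit-islands/1"


@dataclass(frozen=True)
class OverlapRecord:
    """A positive coordinate intersection between two island members.

    ``relation`` is from ``feature_a``'s point of view: ``contains`` means
    a's span fully covers b's, ``contained_by`` the reverse, ``identical``
    equal spans, ``partial`` anything else.
    """

    feature_a: str
    feature_b: str
    relation: str
    overlap_bp: int


@dataclass(frozen=True)
class Island:
    island_id: str
    genome_id: str
    contig_id: str
    span_start: int
    span_end: int
    members: Tuple[GenomicFeature, ...]
    gaps_bp: Tuple[int, ...]
    island_class: str
    overlaps: Tuple[OverlapRecord, ...]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> Tuple[str, ...]:
        return tuple(f.feature_id for f in self.members)

    @property
    def max_gap_observed(self) -> int:
        return max(self.gaps_bp) if self.gaps_bp else 0


def gap_bp(a: GenomicFeature, b: GenomicFeature) -> int:
    """Bases strictly between two spans; 0 for overlapping or abutting.

    ``a`` must precede ``b`` in (start, end, feature_id) order on the same
    contig.
    """
    if a.contig_id != b.contig_id:
        raise FeatureError(
            f"gap undefined across contigs ({a.contig_id!r} vs {b.contig_id!r})"
        )
    if b.sort_key < a.sort_key:
        raise FeatureError(f"{a.feature_id!r} does not precede {b.feature_id!r}")
    return max(0, b.start - a.end - 1)


def chain_contig(
    features: Sequence[GenomicFeature], max_gap_bp: int
) -> List[List[GenomicFeature]]:
    """Single-linkage chaining of one contig's features.

    Returns the connected components of the relation ``gap <= max_gap_bp``,
    as position-ordered lists.  A sweep over the sorted features tracking
    the running maximum end is exactly the transitive closure: a break is
    declared only when the next start lies more than ``max_gap_bp`` bases
    past everything seen so far, and later features (whose starts are
    >= the break point) can never reach back across it.
    """
    if max_gap_bp <= 0:
        raise FeatureError("max_gap_bp must be positive")
    ordered = sorted(features, key=lambda f: f.sort_key)
    contigs = {f.contig_id for f in ordered}
    if len(contigs) > 1:
        raise FeatureError(f"chain_contig expects one contig, got {sorted(contigs)}")

    clusters: List[List[GenomicFeature]] = []
    current: List[GenomicFeature] = []
    max_end = 0
    for f in ordered:
        if current and f.start - max_end - 1 > max_gap_bp:
            clusters.append(current)
            current = []
        current.append(f)
        max_end = max(max_end, f.end)
    if current:
        clusters.append(current)
    return clusters


def _category_flags(members: Iterable[GenomicFeature]) -> FrozenSet[Category]:
    return frozenset(f.category for f in members)


def classify_island(members: Sequence[GenomicFeature]) -> Optional[str]:
    """Label a candidate cluster, or ``None`` if it is not an island.

    A cluster qualifies only with a metabolic anchor (>= 1 BGC) plus at
    least one prophage or defensive element; pure-BGC or pure-defensive
    clusters return ``None`` and are reported as non-island clusters.
    The label is a pure function of the member category set.
    """
    if not members:
        raise FeatureError("cannot classify an empty cluster")
    cats = _category_flags(members)
    metabolic = Category.BGC in cats
    crispr = Category.CRISPR_ARRAY in cats
    cas = Category.CAS_CLUSTER in cats
    defense = Category.DEFENSE_SYSTEM in cats
    prophage = Category.PROPHAGE in cats
    if not metabolic:
        return None
    if prophage and (crispr or cas or defense):
        return PROPHAGE_DEFENSIVE_METABOLIC
    if prophage:
        return PROPHAGE_METABOLITE
    if crispr and cas:
        return COMBINED_CRISPR_CAS_DEFENSE_METABOLITE
    if crispr and defense:
        return CRISPR_DEFENSE_METABOLITE
    if cas and defense:
        return CAS_DEFENSE_METABOLITE
    if crispr:
        return CRISPR_METABOLITE
    if cas:
        return CAS_METABOLITE
    if defense:
        return DEFENSE_METABOLITE
    return None  # BGC-only cluster


def detect_overlaps(members: Sequence[GenomicFeature]) -> List[OverlapRecord]:
    """Record every positive coordinate intersection among island members."""
    ordered = sorted(members, key=lambda f: f.sort_key)
    records: List[OverlapRecord] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if hi < lo:
                continue
            if (a.start, a.end) == (b.start, b.end):
                relation = "identical"
            elif a.start <= b.start and b.end <= a.end:
                relation = "contains"
            elif b.start <= a.start and a.end <= b.end:
                relation = "contained_by"
            else:
                relation = "partial"
            records.append(OverlapRecord(a.feature_id, b.feature_id, relation, hi - lo + 1))
    return records


def _cluster_gaps(members: Sequence[GenomicFeature]) -> Tuple[int, ...]:
    """Intervening distance of each member beyond the region chained so far."""
    gaps = []
    max_end = members[0].end
    for f in members[1:]:
        gaps.append(max(0, f.start - max_end - 1))
        max_end = max(max_end, f.end)
    return tuple(gaps)


def detect_islands(
    annset: AnnotationSet,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    *,
    return_nonislands: bool = False,
):
    """Run the full detector over one genome.

    For each contig: sort, chain at ``thresholds.max_gap_bp``, classify,
    and record member overlaps.  Clusters without an island label are
    dropped unless ``return_nonislands`` is set, in which case a second
    list of (contig_id, members) pairs is returned as a side report.

    Island ids are deterministic: ``genome:contig:ordinal`` with ordinals
    assigned in position order per contig.
    """
    islands: List[Island] = []
    nonislands: List[Tuple[str, List[GenomicFeature]]] = []
    for contig in annset.contigs:
        ordinal = 0
        for cluster in chain_contig(annset.contig_features(contig), thresholds.max_gap_bp):
            label = classify_island(cluster)
            if label is None:
                nonislands.append((contig, cluster))
                continue
            ordinal += 1
            islands.append(
                Island(
                    island_id=f"{annset.genome_id}:{contig}:{ordinal}",
                    genome_id=annset.genome_id,
                    contig_id=contig,
                    span_start=min(f.start for f in cluster),
                    span_end=max(f.end for f in cluster),
                    members=tuple(cluster),
                    gaps_bp=_cluster_gaps(cluster),
                    island_class=label,
                    overlaps=tuple(detect_overlaps(cluster)),
                )
            )
    if return_nonislands:
        return islands, nonislands
    return islands


TSV_COLUMNS = [
    "island_id", "genome_id", "contig_id", "span_start", "span_end",
    "island_class", "n_members", "member_ids", "max_gap_bp_observed", "n_overlaps",
]


def islands_to_tsv(islands: Sequence[Island]) -> str:
    out = _io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(TSV_COLUMNS)
    for isl in islands:
        writer.writerow(
            [
                isl.island_id, isl.genome_id, isl.contig_id, isl.span_start,
                isl.span_end, isl.island_class, isl.n_members,
                ",".join(isl.member_ids), isl.max_gap_observed, len(isl.overlaps),
            ]
        )
    return out.getvalue()


def islands_to_gff3(islands: Sequence[Island]) -> str:
    lines = ["##gff-version 3"]
    for isl in islands:
        attrs = (
            f"ID={isl.island_id};island_class={isl.island_class};"
            f"n_members={isl.n_members}"
        )
        lines.append(
            "\t".join(
                [
                    isl.contig_id, "islandkit", "genomic_island", str(isl.span_start),
                    str(isl.span_end), ".", ".", ".", attrs,
                ]
            )
        )
        for f in isl.members:
            child = (
                f"ID={f.feature_id};Parent={isl.island_id};"
                f"category={f.category.value};subtype={f.subtype}"
            )
            lines.append(
                "\t".join(
                    [f.contig_id, f.source or "islandkit", "island_member",
                     str(f.start), str(f.end), ".", f.strand.value, ".", child]
                )
            )
    return "\n".join(lines) + "\n"


def islands_to_json(islands: Sequence[Island]) -> str:
    payload = {
        "schema_version": JSON_SCHEMA_VERSION,
        "islands": [
            {
                "island_id": isl.island_id,
                "genome_id": isl.genome_id,
                "contig_id": isl.contig_id,
                "span_start": isl.span_start,
                "span_end": isl.span_end,
                "island_class": isl.island_class,
                "members": list(isl.member_ids),
                "gaps_bp": list(isl.gaps_bp),
                "overlaps": [
                    {
                        "feature_a": o.feature_a,
                        "feature_b": o.feature_b,
                        "relation": o.relation,
                        "overlap_bp": o.overlap_bp,
                    }
                    for o in isl.overlaps
                ],
            }
            for isl in islands
        ],
    }
    return json.dumps(payload, indent=1) + "\n"
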