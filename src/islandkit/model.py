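"""Core data model for harmonized genome annotations.

Every upstream annotator (BGC finders, defense-system detectors, CRISPR
finders, prophage predictors) is reduced to one row per element: a genomic
interval on a contig with a category, a free-text subtype and a source tag.
Coordinates are 1-based inclusive throughout, the convention used by GFF3
and by the printed spans these tables are meant to reproduce.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "Category",
    "Strand",
    "GenomicFeature",
    "AnnotationSet",
    "Thresholds",
    "FeatureError",
]


class FeatureError(ValueError):
    """Raised for invalid features or annotation sets."""


class Category(str, enum.Enum):
    """The five element classes the island survey recognises."""

    BGC = "BGC"
    DEFENSE_SYSTEM = "DEFENSE_SYSTEM"
    CRISPR_ARRAY = "CRISPR_ARRAY"
    CAS_CLUSTER = "CAS_CLUSTER"
    PROPHAGE = "PROPHAGE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Strand(str, enum.Enum):
    FORWARD = "+"
    REVERSE = "-"
    UNKNOWN = "."

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Anti-defense systems ride along as DEFENSE_SYSTEM with this subtype prefix;
# they count as defensive elements for island membership.
ANTI_DEFENSE_PREFIX = "anti:"


@dataclass(frozen=True, order=False)
class GenomicFeature:
    """One annotated element: a 1-based inclusive interval on a contig.

    Parameters
    ----------
    feature_id
        Unique within a dataset.  Auto-assigned on ingest when absent as
        ``genome:contig:start-end:category``.
    category
        One of :class:`Category`; unknown categories are rejected at ingest.
    subtype
        Free text, e.g. ``"ectoine"``, ``"RM_Type_I"``, ``"Hachiman"``.
        Hybrid BGCs are a single feature whose subtype is a comma-joined
        sorted list of product classes.
    """

    feature_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    category: Category
    subtype: str = ""
    source: str = ""
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        if not isinstance(self.category, Category):
            object.__setattr__(self, "category", Category(self.category))
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))
        if not self.feature_id:
            raise FeatureError("feature_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise FeatureError(
                f"invalid span {self.start}-{self.end} for {self.feature_id!r}: "
                "require 1 <= start <= end"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def sort_key(self) -> Tuple[int, int, str]:
        """Total deterministic order within a contig."""
        return (self.start, self.end, self.feature_id)

    @property
    def is_anti_defense(self) -> bool:
        return self.category is Category.DEFENSE_SYSTEM and self.subtype.startswith(
            ANTI_DEFENSE_PREFIX
        )

    @staticmethod
    def auto_id(genome_id: str, contig_id: str, start: int, end: int, category: Category) -> str:
        return f"{genome_id}:{contig_id}:{start}-{end}:{Category(category).value}"


def default_feature_id(f: GenomicFeature) -> GenomicFeature:
    """Return ``f`` with the deterministic auto id filled in."""
    return replace(
        f, feature_id=GenomicFeature.auto_id(f.genome_id, f.contig_id, f.start, f.end, f.category)
    )


class AnnotationSet:
    """All harmonized features of one genome, grouped and sorted per contig.

    Within a contig, features are kept in ``(start, end, feature_id)`` order,
    which downstream chaining relies on.
    """

    def __init__(self, genome_id: str, features: Iterable[GenomicFeature] = ()) -> None:
        self.genome_id = genome_id
        self._by_contig: Dict[str, List[GenomicFeature]] = {}
        self._ids: set = set()
        for f in features:
            self.add(f)

    def add(self, feature: GenomicFeature) -> None:
        if feature.genome_id != self.genome_id:
            raise FeatureError(
                f"feature {feature.feature_id!r} belongs to genome "
                f"{feature.genome_id!r}, not {self.genome_id!r}"
            )
        if feature.feature_id in self._ids:
            raise FeatureError(f"duplicate feature_id {feature.feature_id!r}")
        self._ids.add(feature.feature_id)
        self._by_contig.setdefault(feature.contig_id, []).append(feature)

    @property
    def contigs(self) -> List[str]:
        return sorted(self._by_contig)

    def contig_features(self, contig_id: str) -> List[GenomicFeature]:
        """Features on one contig in (start, end, feature_id) order."""
        return sorted(self._by_contig.get(contig_id, ()), key=lambda f: f.sort_key)

    def __iter__(self) -> Iterator[GenomicFeature]:
        for contig in self.contigs:
            yield from self.contig_features(contig)

    def __len__(self) -> int:
        return len(self._ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.genome_id == other.genome_id and list(self) == list(other)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnnotationSet({self.genome_id!r}, n={len(self)})"


def merge_sources(sets: List[AnnotationSet]) -> AnnotationSet:
    """Union of feature sets from several annotators for one genome.

    All sets must share ``genome_id``; duplicate feature ids across sources
    are an error (each upstream row is one element).
    """
    if not sets:
        raise FeatureError("merge_sources requires at least one AnnotationSet")
    genome_ids = {s.genome_id for s in sets}
    if len(genome_ids) > 1:
        raise FeatureError(f"cannot merge mixed genomes: {sorted(genome_ids)}")
    merged = AnnotationSet(sets[0].genome_id)
    for s in sets:
        for f in s:
            merged.add(f)
    return merged


@dataclass(frozen=True)
class Thresholds:
    """All survey decision thresholds, defaulting to the published analysis.

    Attributes
    ----------
    max_gap_bp
        Maximum intervening distance between adjacent island elements (bp).
    min_completeness_pct, max_contamination_pct
        High-quality prophage gate; both inequalities are strict
        (``completeness > 90`` and ``contamination < 5``).
    phastest_incomplete_below, phastest_intact_above
        Completeness-score class boundaries: ``score < 70`` incomplete,
        ``score > 90`` intact, in between questionable.
    spacer_evalue_max
        Documentation only: under the full-length zero-mismatch rule the
        e-value filter can never reject a hit, so it is not computed.
    """

    max_gap_bp: int = 50_000
    min_completeness_pct: float = 90.0
    max_contamination_pct: float = 5.0
    phastest_incomplete_below: float = 70.0
    phastest_intact_above: float = 90.0
    spacer_evalue_max: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_gap_bp <= 0:
            raise FeatureError("max_gap_bp must be positive")
        for name in ("min_completeness_pct", "max_contamination_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise FeatureError(f"{name} must be a percentage in [0, 100], got {v}")


DEFAULT_THRESHOLDS = Thresholds()
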