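"""Prophage quality triage and survey summary statistics.

Two independent decision rules are applied to upstream predictions:

* completeness-score triage into three classes — incomplete (score < 70),
  questionable (70 <= score <= 90), intact (score > 90); and
* a high-quality gate requiring completeness above 90 % and contamination
  below 5 % (both inequalities strict, as worded).

Records without a completeness score (e.g. machine-learning predictions
that carry only completeness/contamination estimates) are triaged as
``unscored`` rather than rejected.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from typing import Dict, IO, Iterable, List, Optional, Sequence, Union

from .model import FeatureError, Thresholds, DEFAULT_THRESHOLDS

__all__ = [
    "ProphageRecord",
    "ProphageSummary",
    "classify_score",
    "passes_quality",
    "gc_percent",
    "summarize",
    "tally_classes",
    "triage_records",
    "read_quality_table",
    "collapse_overlapping",
    "TRIAGE_CLASSES",
]

INTACT = "intact"
QUESTIONABLE = "questionable"
INCOMPLETE = "incomplete"
UNSCORED = "unscored"
TRIAGE_CLASSES = (INTACT, QUESTIONABLE, INCOMPLETE, UNSCORED)

_IUPAC = set("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class ProphageRecord:
    prophage_id: str
    genome_id: str = ""
    contig_id: str = ""
    start: Optional[int] = None
    end: Optional[int] = None
    length_kbp: Optional[float] = None
    gc_pct: Optional[float] = None
    score: Optional[float] = None
    completeness_pct: Optional[float] = None
    contamination_pct: Optional[float] = None
    triage_class: str = UNSCORED

    def __post_init__(self) -> None:
        for name in ("gc_pct", "completeness_pct", "contamination_pct"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise FeatureError(f"{name}={v} outside [0, 100] for {self.prophage_id!r}")
        if self.start is not None and self.end is not None:
            derived = (self.end - self.start + 1) / 1000.0
            if self.length_kbp is None:
                object.__setattr__(self, "length_kbp", derived)
            elif abs(self.length_kbp - derived) > 0.05:
                raise FeatureError(
                    f"length_kbp={self.length_kbp} inconsistent with span "
                    f"{self.start}-{self.end} ({derived:.3f} kbp) for {self.prophage_id!r}"
                )
        if self.length_kbp is not None and self.length_kbp <= 0:
            raise FeatureError(f"length_kbp must be positive for {self.prophage_id!r}")
        if self.triage_class not in TRIAGE_CLASSES:
            raise FeatureError(f"unknown triage_class {self.triage_class!r}")


@dataclass(frozen=True)
class ProphageSummary:
    n: int
    mean_length_kbp: float
    min_length_kbp: float
    max_length_kbp: float
    mean_gc_pct: float
    min_gc_pct: float
    max_gc_pct: float


def classify_score(score: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Completeness-score triage: <70 incomplete, 70-90 questionable, >90 intact."""
    try:
        s = float(score)
    except (TypeError, ValueError):
        raise FeatureError(f"score must be numeric, got {score!r}") from None
    if s != s:  # NaN
        raise FeatureError("score must be a finite number")
    if s < thresholds.phastest_incomplete_below:
        return INCOMPLETE
    if s <= thresholds.phastest_intact_above:
        return QUESTIONABLE
    return INTACT


def passes_quality(
    completeness_pct: float,
    contamination_pct: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """High-quality gate: completeness > 90 and contamination < 5, both strict."""
    for name, v in (("completeness_pct", completeness_pct), ("contamination_pct", contamination_pct)):
        if not (0 <= v <= 100):
            raise FeatureError(f"{name}={v} outside [0, 100]")
    return (
        completeness_pct > thresholds.min_completeness_pct
        and contamination_pct < thresholds.max_contamination_pct
    )


def gc_percent(sequence: str) -> float:
    """GC content as a percentage of all positions.

    Ambiguity codes (including N) count in the denominator only; only
    literal G and C count as GC.  Case-insensitive.
    """
    if not sequence:
        raise FeatureError("cannot compute GC of an empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise FeatureError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def summarize(records: Sequence[ProphageRecord]) -> ProphageSummary:
    """Arithmetic mean and extrema of length and GC over the records."""
    if not records:
        raise FeatureError("summarize requires at least one record")
    lengths = [r.length_kbp for r in records if r.length_kbp is not None]
    gcs = [r.gc_pct for r in records if r.gc_pct is not None]
    if not lengths or not gcs:
        raise FeatureError("records must carry length_kbp and gc_pct to summarize")
    return ProphageSummary(
        n=len(records),
        mean_length_kbp=sum(lengths) / len(lengths),
        min_length_kbp=min(lengths),
        max_length_kbp=max(lengths),
        mean_gc_pct=sum(gcs) / len(gcs),
        min_gc_pct=min(gcs),
        max_gc_pct=max(gcs),
    )


def tally_classes(records: Iterable[ProphageRecord]) -> Dict[str, int]:
    """Counts per triage class plus a ``total`` entry (sum of all classes)."""
    counts: Dict[str, int] = {}
    total = 0
    for r in records:
        counts[r.triage_class] = counts.get(r.triage_class, 0) + 1
        total += 1
    counts["total"] = total
    return counts


def triage_records(
    records: Iterable[ProphageRecord], thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> List[ProphageRecord]:
    """Assign each record its triage class (``unscored`` when no score)."""
    out = []
    for r in records:
        cls = UNSCORED if r.score is None else classify_score(r.score, thresholds)
        out.append(replace(r, triage_class=cls))
    return out


QUALITY_COLUMNS = [
    "prophage_id", "genome_id", "contig_id", "start", "end",
    "score", "completeness_pct", "contamination_pct",
]


def read_quality_table(stream: Union[str, IO[str]]) -> List[ProphageRecord]:
    """Parse the quality TSV; empty numeric cells mean missing."""
    fh = _io.StringIO(stream) if isinstance(stream, str) else stream
    reader = csv.DictReader(fh, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = [c for c in ("prophage_id",) if c not in reader.fieldnames]
    if missing:
        raise FeatureError(f"quality table missing columns: {missing}")

    def num(row: dict, key: str, cast=float):
        v = (row.get(key) or "").strip()
        return cast(v) if v else None

    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            records.append(
                ProphageRecord(
                    prophage_id=row["prophage_id"].strip(),
                    genome_id=(row.get("genome_id") or "").strip(),
                    contig_id=(row.get("contig_id") or "").strip(),
                    start=num(row, "start", int),
                    end=num(row, "end", int),
                    gc_pct=num(row, "gc_pct"),
                    length_kbp=num(row, "length_kbp"),
                    score=num(row, "score"),
                    completeness_pct=num(row, "completeness_pct"),
                    contamination_pct=num(row, "contamination_pct"),
                )
            )
        except (ValueError, FeatureError) as exc:
            raise FeatureError(f"line {lineno}: {exc}") from None
    return records


def collapse_overlapping(
    records: Sequence[ProphageRecord], min_overlap_frac: float = 0.5
) -> List[ProphageRecord]:
    """Optional dedup of coordinate-overlapping calls from different tools.

    Two records on the same genome and contig collapse when their
    intersection covers at least ``min_overlap_frac`` of the shorter span;
    the record with the higher completeness (then score, then id) is kept.
    The threshold is a pragmatic default, not survey-derived.
    """
    def span(r: ProphageRecord):
        return None if r.start is None or r.end is None else (r.start, r.end)

    kept: List[ProphageRecord] = []
    for r in sorted(
        records,
        key=lambda r: (
            -(r.completeness_pct or -1), -(r.score or -1), r.prophage_id,
        ),
    ):
        s = span(r)
        redundant = False
        for k in kept:
            ks = span(k)
            if s is None or ks is None:
                continue
            if (r.genome_id, r.contig_id) != (k.genome_id, k.contig_id):
                continue
            inter = min(s[1], ks[1]) - max(s[0], ks[0]) + 1
            shorter = min(s[1] - s[0] + 1, ks[1] - ks[0] + 1)
            if inter > 0 and inter / shorter >= min_overlap_frac:
                redundant = True
                break
        if not redundant:
            kept.append(r)
    return sorted(kept, key=lambda r: r.prophage_id)
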