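"""Survey-level tallies: counts, shares, ribbon export and codon tallies.

Shares are always derived from counts at full precision; display rounding
(two decimals, half away from zero) happens only at formatting time, so a
count of 58 out of 148 is stored as 39.189 % and prints as "39.19" while
comparisons to truncated published figures use the raw value.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .model import Category, GenomicFeature

__all__ = [
    "CountTable",
    "RibbonRow",
    "tally",
    "tally_bgc",
    "ribbon_export",
    "tta_codon_count",
    "format_pct",
    "count_table_to_tsv",
    "ribbon_to_tsv",
]

logger = logging.getLogger(__name__)

DIMENSIONS = ("bgc_class", "cas_type", "defense_system", "anti_defense_system", "island_class")


@dataclass(frozen=True)
class CountTable:
    dimension: str
    rows: Tuple[Tuple[str, int], ...]  # ordered (key, count)
    total: int

    @property
    def counts(self) -> Dict[str, int]:
        return dict(self.rows)

    @property
    def shares(self) -> Dict[str, float]:
        """Percent share per key, exact to float precision."""
        if self.total == 0:
            return {}
        return {k: 100.0 * c / self.total for k, c in self.rows}


@dataclass(frozen=True)
class RibbonRow:
    group: str
    key: str
    count: int
    group_share_pct: float


def tally(dimension: str, keys: Iterable[str]) -> CountTable:
    """Exact counts and shares over one categorical dimension.

    Keys are ordered by (count desc, key asc) for stable output.  An empty
    input yields total 0 and no shares.
    """
    counts: Dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    ordered = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return CountTable(dimension=dimension, rows=ordered, total=sum(counts.values()))


def tally_bgc(features: Iterable[GenomicFeature]) -> Tuple[CountTable, CountTable]:
    """Two views over BGC features with comma-joined hybrid subtypes.

    Returns ``(single_class, hybrid_combination)``: in the first, a hybrid
    locus contributes one count to each component product class; in the
    second, hybrids are counted once under their sorted ``+``-joined label
    and pure single-class loci are excluded.
    """
    single_keys: List[str] = []
    hybrid_keys: List[str] = []
    for f in features:
        if f.category is not Category.BGC:
            continue
        classes = sorted(p.strip() for p in f.subtype.split(",") if p.strip())
        single_keys.extend(classes)
        if len(classes) > 1:
            hybrid_keys.append("+".join(classes))
    return tally("bgc_class", single_keys), tally("bgc_class", hybrid_keys)


def ribbon_export(
    group_key: str, tables: Mapping[str, CountTable]
) -> List[RibbonRow]:
    """Flatten per-group count tables into circular-plot ribbon rows.

    One row per (group, key) with the count and the within-group share.
    Empty groups are skipped with a logged warning.  Row order is stable:
    groups ascending, then each group's own table order.
    """
    rows: List[RibbonRow] = []
    for group in sorted(tables):
        table = tables[group]
        if table.total == 0:
            logger.warning("ribbon_export: group %r has no counts, skipping", group)
            continue
        shares = table.shares
        for key, count in table.rows:
            rows.append(RibbonRow(group, key, count, shares[key]))
    return rows


def tta_codon_count(cds: str, frame: int = 0) -> int:
    """In-frame TTA codons in the given reading frame of the given strand.

    TTA (Leu) is the rare codon whose translation in high-GC actinobacteria
    requires a dedicated tRNA and acts as a regulatory checkpoint; its
    abundance in defense genes near biosynthetic loci is worth tallying.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = cds.upper()
    if len(seq) < 3:
        warnings.warn("sequence shorter than one codon; TTA count is 0")
        return 0
    return sum(1 for i in range(frame, len(seq) - 2, 3) if seq[i : i + 3] == "TTA")


def format_pct(value: float, decimals: int = 2) -> str:
    """Round half away from zero, e.g. 39.189 -> '39.19'."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def count_table_to_tsv(table: CountTable) -> str:
    out = _io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow([table.dimension, "count", "share_pct"])
    shares = table.shares
    for key, count in table.rows:
        writer.writerow([key, count, format_pct(shares[key])])
    writer.writerow(["total", table.total, format_pct(100.0) if table.total else ""])
    return out.getvalue()


def ribbon_to_tsv(rows: Sequence[RibbonRow]) -> str:
    out = _io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["group", "key", "count", "group_share_pct"])
    for r in rows:
        writer.writerow([r.group, r.key, r.count, format_pct(r.group_share_pct)])
    return out.getvalue()
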