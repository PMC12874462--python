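"""Readers and writers for harmonized feature tables.

The native interchange format is a UTF-8 tab-separated table with a header
row and columns::

    genome_id  contig_id  start  end  category  subtype  source  [strand]  [feature_id]

Coordinates are 1-based inclusive.  BED input (0-based half-open) is
converted on ingest; GFF3 carries ``category`` and ``subtype`` as attributes.
native_tsv and JSON round-trip losslessly.
"""

from __future__ import annotations

import csv
import io as _io
import json
from typing import IO, Iterable, List, Optional, Union

from .model import (
    AnnotationSet,
    Category,
    FeatureError,
    GenomicFeature,
    Strand,
)

__all__ = [
    "read_feature_table",
    "write_features",
    "features_to_json",
    "features_from_json",
]

NATIVE_COLUMNS = ["genome_id", "contig_id", "start", "end", "category", "subtype", "source"]
OPTIONAL_COLUMNS = ["strand", "feature_id"]

JSON_SCHEMA_VERSION = "islandkit-features/1"

_GFF3_TYPE_BY_CATEGORY = {
    Category.BGC: "biosynthetic_gene_cluster",
    Category.DEFENSE_SYSTEM: "defense_system",
    Category.CRISPR_ARRAY: "CRISPR",
    Category.CAS_CLUSTER: "cas_operon",
    Category.PROPHAGE: "prophage",
}


def _as_text_stream(stream: Union[str, IO[str]]) -> IO[str]:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value.replace(",", ""))
    except ValueError:
        raise FeatureError(f"line {lineno}: {what} is not an integer: {value!r}") from None


def _parse_category(value: str, lineno: int) -> Category:
    try:
        return Category(value)
    except ValueError:
        valid = ", ".join(c.value for c in Category)
        raise FeatureError(
            f"line {lineno}: unknown category {value!r} (expected one of {valid})"
        ) from None


def read_feature_table(
    stream: Union[str, IO[str]],
    dialect: str = "native_tsv",
    *,
    genome_id: Optional[str] = None,
    default_category: Optional[Union[str, Category]] = None,
) -> AnnotationSet:
    """Parse a feature table into a validated :class:`AnnotationSet`.

    Parameters
    ----------
    stream
        Text content or an open text stream.
    dialect
        ``"native_tsv"``, ``"bed"`` or ``"gff3"``.
    genome_id
        Required for BED (which has no genome column); optional override for
        GFF3 (defaults to the first ``##genome`` pragma or ``"genome"``).
    default_category
        For BED: category applied when a line's name field is not itself a
        category token.  For GFF3: fallback when no ``category`` attribute is
        present and the type column is unrecognised.
    """
    if dialect == "native_tsv":
        return _read_native_tsv(_as_text_stream(stream))
    if dialect == "bed":
        return _read_bed(_as_text_stream(stream), genome_id, default_category)
    if dialect == "gff3":
        return _read_gff3(_as_text_stream(stream), genome_id, default_category)
    raise FeatureError(f"unknown dialect {dialect!r}")


def _read_native_tsv(stream: IO[str]) -> AnnotationSet:
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        return AnnotationSet("genome")
    header = [h.strip() for h in header]
    missing = [c for c in NATIVE_COLUMNS if c not in header]
    if missing:
        raise FeatureError(f"line 1: missing required columns: {', '.join(missing)}")
    idx = {c: header.index(c) for c in header}

    features: List[GenomicFeature] = []
    genome_id: Optional[str] = None
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < len(NATIVE_COLUMNS):
            raise FeatureError(f"line {lineno}: expected at least {len(NATIVE_COLUMNS)} columns, got {len(row)}")

        def cell(name: str, default: str = "") -> str:
            i = idx.get(name)
            return row[i].strip() if i is not None and i < len(row) else default

        start = _parse_int(cell("start"), "start", lineno)
        end = _parse_int(cell("end"), "end", lineno)
        if start > end:
            raise FeatureError(f"line {lineno}: start {start} > end {end}")
        category = _parse_category(cell("category"), lineno)
        g = cell("genome_id")
        if genome_id is None:
            genome_id = g
        strand_text = cell("strand") or "."
        fid = cell("feature_id") or GenomicFeature.auto_id(g, cell("contig_id"), start, end, category)
        try:
            features.append(
                GenomicFeature(
                    feature_id=fid,
                    genome_id=g,
                    contig_id=cell("contig_id"),
                    start=start,
                    end=end,
                    category=category,
                    subtype=cell("subtype"),
                    source=cell("source"),
                    strand=Strand(strand_text),
                )
            )
        except ValueError as exc:
            raise FeatureError(f"line {lineno}: {exc}") from None

    if genome_id is None:
        return AnnotationSet("genome")
    mixed = {f.genome_id for f in features}
    if len(mixed) > 1:
        raise FeatureError(f"table mixes genomes {sorted(mixed)}; one AnnotationSet per genome")
    return AnnotationSet(genome_id, features)


def _read_bed(
    stream: IO[str],
    genome_id: Optional[str],
    default_category: Optional[Union[str, Category]],
) -> AnnotationSet:
    if genome_id is None:
        raise FeatureError("BED input requires genome_id=")
    features: List[GenomicFeature] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 3:
            raise FeatureError(f"line {lineno}: BED needs at least 3 columns")
        contig = cols[0]
        chrom_start = _parse_int(cols[1], "chromStart", lineno)
        chrom_end = _parse_int(cols[2], "chromEnd", lineno)
        # BED is 0-based half-open; internal convention is 1-based inclusive.
        start, end = chrom_start + 1, chrom_end
        if start > end:
            raise FeatureError(f"line {lineno}: empty or inverted BED interval {cols[1]}-{cols[2]}")
        name = cols[3] if len(cols) > 3 else ""
        try:
            category: Category = Category(name)
            subtype = ""
        except ValueError:
            if default_category is None:
                raise FeatureError(
                    f"line {lineno}: name {name!r} is not a category and no default_category given"
                ) from None
            category = Category(default_category)
            subtype = name
        strand = Strand(cols[5]) if len(cols) > 5 and cols[5] in "+-" else Strand.UNKNOWN
        fid = GenomicFeature.auto_id(genome_id, contig, start, end, category)
        features.append(
            GenomicFeature(fid, genome_id, contig, start, end, category, subtype, "bed", strand)
        )
    return AnnotationSet(genome_id, features)


def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for part in text.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


_CATEGORY_BY_GFF3_TYPE = {v: k for k, v in _GFF3_TYPE_BY_CATEGORY.items()}


def _read_gff3(
    stream: IO[str],
    genome_id: Optional[str],
    default_category: Optional[Union[str, Category]],
) -> AnnotationSet:
    features: List[GenomicFeature] = []
    pragma_genome: Optional[str] = None
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if line.startswith("##genome"):
            pragma_genome = line.split(maxsplit=1)[1].strip() if " " in line else None
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FeatureError(f"line {lineno}: GFF3 requires 9 tab-separated columns")
        contig, source, ftype, start_s, end_s, _score, strand_s, _phase, attr_s = cols
        attrs = _parse_gff3_attributes(attr_s)
        start = _parse_int(start_s, "start", lineno)
        end = _parse_int(end_s, "end", lineno)
        if start > end:
            raise FeatureError(f"line {lineno}: start {start} > end {end}")
        if "category" in attrs:
            category = _parse_category(attrs["category"], lineno)
        elif ftype in _CATEGORY_BY_GFF3_TYPE:
            category = _CATEGORY_BY_GFF3_TYPE[ftype]
        elif default_category is not None:
            category = Category(default_category)
        else:
            raise FeatureError(
                f"line {lineno}: cannot determine category (no category attribute, "
                f"unrecognised type {ftype!r})"
            )
        g = genome_id or attrs.get("genome_id") or pragma_genome or "genome"
        fid = attrs.get("ID") or GenomicFeature.auto_id(g, contig, start, end, category)
        strand = Strand(strand_s) if strand_s in "+-" else Strand.UNKNOWN
        features.append(
            GenomicFeature(
                fid, g, contig, start, end, category,
                subtype=attrs.get("subtype", ""), source=source, strand=strand,
            )
        )
    gid = genome_id or (features[0].genome_id if features else pragma_genome or "genome")
    return AnnotationSet(gid, features)


def write_features(annset: AnnotationSet, format: str = "native_tsv") -> str:
    """Serialize an :class:`AnnotationSet`; native_tsv and json round-trip."""
    if format == "native_tsv":
        return _write_native_tsv(annset)
    if format == "gff3":
        return _write_gff3(annset)
    if format == "json":
        return features_to_json(annset)
    raise FeatureError(f"unknown format {format!r}")


def _write_native_tsv(annset: AnnotationSet) -> str:
    out = _io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(NATIVE_COLUMNS + OPTIONAL_COLUMNS)
    for f in annset:
        writer.writerow(
            [
                f.genome_id, f.contig_id, f.start, f.end, f.category.value,
                f.subtype, f.source, f.strand.value, f.feature_id,
            ]
        )
    return out.getvalue()


def _write_gff3(annset: AnnotationSet) -> str:
    lines = ["##gff-version 3", f"##genome {annset.genome_id}"]
    for f in annset:
        attrs = f"ID={f.feature_id};category={f.category.value}"
        if f.subtype:
            attrs += f";subtype={f.subtype}"
        attrs += f";genome_id={f.genome_id}"
        strand = f.strand.value if f.strand is not Strand.UNKNOWN else "."
        lines.append(
            "\t".join(
                [
                    f.contig_id, f.source or "islandkit", _GFF3_TYPE_BY_CATEGORY[f.category],
                    str(f.start), str(f.end), ".", strand, ".", attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def features_to_json(annset: AnnotationSet) -> str:
    payload = {
        "schema_version": JSON_SCHEMA_VERSION,
        "genome_id": annset.genome_id,
        "features": [
            {
                "feature_id": f.feature_id,
                "genome_id": f.genome_id,
                "contig_id": f.contig_id,
                "start": f.start,
                "end": f.end,
                "category": f.category.value,
                "subtype": f.subtype,
                "source": f.source,
                "strand": f.strand.value,
            }
            for f in annset
        ],
    }
    return json.dumps(payload, indent=1) + "\n"


def features_from_json(text: str) -> AnnotationSet:
    payload = json.loads(text)
    if payload.get("schema_version") != JSON_SCHEMA_VERSION:
        raise FeatureError(f"unsupported schema_version {payload.get('schema_version')!r}")
    features = [
        GenomicFeature(
            feature_id=row["feature_id"],
            genome_id=row["genome_id"],
            contig_id=row["contig_id"],
            start=row["start"],
            end=row["end"],
            category=Category(row["category"]),
            subtype=row.get("subtype", ""),
            source=row.get("source", ""),
            strand=Strand(row.get("strand", ".")),
        )
        for row in payload["features"]
    ]
    return AnnotationSet(payload["genome_id"], features)
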