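"""Exact spacer-to-protospacer screening.

CRISPR spacers are matched against prophage sequences requiring a perfect,
full-length, zero-mismatch occurrence on either strand.  Under this rule an
alignment e-value filter is vacuous (an exact full-length hit always passes),
so matching is plain string scanning on the forward sequence and the
reverse complement.  ``N`` never matches on either side.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from typing import IO, Dict, Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .model import FeatureError

__all__ = [
    "Spacer",
    "SpacerHit",
    "reverse_complement",
    "find_hits",
    "screen",
    "read_spacer_fasta",
    "read_target_fasta",
    "hits_to_tsv",
]

_SPACER_ALPHABET = set("ACGTN")
_IUPAC = set("ACGTURYSWKMBDHVN")

# typical CRISPR spacer lengths; outside this we warn but do not reject
SPACER_LEN_TYPICAL = (20, 50)


@dataclass(frozen=True)
class Spacer:
    spacer_id: str
    sequence: str
    array_id: str = ""
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FeatureError(f"spacer {self.spacer_id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _SPACER_ALPHABET
        if bad:
            raise FeatureError(
                f"spacer {self.spacer_id!r} has non-ACGTN characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class SpacerHit:
    """A full-length exact occurrence of a spacer in a target.

    ``position`` is the 1-based start of the matched window on the target's
    forward strand regardless of the hit strand.
    """

    spacer_id: str
    target_id: str
    position: int
    strand: str
    match_len: int


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (case preserved by upstream callers)."""
    bad = set(seq.upper()) - _IUPAC
    if bad:
        raise FeatureError(f"non-IUPAC characters: {sorted(bad)}")
    return str(Seq(seq).reverse_complement()).upper() if seq.isupper() else str(
        Seq(seq).reverse_complement()
    )


def _occurrences(needle: str, haystack: str) -> List[int]:
    """All 0-based occurrence starts, overlapping included."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def find_hits(spacer: Spacer, target_id: str, target_seq: str) -> List[SpacerHit]:
    """All exact full-length occurrences on either strand, case-insensitive.

    A window containing ``N`` in either sequence never matches: a spacer
    carrying N yields no hits, and target Ns break literal matching by
    construction.  Hits are sorted by (position, strand).
    """
    if not target_seq:
        raise FeatureError(f"target {target_id!r} has an empty sequence")
    t = target_seq.upper()
    bad = set(t) - _IUPAC
    if bad:
        raise FeatureError(f"target {target_id!r} has non-IUPAC characters: {sorted(bad)}")
    s = spacer.sequence.upper()
    if "N" in s:
        return []
    hits = [
        SpacerHit(spacer.spacer_id, target_id, i + 1, "+", len(s))
        for i in _occurrences(s, t)
    ]
    rc = str(Seq(s).reverse_complement())
    # a palindromic spacer (rc == s) matches both strands at the same
    # window; report it once, on the forward strand
    if rc != s:
        hits += [
            SpacerHit(spacer.spacer_id, target_id, i + 1, "-", len(s))
            for i in _occurrences(rc, t)
        ]
    return sorted(hits, key=lambda h: (h.position, h.strand))


def screen(
    spacers: Sequence[Spacer], targets: Union[Dict[str, str], Sequence[Tuple[str, str]]]
) -> List[SpacerHit]:
    """Screen every spacer against every target sequence.

    ``targets`` maps target id to sequence (duplicate ids are an error when
    given as pairs).  The hit list is ordered by
    (spacer_id, target_id, position, strand).
    """
    if not isinstance(targets, dict):
        tmap: Dict[str, str] = {}
        for tid, seq in targets:
            if tid in tmap:
                raise FeatureError(f"duplicate target id {tid!r}")
            tmap[tid] = seq
        targets = tmap
    hits: List[SpacerHit] = []
    for sp in spacers:
        for tid in targets:
            hits.extend(find_hits(sp, tid, targets[tid]))
    return sorted(hits, key=lambda h: (h.spacer_id, h.target_id, h.position, h.strand))


def read_spacer_fasta(stream: Union[str, IO[str]]) -> List[Spacer]:
    fh = _io.StringIO(stream) if isinstance(stream, str) else stream
    return [Spacer(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def read_target_fasta(stream: Union[str, IO[str]]) -> Dict[str, str]:
    fh = _io.StringIO(stream) if isinstance(stream, str) else stream
    targets: Dict[str, str] = {}
    for rec in SeqIO.parse(fh, "fasta"):
        if rec.id in targets:
            raise FeatureError(f"duplicate target id {rec.id!r} in FASTA")
        targets[rec.id] = str(rec.seq)
    return targets


def hits_to_tsv(hits: Sequence[SpacerHit]) -> str:
    out = _io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["spacer_id", "target_id", "position", "strand", "match_len"])
    for h in hits:
        writer.writerow([h.spacer_id, h.target_id, h.position, h.strand, h.match_len])
    return out.getvalue()
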