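"""Published worked examples used as reference inputs throughout the suite.

Three island architectures with printed coordinates serve as end-to-end
fixtures for the detector:

* ``oceanimonas`` — Oceanimonas sp. GK1: an NI-siderophore BGC
  (746,012-777,519) adjacent to a Belisama defense system (804,690-805,508);
  a defense-metabolite island with one 27,170 bp gap.
* ``ibrc_m_10908k`` — S. proteolyticus IBRC-M 10908K: a
  lanthipeptide-class-III BGC (3,415,756-3,438,299) near the prophage
  Ph_Salpro4 (3,477,714-3,537,879); a prophage-metabolite island
  (gap 39,414 bp).
* ``tgb10`` — S. proteolyticus TGB10: CRISPR array (657,024-657,967),
  Cas cluster (658,046-666,649), Hachiman components (676,953-680,635) and
  a hydrogen-cyanide BGC (705,616-718,582); the combined
  CRISPR-Cas-defense-metabolite island (gaps 78; 10,303; 24,980 bp).

Also included: the eight-prophage characteristics table (lengths in kbp and
GC in percent) behind the survey's summary statistics, the published triage
tally, and the Cas gene inventory anchor (58 Cas3_TypeI of 148 Cas genes).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .islands import (
    COMBINED_CRISPR_CAS_DEFENSE_METABOLITE,
    DEFENSE_METABOLITE,
    PROPHAGE_METABOLITE,
)
from .model import AnnotationSet, Category, GenomicFeature
from .prophages import ProphageRecord

__all__ = [
    "FIXTURE_NAMES",
    "island_fixture",
    "PROPHAGE_TABLE",
    "TRIAGE_TALLY",
    "CAS_GENE_COUNTS",
]

FIXTURE_NAMES = ("oceanimonas", "ibrc_m_10908k", "tgb10")


def _feat(genome, contig, start, end, category, subtype, fid):
    return GenomicFeature(
        feature_id=fid, genome_id=genome, contig_id=contig, start=start, end=end,
        category=category, subtype=subtype, source="published",
    )


_FIXTURES: Dict[str, Tuple[List[GenomicFeature], dict]] = {
    "oceanimonas": (
        [
            _feat("Oceanimonas_GK1", "ctg1", 746_012, 777_519, Category.BGC,
                  "NI-siderophore", "GK1_bgc_siderophore"),
            _feat("Oceanimonas_GK1", "ctg1", 804_690, 805_508, Category.DEFENSE_SYSTEM,
                  "Belisama", "GK1_def_belisama"),
        ],
        {"n_islands": 1, "island_class": DEFENSE_METABOLITE, "n_members": 2,
         "gaps_bp": [27_170]},
    ),
    "ibrc_m_10908k": (
        [
            _feat("S_proteolyticus_IBRC-M_10908K", "ctg1", 3_415_756, 3_438_299,
                  Category.BGC, "lanthipeptide-class-III", "10908K_bgc_lanthipeptide"),
            _feat("S_proteolyticus_IBRC-M_10908K", "ctg1", 3_477_714, 3_537_879,
                  Category.PROPHAGE, "Ph_Salpro4", "10908K_prophage_salpro4"),
        ],
        {"n_islands": 1, "island_class": PROPHAGE_METABOLITE, "n_members": 2,
         "gaps_bp": [39_414]},
    ),
    "tgb10": (
        [
            _feat("S_proteolyticus_TGB10", "ctg1", 657_024, 657_967,
                  Category.CRISPR_ARRAY, "CRISPR", "TGB10_crispr_array"),
            _feat("S_proteolyticus_TGB10", "ctg1", 658_046, 666_649,
                  Category.CAS_CLUSTER, "cas_full", "TGB10_cas_cluster"),
            _feat("S_proteolyticus_TGB10", "ctg1", 676_953, 680_635,
                  Category.DEFENSE_SYSTEM, "Hachiman", "TGB10_def_hachiman"),
            _feat("S_proteolyticus_TGB10", "ctg1", 705_616, 718_582,
                  Category.BGC, "hydrogen-cyanide", "TGB10_bgc_hcn"),
        ],
        {"n_islands": 1, "island_class": COMBINED_CRISPR_CAS_DEFENSE_METABOLITE,
         "n_members": 4, "gaps_bp": [78, 10_303, 24_980]},
    ),
}


def island_fixture(name: str) -> Tuple[AnnotationSet, dict]:
    """Return (feature set, expected-island summary) for a named fixture."""
    key = name.lower()
    if key not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    features, expected = _FIXTURES[key]
    return AnnotationSet(features[0].genome_id, features), dict(expected)


#: The eight curated prophages: (name, host, length kbp, GC %, lifestyle).
PROPHAGE_TABLE: List[ProphageRecord] = [
    ProphageRecord("Ph_Alpe", genome_id="A_persicus", length_kbp=43.5, gc_pct=39.81),
    ProphageRecord("Ph_Ocea", genome_id="Oceanimonas_GK1", length_kbp=38.4, gc_pct=58.25),
    ProphageRecord("Ph_Salpro1", genome_id="S_proteolyticum_IBRC-M_10908", length_kbp=60.1, gc_pct=62.84),
    ProphageRecord("Ph_Salpro2", genome_id="S_proteolyticum_IBRC-M_10908", length_kbp=60.6, gc_pct=63.05),
    ProphageRecord("Ph_Salpro3", genome_id="S_proteolyticum_IBRC-M_10908", length_kbp=36.9, gc_pct=65.63),
    ProphageRecord("Ph_Salpro4", genome_id="S_proteolyticum_IBRC-M_10908K", length_kbp=60.1, gc_pct=62.84),
    ProphageRecord("Ph_Sapr1", genome_id="S_proteolyticus_19052", length_kbp=44.2, gc_pct=51.82),
    ProphageRecord("Ph_Sapr2", genome_id="S_proteolyticus_TGB10", length_kbp=59.5, gc_pct=46.69),
]

#: Published completeness-score triage tally over 37 predictions.
TRIAGE_TALLY: Dict[str, int] = {"intact": 15, "questionable": 10, "incomplete": 12}

#: Published Cas gene inventory anchor: 58 of 148 genes are Cas3_TypeI
#: (39.18 % as printed); the remainder binned for share arithmetic.
CAS_GENE_COUNTS: Dict[str, int] = {
    "Cas3_TypeI": 58,
    "Cas3a_TypeI": 8,
    "other_cas": 82,
}
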