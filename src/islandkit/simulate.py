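"""Seeded synthetic genome annotations with a ground-truth manifest.

The generator emulates the spatial and statistical structure the survey
pipeline consumes, so every stage is testable without any external data:

* multi-contig genomes carrying planted islands of known class, with
  controlled inter-element gaps around the 50 kb chaining threshold
  (including just-over-threshold decoys and negative gaps that force
  overlapping or embedded elements);
* background features separated from everything else by more than the
  threshold, so they can never chain into a planted island;
* prophage sequences with controlled GC content and verbatim planted
  protospacers on either strand, plus decoy spacers with no target;
* prophage quality tables whose scores and completeness/contamination
  values span the 70/90 score boundaries and the 90 %/5 % quality gates.

Everything is drawn from ``numpy`` generators seeded from ``SimConfig.seed``,
so a fixed seed reproduces every output byte for byte.  The manifest records
what was planted and what the detector is expected to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as fio
from .islands import classify_island
from .model import (
    AnnotationSet,
    Category,
    FeatureError,
    GenomicFeature,
    Thresholds,
    DEFAULT_THRESHOLDS,
)
from .prophages import (
    INCOMPLETE,
    INTACT,
    QUESTIONABLE,
    UNSCORED,
    ProphageRecord,
    classify_score,
    passes_quality,
)
from .spacers import Spacer

__all__ = [
    "IslandSpec",
    "SimConfig",
    "GroundTruthManifest",
    "SimResult",
    "generate",
    "default_island_specs",
]

MANIFEST_SCHEMA_VERSION = "islandkit-manifest/1"

# plausible element length ranges (bp) per category
_LENGTH_RANGES = {
    Category.BGC: (10_000, 30_000),
    Category.DEFENSE_SYSTEM: (1_000, 6_000),
    Category.CRISPR_ARRAY: (500, 2_000),
    Category.CAS_CLUSTER: (5_000, 10_000),
    Category.PROPHAGE: (36_000, 61_000),
}

_SUBTYPES = {
    Category.BGC: ("ectoine", "terpene", "T3PKS", "betalactone", "NI-siderophore",
                   "lanthipeptide-class-III", "hserlactone", "hydrogen-cyanide"),
    Category.DEFENSE_SYSTEM: ("RM_Type_I", "RM_Type_IIG", "Hachiman", "AbiD",
                              "Belisama", "Mokosh_TypeII", "Ceres", "gcu233"),
    Category.CRISPR_ARRAY: ("CRISPR",),
    Category.CAS_CLUSTER: ("cas_TypeI-E", "cas_TypeI-F"),
    Category.PROPHAGE: ("prophage",),
}


@dataclass(frozen=True)
class IslandSpec:
    """One planted element chain.

    ``gap_bp_list`` holds the intervening distance planted between adjacent
    members (length = members - 1).  Values above the detection threshold
    split the chain (decoys); negative values force the next member to
    overlap the previous one, exercising overlap/embedding records.
    ``class_label`` is the expected island class, or ``None`` for chains
    that must not be detected as islands at all (e.g. a BGC-only chain).
    """

    member_categories: Tuple[Category, ...]
    gap_bp_list: Tuple[int, ...]
    class_label: Optional[str] = None
    contig_index: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.gap_bp_list) != len(self.member_categories) - 1:
            raise FeatureError(
                "gap_bp_list must have one entry fewer than member_categories"
            )
        if not self.member_categories:
            raise FeatureError("IslandSpec needs at least one member")


def default_island_specs(max_gap_bp: int = DEFAULT_THRESHOLDS.max_gap_bp) -> List[IslandSpec]:
    """The default planting mix, mirroring the published survey architectures.

    Mostly two-member defense-metabolite pairs (the dominant published
    class), the published gap arithmetic for the prophage-metabolite and
    combined quartet cases, embedded/overlapping variants, and
    just-over-threshold decoys that must split into non-islands.
    """
    B, D, C, A, P = (Category.BGC, Category.DEFENSE_SYSTEM, Category.CRISPR_ARRAY,
                     Category.CAS_CLUSTER, Category.PROPHAGE)
    return [
        IslandSpec((B, D), (27_170,), "defense-metabolite"),
        IslandSpec((D, B), (12_000,), "defense-metabolite"),
        IslandSpec((B, C), (5_000,), "CRISPR-metabolite"),
        IslandSpec((B, A), (45_000,), "Cas-metabolite"),
        IslandSpec((C, A, D, B), (78, 10_303, 24_980), "combined CRISPR-Cas-defense-metabolite"),
        IslandSpec((B, P), (39_414,), "prophage-metabolite"),
        IslandSpec((P, D, B), (8_000, 15_000), "prophage-defensive-metabolic"),
        # embedded defense system inside a BGC (negative gap rewinds into it;
        # magnitude stays below the minimum BGC length so layout is feasible)
        IslandSpec((B, D), (-8_000,), "defense-metabolite"),
        # gap exactly at the threshold still chains
        IslandSpec((B, D), (max_gap_bp,), "defense-metabolite"),
        # decoys: one base over the threshold must split into non-islands
        IslandSpec((B, D), (max_gap_bp + 1,), None),
        IslandSpec((B, B), (2_000,), None),  # no defensive element: not an island
    ]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genomes: int = 5
    contigs_per_genome: Tuple[int, int] = (2, 4)
    contig_len_bp: Tuple[int, int] = (400_000, 800_000)
    planted_islands: Optional[Sequence[IslandSpec]] = None  # default mix if None
    background_features_per_genome: int = 6
    background_min_separation_bp: Optional[int] = None  # default: max_gap + 10 kb
    n_prophages: int = 8
    prophage_len_bp: Tuple[int, int] = (36_000, 61_000)
    gc_target_pct: Tuple[float, float] = (40.0, 66.0)
    protospacers_per_prophage: int = 2
    n_decoy_spacers: int = 4
    spacer_len_nt: int = 32
    thresholds: Thresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        for name in ("contigs_per_genome", "contig_len_bp", "prophage_len_bp"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise FeatureError(f"degenerate range for {name}: ({lo}, {hi})")
        if self.spacer_len_nt < 1:
            raise FeatureError("spacer_len_nt must be positive")


@dataclass
class GroundTruthManifest:
    """What was planted, and what the pipeline must recover."""

    planted_islands: List[dict] = field(default_factory=list)
    planted_hits: List[dict] = field(default_factory=list)
    decoy_spacers: List[str] = field(default_factory=list)
    triage: Dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": MANIFEST_SCHEMA_VERSION,
                "seed": self.seed,
                "planted_islands": self.planted_islands,
                "planted_hits": self.planted_hits,
                "decoy_spacers": self.decoy_spacers,
                "triage": self.triage,
            },
            indent=1,
        ) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        data = json.loads(text)
        if data.get("schema_version") != MANIFEST_SCHEMA_VERSION:
            raise FeatureError(f"unsupported manifest schema {data.get('schema_version')!r}")
        return cls(
            planted_islands=data["planted_islands"],
            planted_hits=data["planted_hits"],
            decoy_spacers=data["decoy_spacers"],
            triage=data["triage"],
            seed=data["seed"],
        )


@dataclass
class SimResult:
    annotation_sets: List[AnnotationSet]
    prophage_seqs: Dict[str, str]
    spacers: List[Spacer]
    quality_records: List[ProphageRecord]
    manifest: GroundTruthManifest
    gc_targets: Dict[str, float] = field(default_factory=dict)

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for annset in self.annotation_sets:
            path = outdir / f"features_{annset.genome_id}.tsv"
            path.write_text(fio.write_features(annset, "native_tsv"))
        with open(outdir / "prophages.fasta", "w") as fh:
            for pid, seq in self.prophage_seqs.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(outdir / "spacers.fasta", "w") as fh:
            for sp in self.spacers:
                fh.write(f">{sp.spacer_id}\n{sp.sequence}\n")
        with open(outdir / "quality.tsv", "w") as fh:
            fh.write("prophage_id\tgenome_id\tcontig_id\tstart\tend\tscore\t"
                     "completeness_pct\tcontamination_pct\n")
            for r in self.quality_records:
                def cell(v):
                    return "" if v is None else (f"{v:g}" if isinstance(v, float) else str(v))
                fh.write("\t".join([
                    r.prophage_id, r.genome_id, r.contig_id,
                    cell(r.start), cell(r.end), cell(r.score),
                    cell(r.completeness_pct), cell(r.contamination_pct),
                ]) + "\n")
        (outdir / "manifest.json").write_text(self.manifest.to_json())


def _sample_len(rng: np.random.Generator, category: Category) -> int:
    lo, hi = _LENGTH_RANGES[category]
    return int(rng.integers(lo, hi + 1))


def _spec_layout(
    rng: np.random.Generator, spec: IslandSpec
) -> Tuple[List[Tuple[int, int]], int]:
    """Relative member coordinates (offset from segment start 0) and extent."""
    coords: List[Tuple[int, int]] = []
    cursor = 0
    max_end = -1
    for i, cat in enumerate(spec.member_categories):
        length = _sample_len(rng, cat)
        start = cursor
        if start < 0:
            raise FeatureError(f"negative gap rewinds before segment start in {spec}")
        end = start + length - 1
        coords.append((start, end))
        max_end = max(max_end, end)
        if i < len(spec.gap_bp_list):
            cursor = end + 1 + spec.gap_bp_list[i]
    return coords, max_end + 1


def _expected_fragments(spec: IslandSpec, max_gap_bp: int) -> List[List[int]]:
    """Split member indices at planted gaps over the threshold."""
    frags: List[List[int]] = [[0]]
    for i, gap in enumerate(spec.gap_bp_list):
        if gap > max_gap_bp:
            frags.append([])
        frags[-1].append(i + 1)
    return frags


def _plant_islands(
    rng: np.random.Generator,
    genome_id: str,
    contig_lens: List[int],
    specs: Sequence[IslandSpec],
    thresholds: Thresholds,
    features: List[GenomicFeature],
    manifest: GroundTruthManifest,
    cursors: List[int],
    separation: int,
) -> None:
    for k, spec in enumerate(specs):
        coords, extent = _spec_layout(rng, spec)
        placed = False
        order = (
            [spec.contig_index]
            if spec.contig_index is not None
            else list(rng.permutation(len(contig_lens)))
        )
        for ci in order:
            if cursors[ci] + extent + 1 <= contig_lens[ci]:
                base = cursors[ci] + 1
                contig = f"ctg{ci + 1}"
                member_ids = []
                for m, (off_start, off_end) in enumerate(coords):
                    cat = spec.member_categories[m]
                    sub = str(rng.choice(_SUBTYPES[cat]))
                    fid = f"{genome_id}:{contig}:isl{k + 1}:m{m + 1}"
                    features.append(
                        GenomicFeature(
                            fid, genome_id, contig, base + off_start, base + off_end,
                            cat, sub, "simulated",
                        )
                    )
                    member_ids.append(fid)
                cursors[ci] = base + extent - 1 + separation
                detectable = all(g <= thresholds.max_gap_bp for g in spec.gap_bp_list)
                label = spec.class_label
                if detectable and label is None and classify_island(
                    [f for f in features if f.feature_id in member_ids]
                ) is not None:
                    raise FeatureError(
                        f"spec {spec} declared non-island but its members qualify"
                    )
                if not detectable:
                    # fragments left behind must not themselves qualify as islands
                    for frag in _expected_fragments(spec, thresholds.max_gap_bp):
                        frag_members = [features[-len(coords) + i] for i in frag]
                        if classify_island(frag_members) is not None:
                            raise FeatureError(
                                f"decoy spec {spec} leaves an island-qualifying fragment"
                            )
                manifest.planted_islands.append(
                    {
                        "genome_id": genome_id,
                        "contig_id": contig,
                        "member_ids": member_ids,
                        "expected_class": label if detectable else None,
                        "detectable": bool(detectable and label is not None),
                        "gap_bp_list": list(spec.gap_bp_list),
                    }
                )
                placed = True
                break
        if not placed:
            raise FeatureError(
                f"infeasible placement: island spec of extent {extent} bp does not "
                f"fit on any contig of {genome_id}"
            )


def _plant_background(
    rng: np.random.Generator,
    genome_id: str,
    contig_lens: List[int],
    n: int,
    features: List[GenomicFeature],
    cursors: List[int],
    separation: int,
) -> None:
    cats = list(Category)
    for k in range(n):
        cat = cats[int(rng.integers(len(cats)))]
        length = _sample_len(rng, cat)
        for ci in rng.permutation(len(contig_lens)):
            if cursors[ci] + length + 1 <= contig_lens[ci]:
                start = cursors[ci] + 1
                contig = f"ctg{ci + 1}"
                fid = f"{genome_id}:{contig}:bg{k + 1}"
                features.append(
                    GenomicFeature(
                        fid, genome_id, contig, start, start + length - 1, cat,
                        str(rng.choice(_SUBTYPES[cat])), "simulated",
                    )
                )
                cursors[ci] = start + length - 1 + separation
                break
        # silently skip background features that no longer fit


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc_pct: Optional[float] = None) -> str:
    if gc_pct is None:
        probs = np.full(4, 0.25)
    else:
        g = gc_pct / 100.0
        probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def _count_occurrences(needle: str, seqs: Dict[str, str]) -> int:
    from .spacers import reverse_complement

    rc = reverse_complement(needle)
    n = 0
    for seq in seqs.values():
        n += seq.count(needle) + (seq.count(rc) if rc != needle else 0)
    return n


def generate(config: SimConfig) -> SimResult:
    """Generate one synthetic dataset; deterministic under a fixed seed."""
    specs = (
        list(config.planted_islands)
        if config.planted_islands is not None
        else default_island_specs(config.thresholds.max_gap_bp)
    )
    separation = (
        config.background_min_separation_bp
        if config.background_min_separation_bp is not None
        else config.thresholds.max_gap_bp + 10_000
    )
    if separation <= config.thresholds.max_gap_bp:
        raise FeatureError(
            "background separation must exceed max_gap_bp or background features "
            "could chain into planted islands"
        )
    manifest = GroundTruthManifest(seed=config.seed)
    annotation_sets: List[AnnotationSet] = []

    for g in range(config.n_genomes):
        rng = np.random.default_rng([config.seed, 1, g])
        genome_id = f"simg{g + 1}"
        n_ctg = int(rng.integers(config.contigs_per_genome[0], config.contigs_per_genome[1] + 1))
        contig_lens = [
            int(rng.integers(config.contig_len_bp[0], config.contig_len_bp[1] + 1))
            for _ in range(n_ctg)
        ]
        features: List[GenomicFeature] = []
        cursors = [0] * n_ctg
        genome_specs = [s for i, s in enumerate(specs) if i % config.n_genomes == g]
        _plant_islands(
            rng, genome_id, contig_lens, genome_specs, config.thresholds,
            features, manifest, cursors, separation,
        )
        _plant_background(
            rng, genome_id, contig_lens, config.background_features_per_genome,
            features, cursors, separation,
        )
        annotation_sets.append(AnnotationSet(genome_id, features))

    # prophage sequences with planted protospacers
    rng = np.random.default_rng([config.seed, 2])
    prophage_seqs: Dict[str, str] = {}
    gc_targets: Dict[str, float] = {}
    for p in range(config.n_prophages):
        pid = f"Ph_sim{p + 1}"
        length = int(rng.integers(config.prophage_len_bp[0], config.prophage_len_bp[1] + 1))
        gc = float(rng.uniform(*config.gc_target_pct))
        prophage_seqs[pid] = _random_seq(rng, length, gc)
        gc_targets[pid] = gc

    spacers: List[Spacer] = []
    from .spacers import reverse_complement

    for p, pid in enumerate(prophage_seqs):
        seq = prophage_seqs[pid]
        for j in range(config.protospacers_per_prophage):
            for _attempt in range(20):
                spacer_seq = _random_seq(rng, config.spacer_len_nt)
                pos = int(rng.integers(1, len(seq) - config.spacer_len_nt + 2))
                strand = "+" if rng.random() < 0.5 else "-"
                embedded = spacer_seq if strand == "+" else reverse_complement(spacer_seq)
                candidate = seq[: pos - 1] + embedded + seq[pos - 1 + config.spacer_len_nt :]
                trial = dict(prophage_seqs)
                trial[pid] = candidate
                if _count_occurrences(spacer_seq, trial) == 1:
                    seq = candidate
                    prophage_seqs[pid] = candidate
                    sid = f"sp_{pid}_{j + 1}"
                    spacers.append(Spacer(sid, spacer_seq, array_id=f"array_{pid}",
                                          genome_id=f"simg{(p % config.n_genomes) + 1}"))
                    manifest.planted_hits.append(
                        {"spacer_id": sid, "target_id": pid, "position": pos,
                         "strand": strand}
                    )
                    break
            else:  # pragma: no cover - astronomically unlikely at 32 nt
                raise FeatureError("could not place a unique protospacer")

    for d in range(config.n_decoy_spacers):
        for _attempt in range(20):
            decoy = _random_seq(rng, config.spacer_len_nt)
            if _count_occurrences(decoy, prophage_seqs) == 0:
                sid = f"sp_decoy_{d + 1}"
                spacers.append(Spacer(sid, decoy))
                manifest.decoy_spacers.append(sid)
                break
        else:  # pragma: no cover
            raise FeatureError("could not generate a non-matching decoy spacer")

    # quality table spanning the triage boundaries and the quality gates
    rng = np.random.default_rng([config.seed, 3])
    quality_records: List[ProphageRecord] = []
    class_cycle = [INTACT, QUESTIONABLE, INCOMPLETE, UNSCORED]
    gate_corners = [(95.0, 0.0), (90.0, 4.0), (95.0, 5.0), (90.1, 4.9), (85.0, 6.0)]
    for p, pid in enumerate(prophage_seqs):
        cls = class_cycle[p % len(class_cycle)]
        if cls == INTACT:
            score: Optional[float] = float(rng.uniform(90.5, 150.0))
        elif cls == QUESTIONABLE:
            score = float(rng.uniform(70.0, 90.0))
        elif cls == INCOMPLETE:
            score = float(rng.uniform(10.0, 69.5))
        else:
            score = None
        comp, cont = gate_corners[p % len(gate_corners)]
        quality_records.append(
            ProphageRecord(pid, genome_id=f"simg{(p % config.n_genomes) + 1}",
                           score=score, completeness_pct=comp, contamination_pct=cont)
        )
        manifest.triage[pid] = {
            "expected_class": cls,
            "expected_pass": bool(comp > 90.0 and cont < 5.0),
        }
    # explicit boundary plantings for the score rule
    for score, cls in ((69.0, INCOMPLETE), (70.0, QUESTIONABLE), (90.0, QUESTIONABLE), (91.0, INTACT)):
        pid = f"Ph_boundary_{int(score)}"
        quality_records.append(ProphageRecord(pid, score=score))
        manifest.triage[pid] = {"expected_class": cls, "expected_pass": None}

    return SimResult(annotation_sets, prophage_seqs, spacers, quality_records, manifest, gc_targets)
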