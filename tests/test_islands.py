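"""Island chaining, classification and overlap recording.

The chaining oracle is brute force: union-find over the symmetric pairwise
relation "intervening distance <= threshold" computed on all feature pairs.
"""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from islandkit.islands import (
    CAS_DEFENSE_METABOLITE,
    CAS_METABOLITE,
    COMBINED_CRISPR_CAS_DEFENSE_METABOLITE,
    CRISPR_DEFENSE_METABOLITE,
    CRISPR_METABOLITE,
    DEFENSE_METABOLITE,
    PROPHAGE_DEFENSIVE_METABOLIC,
    PROPHAGE_METABOLITE,
    chain_contig,
    classify_island,
    detect_islands,
    detect_overlaps,
    gap_bp,
)
from islandkit.examples import island_fixture
from islandkit.model import AnnotationSet, Category, FeatureError, Thresholds

from conftest import make_feature

B, D, C, A, P = (
    Category.BGC,
    Category.DEFENSE_SYSTEM,
    Category.CRISPR_ARRAY,
    Category.CAS_CLUSTER,
    Category.PROPHAGE,
)


def pairwise_gap(a, b):
    """Symmetric intervening distance between two intervals."""
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


def brute_force_clusters(features, max_gap):
    """Transitive closure of gap <= max_gap via union-find over all pairs."""
    parent = {f.feature_id: f.feature_id for f in features}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(features, 2):
        if pairwise_gap(a, b) <= max_gap:
            parent[find(a.feature_id)] = find(b.feature_id)
    groups = {}
    for f in features:
        groups.setdefault(find(f.feature_id), set()).add(f.feature_id)
    return {frozenset(g) for g in groups.values()}


contig_features = st.lists(
    st.tuples(st.integers(1, 500_000), st.integers(0, 80_000)),
    min_size=0,
    max_size=25,
).map(
    lambda spans: [
        make_feature(s, s + d, list(Category)[i % 5], fid=f"f{i}")
        for i, (s, d) in enumerate(spans)
    ]
)


class TestGap:
    @pytest.mark.parametrize(
        "a_span, b_span, expected",
        [
            ((746_012, 777_519), (804_690, 805_508), 27_170),
            ((3_415_756, 3_438_299), (3_477_714, 3_537_879), 39_414),
            ((657_024, 657_967), (658_046, 666_649), 78),
            ((100, 200), (201, 300), 0),  # abutting
            ((100, 200), (150, 250), 0),  # overlapping
            ((100, 200), (100, 200), 0),  # identical spans
        ],
    )
    def test_intervening_distance(self, a_span, b_span, expected):
        a = make_feature(*a_span, fid="a")
        b = make_feature(*b_span, fid="b")
        assert gap_bp(a, b) == expected

    def test_cross_contig_is_an_error(self):
        a = make_feature(1, 10, fid="a", contig="ctg1")
        b = make_feature(20, 30, fid="b", contig="ctg2")
        with pytest.raises(FeatureError, match="contig"):
            gap_bp(a, b)


class TestChaining:
    def test_quartet_with_published_gaps_chains_into_one_cluster(self):
        annset, _ = island_fixture("tgb10")
        clusters = chain_contig(annset.contig_features("ctg1"), 50_000)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_gap_at_threshold_chains_and_one_over_splits(self):
        a = make_feature(1, 100, fid="a")
        b_at = make_feature(100 + 1 + 50_000, 60_000 + 101, fid="b")
        assert len(chain_contig([a, b_at], 50_000)) == 1
        b_over = make_feature(100 + 2 + 50_000, 60_000 + 102, fid="b")
        assert len(chain_contig([a, b_over], 50_000)) == 2

    def test_empty_input(self):
        assert chain_contig([], 50_000) == []

    def test_containment_links_through_covering_feature(self):
        # b sits inside a; c is far from b but within reach of a's end
        a = make_feature(1, 200_000, fid="a")
        b = make_feature(10, 20, fid="b")
        c = make_feature(240_000, 240_100, fid="c")
        clusters = chain_contig([a, b, c], 50_000)
        assert len(clusters) == 1

    @given(features=contig_features, max_gap=st.integers(1, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_sweep_equals_brute_force_closure(self, features, max_gap):
        clusters = chain_contig(features, max_gap)
        got = {frozenset(f.feature_id for f in cl) for cl in clusters}
        assert got == brute_force_clusters(features, max_gap)

    @given(features=contig_features, t1=st.integers(1, 60_000), t2=st.integers(0, 40_000))
    @settings(max_examples=100, deadline=None)
    def test_threshold_monotonicity(self, features, t1, t2):
        small = chain_contig(features, t1)
        big = chain_contig(features, t1 + t2)
        big_sets = [{f.feature_id for f in cl} for cl in big]
        for cl in small:
            ids = {f.feature_id for f in cl}
            assert any(ids <= bs for bs in big_sets)


class TestClassification:
    @pytest.mark.parametrize(
        "cats, expected",
        [
            ((B, D), DEFENSE_METABOLITE),
            ((B, C), CRISPR_METABOLITE),
            ((B, A), CAS_METABOLITE),
            ((B, C, A), COMBINED_CRISPR_CAS_DEFENSE_METABOLITE),
            ((B, C, A, D), COMBINED_CRISPR_CAS_DEFENSE_METABOLITE),
            ((B, C, D), CRISPR_DEFENSE_METABOLITE),
            ((B, A, D), CAS_DEFENSE_METABOLITE),
            ((B, P), PROPHAGE_METABOLITE),
            ((B, P, D), PROPHAGE_DEFENSIVE_METABOLIC),
            ((B, P, C), PROPHAGE_DEFENSIVE_METABOLIC),
            ((B, P, C, A, D), PROPHAGE_DEFENSIVE_METABOLIC),
            ((B,), None),
            ((B, B), None),
            ((D, C, A), None),  # no metabolic anchor
            ((P, D), None),
        ],
    )
    def test_label_is_pure_function_of_category_set(self, cats, expected):
        members = [
            make_feature(1 + 1000 * i, 500 + 1000 * i, cat, fid=f"m{i}")
            for i, cat in enumerate(cats)
        ]
        assert classify_island(members) == expected

    def test_empty_cluster_is_an_error(self):
        with pytest.raises(FeatureError):
            classify_island([])

    def test_anti_defense_counts_as_defensive(self):
        members = [
            make_feature(1, 10_000, B, fid="bgc"),
            make_feature(20_000, 21_000, D, fid="anti", subtype="anti:ardc"),
        ]
        assert classify_island(members) == DEFENSE_METABOLITE


class TestOverlaps:
    def test_embedded_defense_system_recorded_as_contains(self):
        bgc = make_feature(100, 1_000, B, fid="bgc")
        defense = make_feature(400, 600, D, fid="def")
        (rec,) = detect_overlaps([bgc, defense])
        assert rec.relation == "contains" and rec.overlap_bp == 201
        assert (rec.feature_a, rec.feature_b) == ("bgc", "def")

    @pytest.mark.parametrize(
        "a_span, b_span, relation, bp",
        [
            ((1, 10), (5, 20), "partial", 6),
            ((5, 20), (5, 20), "identical", 16),
            # feature_a is always first in (start, end, id) sort order, so
            # the relation is reported from the earlier feature's viewpoint
            ((1, 100), (1, 50), "contained_by", 50),
            ((10, 50), (1, 100), "contains", 41),
        ],
    )
    def test_relations(self, a_span, b_span, relation, bp):
        a = make_feature(*a_span, fid="a")
        b = make_feature(*b_span, fid="b")
        (rec,) = detect_overlaps([a, b])
        assert (rec.relation, rec.overlap_bp) == (relation, bp)

    def test_disjoint_features_yield_no_records(self):
        assert detect_overlaps([make_feature(1, 10, fid="a"), make_feature(20, 30, fid="b")]) == []


class TestDetectIslands:
    @pytest.mark.parametrize("name", ["tgb10", "ibrc_m_10908k", "oceanimonas"])
    def test_worked_examples(self, name):
        annset, expected = island_fixture(name)
        islands = detect_islands(annset)
        assert len(islands) == expected["n_islands"]
        isl = islands[0]
        assert isl.island_class == expected["island_class"]
        assert isl.n_members == expected["n_members"]
        assert list(isl.gaps_bp) == expected["gaps_bp"]
        assert isl.span_start == min(f.start for f in isl.members)
        assert isl.span_end == max(f.end for f in isl.members)

    def test_nonisland_clusters_reported_separately(self):
        feats = [
            make_feature(1, 10_000, B, fid="bgc1"),
            make_feature(12_000, 15_000, B, fid="bgc2"),
        ]
        islands, nonislands = detect_islands(
            AnnotationSet("g1", feats), return_nonislands=True
        )
        assert islands == [] and len(nonislands) == 1

    def test_islands_partition_features_and_never_share_members(self):
        feats = [
            make_feature(1, 10_000, B, fid="b1"),
            make_feature(15_000, 16_000, D, fid="d1"),
            make_feature(200_000, 210_000, B, fid="b2"),
            make_feature(215_000, 216_000, C, fid="c1"),
        ]
        islands = detect_islands(AnnotationSet("g1", feats))
        ids = [fid for isl in islands for fid in isl.member_ids]
        assert len(ids) == len(set(ids)) == 4

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_input_order_invariance(self, data):
        features = data.draw(contig_features)
        perm = data.draw(st.permutations(features))
        t = Thresholds()
        a = detect_islands(AnnotationSet("g1", features), t)
        b = detect_islands(AnnotationSet("g1", perm), t)
        assert [(i.island_id, i.member_ids, i.island_class) for i in a] == [
            (i.island_id, i.member_ids, i.island_class) for i in b
        ]

    def test_deterministic_island_ids(self):
        annset, _ = island_fixture("tgb10")
        (isl,) = detect_islands(annset)
        assert isl.island_id == "S_proteolyticus_TGB10:ctg1:1"
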