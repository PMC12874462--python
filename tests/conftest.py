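import pytest

from islandkit.model import AnnotationSet, Category, GenomicFeature


def make_feature(
    start,
    end,
    category=Category.BGC,
    fid=None,
    contig="ctg1",
    genome="g1",
    subtype="",
):
    return GenomicFeature(
        feature_id=fid or f"{genome}:{contig}:{start}-{end}:{Category(category).value}",
        genome_id=genome,
        contig_id=contig,
        start=start,
        end=end,
        category=category,
        subtype=subtype,
        source="test",
    )


@pytest.fixture
def three_feature_set():
    feats = [
        make_feature(100, 1_000, Category.BGC, subtype="ectoine"),
        make_feature(5_000, 6_000, Category.DEFENSE_SYSTEM, subtype="RM_Type_I"),
        make_feature(9_000, 9_500, Category.CRISPR_ARRAY, subtype="CRISPR"),
    ]
    return AnnotationSet("g1", feats)
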