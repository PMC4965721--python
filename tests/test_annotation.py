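"""Genomic-context classification, isoform choice, interval enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conmeth.annotation import (
    FeatureIndex,
    classify_region,
    gene_features,
    interval_enrichment,
    location_distribution,
    select_reference_isoform,
)


def gene(tx, gid, strand="+", txStart=10_000, txEnd=18_000,
         cdsStart=12_000, cdsEnd=16_000,
         exonStarts=(10_000, 13_000, 15_500), exonEnds=(12_500, 14_000, 18_000)):
    return dict(transcript_id=tx, gene_id=gid, chrom="chr1", strand=strand,
                txStart=txStart, txEnd=txEnd, cdsStart=cdsStart, cdsEnd=cdsEnd,
                exonStarts=exonStarts, exonEnds=exonEnds)


def test_longest_isoform_selected():
    genes = pd.DataFrame([gene("tx1", "g1", txEnd=15_000),
                          gene("tx2", "g1", txEnd=18_000)])
    ref = select_reference_isoform(genes)
    assert ref.loc[0, "transcript_id"] == "tx2"


def test_single_isoform_is_itself_and_ties_break_lexicographically():
    genes = pd.DataFrame([gene("txB", "g1"), gene("txA", "g1"), gene("txZ", "g2")])
    ref = select_reference_isoform(genes).set_index("gene_id")
    assert ref.loc["g1", "transcript_id"] == "txA"
    assert ref.loc["g2", "transcript_id"] == "txZ"


def test_promoter_interval_definition():
    feats = gene_features(pd.DataFrame([gene("tx1", "g1")]))
    prom = feats[feats["feature_class"] == "promoter"].iloc[0]
    assert (prom.start, prom.end) == (8_000, 10_000)


def test_promoter_reflects_with_strand():
    plus = gene_features(pd.DataFrame([gene("tx1", "g1", strand="+")]))
    minus = gene_features(pd.DataFrame([gene("tx1", "g1", strand="-")]))
    p = plus[plus["feature_class"] == "promoter"].iloc[0]
    m = minus[minus["feature_class"] == "promoter"].iloc[0]
    assert (p.start, p.end) == (8_000, 10_000)
    assert (m.start, m.end) == (18_000, 20_000)
    # UTR identities swap as well
    p5 = set(map(tuple, plus[plus["feature_class"] == "utr5"][["start", "end"]].values))
    m3 = set(map(tuple, minus[minus["feature_class"] == "utr3"][["start", "end"]].values))
    assert p5 == m3


@pytest.fixture()
def toy_index():
    feats = gene_features(pd.DataFrame([gene("tx1", "g1")]))
    tracks = {
        "cpg_island": pd.DataFrame({"chrom": ["chr1"], "start": [6_000], "end": [8_000]}),
        "repeat": pd.DataFrame({"chrom": ["chr1"], "start": [30_000], "end": [31_000]}),
    }
    return FeatureIndex(feats, tracks)


def test_overlap_labels(toy_index):
    assert "promoter" in classify_region(("chr1", 8_500, 9_500), toy_index)
    # inside the gene, overlapping only intron intervals
    labels = classify_region(("chr1", 12_600, 12_900), toy_index)
    assert "intron" in labels and "exon" not in labels and "intergenic" not in labels


def test_shore_boundary_inclusive_at_2kb(toy_index):
    # island [6000, 8000): gap of exactly 2000 bp still counts as shore
    labels = classify_region(("chr1", 10_000, 11_000), toy_index)
    assert "shore" in labels and "cpg_island" not in labels
    labels = classify_region(("chr1", 10_001, 11_000), toy_index)
    assert "shore" not in labels
    labels = classify_region(("chr1", 7_000, 7_500), toy_index)
    assert "cpg_island" in labels and "shore" not in labels


def test_repeat_and_complement_labels(toy_index):
    assert "repeat" in classify_region(("chr1", 30_500, 30_600), toy_index)
    assert "non_repeat" in classify_region(("chr1", 40_000, 41_000), toy_index)


def test_intergenic_means_no_gene_or_promoter(toy_index):
    labels = classify_region(("chr1", 50_000, 51_000), toy_index)
    assert "intergenic" in labels


def test_unknown_chromosome_raises(toy_index):
    with pytest.raises(ValueError, match="chr9"):
        classify_region(("chr9", 0, 100), toy_index)


def test_location_distribution_counts(toy_index):
    q = pd.DataFrame({"chrom": ["chr1"] * 4,
                      "start": [8_500, 9_000, 40_000, 50_000],
                      "end": [9_000, 9_500, 41_000, 51_000]})
    bg = pd.DataFrame({"chrom": ["chr1"] * 8,
                       "start": [8_500, 9_000, 40_000, 50_000, 60_000, 61_000, 62_000, 63_000],
                       "end": [9_000, 9_500, 41_000, 51_000, 60_500, 61_500, 62_500, 63_500]})
    tbl = location_distribution(q, bg, toy_index)
    assert tbl.loc["promoter", "query_fraction"] == pytest.approx(0.5)
    assert tbl.loc["promoter", "background_fraction"] == pytest.approx(0.25)
    # query == background -> identical rows
    same = location_distribution(q, q, toy_index)
    assert (same["query_fraction"] == same["background_fraction"]).all()
    with pytest.raises(ValueError):
        location_distribution(q.iloc[:0], bg, toy_index)


def test_distribution_invariant_to_feature_order():
    base = pd.DataFrame([gene("tx1", "g1"), gene("tx9", "g2", txStart=40_000,
                                                 txEnd=48_000, cdsStart=42_000,
                                                 cdsEnd=46_000,
                                                 exonStarts=(40_000, 45_500),
                                                 exonEnds=(42_500, 48_000))])
    q = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [8_500, 41_000, 70_000],
                      "end": [9_000, 41_200, 71_000]})
    f1 = gene_features(base)
    f2 = gene_features(base.iloc[::-1].reset_index(drop=True))
    t1 = location_distribution(q, q, FeatureIndex(f1))
    t2 = location_distribution(q, q, FeatureIndex(f2))
    pd.testing.assert_frame_equal(t1, t2)


def naive_classify(region, features, tracks, shore_bp=2000):
    """O(n*m) reference scan used as the independent classification oracle."""
    chrom, start, end = region
    labels = set()
    genic = {"promoter", "utr5", "exon", "intron", "utr3"}
    hit_genic = False
    for f in features.itertuples(index=False):
        if f.chrom == chrom and f.start < end and f.end > start:
            labels.add(f.feature_class)
            if f.feature_class in genic:
                hit_genic = True
    if not hit_genic:
        labels.add("intergenic")
    isl = tracks.get("cpg_island")
    if isl is not None:
        in_isl = near = False
        for f in isl.itertuples(index=False):
            if f.chrom != chrom:
                continue
            if f.start < end and f.end > start:
                in_isl = True
            elif f.start - end <= shore_bp and start - f.end <= shore_bp:
                near = True
        if in_isl:
            labels.add("cpg_island")
        elif near:
            labels.add("shore")
    rpt = tracks.get("repeat")
    if rpt is not None:
        hit = any(
            f.chrom == chrom and f.start < end and f.end > start
            for f in rpt.itertuples(index=False)
        )
        labels.add("repeat" if hit else "non_repeat")
    return labels


def test_classifier_agrees_with_naive_scan_on_random_regions(small_fixture):
    ann = small_fixture.annotation
    feats = ann.features
    tracks = {"cpg_island": ann.tracks["cpg_island"], "repeat": ann.tracks["repeat"]}
    index = FeatureIndex(feats, {**tracks, "enhancer": ann.tracks["enhancer"]})
    rng = np.random.default_rng(17)
    for _ in range(300):
        start = int(rng.integers(0, 199_000))
        end = start + int(rng.integers(50, 2_000))
        got = classify_region(("chr1", start, end), index)
        want = naive_classify(("chr1", start, end), feats, tracks)
        # enhancer track only known to the indexed classifier
        got.discard("enhancer")
        assert got == want, (start, end)


def test_interval_enrichment_chi_square_oracle():
    q = pd.DataFrame({"chrom": ["chr1"] * 10, "start": np.arange(10) * 100,
                      "end": np.arange(10) * 100 + 50})
    extra = pd.DataFrame({"chrom": ["chr1"] * 100, "start": 10_000 + np.arange(100) * 100,
                          "end": 10_000 + np.arange(100) * 100 + 50})
    bg = pd.concat([q, extra], ignore_index=True)
    # track hits all 10 query regions and 50 of the 100 background-only regions
    track = pd.concat([q, extra.iloc[:50]], ignore_index=True)
    res = interval_enrichment(q, {"t": track}, bg)
    chi2, p, _, _ = stats.chi2_contingency([[10, 0], [50, 50]], correction=False)
    assert res.loc["t", "chi2"] == pytest.approx(chi2)
    assert res.loc["t", "p"] == pytest.approx(p)
    assert res.loc["t", "method"] == "chi2"


def test_interval_enrichment_homogeneous_rates_and_fdr():
    regions = pd.DataFrame({"chrom": ["chr1"] * 40, "start": np.arange(40) * 1000,
                            "end": np.arange(40) * 1000 + 500})
    q = regions.iloc[:10]
    # track hitting every other region: identical hit rate in query and rest
    track = regions.iloc[::2]
    tracks = {"a": track, "b": track, "empty": regions.iloc[:0].assign()}
    res = interval_enrichment(q, tracks, regions)
    assert res.loc["a", "p"] == pytest.approx(1.0, abs=0.05)
    assert len(res["q"]) == 3  # one BH-corrected value per track
    assert res.loc["empty", "method"] == "fisher"  # expected cell < 1 fallback


def test_enrichment_requires_query_within_background():
    q = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
    bg = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
    with pytest.raises(ValueError, match="subset"):
        interval_enrichment(q, {"t": bg}, bg)
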