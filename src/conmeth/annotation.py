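"""Genomic-context assignment and interval enrichment.

Regions are labelled by >=1-bp overlap with genic features derived
from the longest isoform of each gene (promoter = -2 kb..TSS,
5'UTR/exon/intron/3'UTR), plus user tracks (CpG islands, shores =
within 2 kb of an island, repeats, enhancers).  Labels are
non-exclusive, so per-class fractions need not sum to one.  The
co-localisation statistic is a 1-df chi-square on the 2x2 hit table of
query vs background-minus-query regions, BH-corrected across tracks,
falling back to Fisher's exact test when an expected cell drops
below 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .exact import bh_fdr, fisher_exact_two_sided

__all__ = [
    "select_reference_isoform",
    "gene_features",
    "FeatureIndex",
    "classify_region",
    "location_distribution",
    "interval_enrichment",
]

PROMOTER_BP = 2000
SHORE_BP = 2000

GENIC_CLASSES = ("promoter", "utr5", "exon", "intron", "utr3")


def select_reference_isoform(genes: pd.DataFrame) -> pd.DataFrame:
    """One transcript per gene: the longest span, ties broken by the
    lexicographically smallest transcript_id."""
    g = genes.copy()
    g["_span"] = g["txEnd"] - g["txStart"]
    g = g.sort_values(["gene_id", "_span", "transcript_id"],
                      ascending=[True, False, True], kind="mergesort")
    out = g.groupby("gene_id", as_index=False, sort=True).first()
    return out.drop(columns="_span").reset_index(drop=True)


def gene_features(genes: pd.DataFrame, promoter_bp: int = PROMOTER_BP) -> pd.DataFrame:
    """Derive promoter/utr5/exon/intron/utr3 intervals from reference isoforms.

    Intron intervals are the gene span minus the reference isoform's
    exons; UTRs are the exon portions outside the CDS, oriented by
    strand.  Promoters are [TSS - promoter_bp, TSS) on the plus strand
    and the mirrored interval downstream of txEnd on the minus strand.
    Coordinates are 0-based half-open throughout.
    """
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            prom = (max(0, g.txStart - promoter_bp), g.txStart)
        else:
            prom = (g.txEnd, g.txEnd + promoter_bp)
        rows.append(
            dict(chrom=g.chrom, start=prom[0], end=prom[1], strand=g.strand,
                 feature_class="promoter", gene_id=g.gene_id,
                 transcript_id=g.transcript_id)
        )
        exons = sorted(zip(g.exonStarts, g.exonEnds))
        for s, e in exons:
            rows.append(
                dict(chrom=g.chrom, start=s, end=e, strand=g.strand,
                     feature_class="exon", gene_id=g.gene_id,
                     transcript_id=g.transcript_id)
            )
            if s < g.cdsStart:
                cls = "utr5" if g.strand == "+" else "utr3"
                rows.append(
                    dict(chrom=g.chrom, start=s, end=min(e, g.cdsStart),
                         strand=g.strand, feature_class=cls, gene_id=g.gene_id,
                         transcript_id=g.transcript_id)
                )
            if e > g.cdsEnd:
                cls = "utr3" if g.strand == "+" else "utr5"
                rows.append(
                    dict(chrom=g.chrom, start=max(s, g.cdsEnd), end=e,
                         strand=g.strand, feature_class=cls, gene_id=g.gene_id,
                         transcript_id=g.transcript_id)
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 < s2:
                rows.append(
                    dict(chrom=g.chrom, start=e1, end=s2, strand=g.strand,
                         feature_class="intron", gene_id=g.gene_id,
                         transcript_id=g.transcript_id)
                )
    return pd.DataFrame(rows)


class FeatureIndex:
    """Interval index over genic features and annotation tracks.

    Parameters
    ----------
    features
        DataFrame with chrom/start/end/feature_class (e.g. from
        :func:`gene_features`); gene-body classes drive the
        'intergenic' complement label.
    tracks
        Optional mapping name -> BED DataFrame for cpg_island, repeat,
        enhancer or custom tracks.  Shores are derived from the
        cpg_island track (within ``shore_bp``, boundary inclusive),
        never supplied directly.
    """

    def __init__(self, features: pd.DataFrame, tracks: dict | None = None,
                 shore_bp: int = SHORE_BP):
        self.shore_bp = shore_bp
        self._trees: dict = {}
        self.chroms: set = set()
        for row in features.itertuples(index=False):
            self._add(row.feature_class, row.chrom, row.start, row.end)
        for name, bed in (tracks or {}).items():
            if name == "shore":  # always derived from islands
                continue
            for row in bed.itertuples(index=False):
                self._add(name, row.chrom, row.start, row.end)
        self.classes = sorted({cls for cls, _ in self._trees})

    def _add(self, cls, chrom, start, end):
        chrom = str(chrom)
        self.chroms.add(chrom)
        key = (cls, chrom)
        if key not in self._trees:
            self._trees[key] = IntervalTree()
        self._trees[key].addi(int(start), int(end))

    def overlaps(self, cls: str, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get((cls, chrom))
        return bool(tree is not None and tree.overlap(start, end))

    def near(self, cls: str, chrom: str, start: int, end: int, dist: int) -> bool:
        """True if any cls interval lies within ``dist`` bp of the region.

        Gap computed in half-open arithmetic (gap = start - other.end or
        other.start - end); a gap of exactly ``dist`` counts as near.
        """
        tree = self._trees.get((cls, chrom))
        if tree is None:
            return False
        return bool(tree.overlap(start - dist - 1, end + dist + 1))


def classify_region(region, index: FeatureIndex) -> set:
    """Non-exclusive context labels for one region (>=1-bp overlap rule).

    ``region`` is (chrom, start, end), 0-based half-open.  'intergenic'
    means no gene-body or promoter overlap; 'shore' means within
    shore_bp of a CpG island (gap of exactly shore_bp counts) without
    overlapping one; 'non_repeat' complements 'repeat' when a repeat
    track is present.
    """
    chrom, start, end = str(region[0]), int(region[1]), int(region[2])
    if chrom not in index.chroms:
        raise ValueError(f"region chromosome {chrom!r} absent from the feature set")
    labels = set()
    for cls in index.classes:
        if cls in ("cpg_island", "repeat"):
            continue
        if index.overlaps(cls, chrom, start, end):
            labels.add(cls)
    genic = {"promoter", *GENIC_CLASSES}
    if not any(index.overlaps(c, chrom, start, end) for c in genic):
        labels.add("intergenic")
    if ("cpg_island", chrom) in index._trees or any(
        k[0] == "cpg_island" for k in index._trees
    ):
        in_island = index.overlaps("cpg_island", chrom, start, end)
        if in_island:
            labels.add("cpg_island")
        elif index.near("cpg_island", chrom, start, end, index.shore_bp):
            labels.add("shore")
    if any(k[0] == "repeat" for k in index._trees):
        if index.overlaps("repeat", chrom, start, end):
            labels.add("repeat")
        else:
            labels.add("non_repeat")
    return labels


def location_distribution(
    query: pd.DataFrame, background: pd.DataFrame, index: FeatureIndex
) -> pd.DataFrame:
    """Per-class overlap fractions for query and background region sets.

    Returns a DataFrame indexed by feature class with query_count,
    query_fraction, background_count, background_fraction.  Classes are
    non-exclusive, so fractions need not sum to 1.
    """
    if len(query) == 0:
        raise ValueError("empty query region set")
    if len(background) == 0:
        raise ValueError("empty background region set")

    def count(regions):
        tally: dict = {}
        for row in regions.itertuples(index=False):
            for cls in classify_region((row.chrom, row.start, row.end), index):
                tally[cls] = tally.get(cls, 0) + 1
        return tally

    qt, bt = count(query), count(background)
    classes = sorted(set(qt) | set(bt))
    return pd.DataFrame(
        {
            "query_count": [qt.get(c, 0) for c in classes],
            "query_fraction": [qt.get(c, 0) / len(query) for c in classes],
            "background_count": [bt.get(c, 0) for c in classes],
            "background_fraction": [bt.get(c, 0) / len(background) for c in classes],
        },
        index=pd.Index(classes, name="feature_class"),
    )


def _hits(regions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    trees: dict = {}
    for row in track.itertuples(index=False):
        trees.setdefault(str(row.chrom), IntervalTree()).addi(int(row.start), int(row.end))
    out = np.zeros(len(regions), dtype=bool)
    for i, row in enumerate(regions.itertuples(index=False)):
        tree = trees.get(str(row.chrom))
        out[i] = bool(tree is not None and tree.overlap(int(row.start), int(row.end)))
    return out


def interval_enrichment(
    query: pd.DataFrame, tracks: dict, background: pd.DataFrame
) -> pd.DataFrame:
    """Chi-square co-localisation of query regions with each track.

    For each track the 2x2 table is [[query hit, query miss],
    [background-minus-query hit, miss]]; p from the 1-df chi-square
    (no continuity correction), BH across tracks.  When any expected
    cell is below 1 the p-value falls back to Fisher's exact test and
    the row is flagged method='fisher'.
    """
    qkey = set(map(tuple, query[["chrom", "start", "end"]].itertuples(index=False)))
    bkey = set(map(tuple, background[["chrom", "start", "end"]].itertuples(index=False)))
    if not qkey <= bkey:
        raise ValueError("query regions must be a subset of the background universe")
    rest = background[
        ~background[["chrom", "start", "end"]].apply(tuple, axis=1).isin(qkey)
    ]
    rows = []
    for name, track in tracks.items():
        qh = int(_hits(query, track).sum())
        rh = int(_hits(rest, track).sum())
        table = np.array([[qh, len(query) - qh], [rh, len(rest) - rh]], dtype=float)
        expected = stats.contingency.expected_freq(table) if table.sum() else table
        if table.sum() and expected.min() >= 1.0:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            method = "chi2"
        else:
            p = fisher_exact_two_sided(qh, len(query), rh, len(rest))
            chi2, method = np.nan, "fisher"
        rows.append(dict(track=name, chi2=chi2, p=p, method=method,
                         query_hits=qh, background_hits=rh))
    out = pd.DataFrame(rows).set_index("track")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
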