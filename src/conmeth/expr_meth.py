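"""Methylation in relation to expression.

Transcripts are stratified into four expression quartiles; methylation
is profiled over scaled genic units (gene body, UTRs, exons, introns)
with fixed-bp flanks and over fixed +/-200 bp exon/intron boundaries,
smoothed by LOESS-style tri-cube local linear regression; and
per-genic-class mean methylation is correlated with mean expression
across transcripts (Pearson).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "assign_quartiles",
    "average_cpg_methylation",
    "transcript_class_methylation",
    "region_class_correlation",
    "metagene_profile",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")

METAGENE_UNITS = ("gene", "utr5", "utr3", "exon", "intron")
BOUNDARY_UNITS = ("exon_boundary", "intron_boundary")


def assign_quartiles(mean_expr: pd.Series) -> pd.Series:
    """Rank transcripts into four near-equal expression groups Q1..Q4.

    Q1 is the lowest-expression quartile.  Ties are broken by stable
    transcript-id order; group sizes differ by at most one.
    """
    if len(mean_expr) < 4:
        raise ValueError("need at least 4 transcripts to form quartiles")
    s = mean_expr.sort_index(kind="mergesort")
    order = np.argsort(s.to_numpy(), kind="stable")
    labels = np.empty(len(s), dtype=object)
    for qi, chunk in enumerate(np.array_split(order, 4)):
        labels[chunk] = QUARTILES[qi]
    return pd.Series(labels, index=s.index, name="quartile").reindex(mean_expr.index)


def average_cpg_methylation(
    coverage: dict, sample_ids, min_depth: int = 10
) -> pd.DataFrame:
    """Mean per-CpG methylation level across the given samples.

    A sample contributes at a CpG only when its coverage passes
    ``min_depth``.  Returns chrom/pos/level with CpGs covered in at
    least one sample.
    """
    frames = []
    for sid in sample_ids:
        df = coverage[sid]
        ok = df[df["total_reads"] >= min_depth]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": ok["chrom"],
                    "pos": ok["pos"],
                    "level": ok["meth_reads"] / ok["total_reads"],
                }
            )
        )
    allc = pd.concat(frames, ignore_index=True)
    out = allc.groupby(["chrom", "pos"], as_index=False)["level"].mean()
    return out


def _unit_intervals(gene, unit: str) -> list:
    """0-based half-open genomic intervals of one genic unit for a gene model."""
    exons = sorted(zip(gene.exonStarts, gene.exonEnds))
    if unit == "gene":
        return [(gene.txStart, gene.txEnd)]
    if unit == "exon":
        return exons
    if unit == "intron":
        return [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]) if e1 < s2]
    low, high = [], []  # genomically before/after the CDS
    for s, e in exons:
        if s < gene.cdsStart:
            low.append((s, min(e, gene.cdsStart)))
        if e > gene.cdsEnd:
            high.append((max(s, gene.cdsEnd), e))
    if unit == "utr5":
        return low if gene.strand == "+" else high
    if unit == "utr3":
        return high if gene.strand == "+" else low
    raise ValueError(f"unknown metagene unit {unit!r}")


def transcript_class_methylation(
    cpg_levels: pd.DataFrame, genes: pd.DataFrame, cls: str
) -> pd.Series:
    """Mean CpG methylation within one genic class, per transcript.

    ``cpg_levels`` is the chrom/pos/level table from
    :func:`average_cpg_methylation`; transcripts without a covered CpG
    in the class are absent from the result.
    """
    by_chrom = {c: sub.sort_values("pos") for c, sub in cpg_levels.groupby("chrom")}
    vals = {}
    for gene in genes.itertuples(index=False):
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        levels = sub["level"].to_numpy()
        acc = []
        for s, e in _unit_intervals(gene, cls):
            i, j = np.searchsorted(pos, [s, e])
            if j > i:
                acc.append(levels[i:j])
        if acc:
            vals[gene.transcript_id] = float(np.concatenate(acc).mean())
    return pd.Series(vals, name=f"meth_{cls}")


def region_class_correlation(meth: pd.Series, expr: pd.Series):
    """Pearson correlation of per-transcript methylation vs expression.

    Returns (r, p, n) over the transcripts present in both series;
    (NaN, NaN, n) when either side has zero variance.
    """
    joined = pd.concat([meth, expr], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 paired transcripts")
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _relative_positions(gene, unit: str, pos: np.ndarray, flank_bp: int):
    """Map genomic CpG positions onto the unit's metagene axis.

    Body positions land in [0, 1) (percentile-scaled over the unit's
    concatenated intervals); 5' flank positions in (-1, 0) and 3'
    flank positions in (1, 2], both scaled by ``flank_bp``.  On the
    minus strand the whole axis is reflected so 0 is always the
    transcriptional 5' end.  Positions outside unit+flanks map to NaN.
    """
    ivs = _unit_intervals(gene, unit)
    coords = np.full(pos.shape, np.nan)
    if not ivs:
        return coords
    lengths = np.array([e - s for s, e in ivs], dtype=float)
    total = lengths.sum()
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    lo, hi = ivs[0][0], ivs[-1][1]
    for k, (s, e) in enumerate(ivs):
        inside = (pos >= s) & (pos < e)
        coords[inside] = (cum[k] + (pos[inside] - s)) / total
    up = (pos >= lo - flank_bp) & (pos < lo)
    coords[up] = -(lo - pos[up]) / flank_bp  # in (-1, 0)
    down = (pos >= hi) & (pos < hi + flank_bp)
    coords[down] = 1.0 + (pos[down] - hi + 1) / flank_bp  # in (1, 2]
    if gene.strand == "-":
        valid = ~np.isnan(coords)
        coords[valid] = 1.0 - coords[valid]  # reflect; flanks land in (1,2]/(-1,0)
    return coords


def metagene_profile(
    genes: pd.DataFrame,
    cpg_levels: pd.DataFrame,
    quartiles: pd.Series,
    unit: str = "gene",
    n_bins: int = 40,
    flank_bins: int = 10,
    flank_bp: int = 2000,
    boundary_bp: int = 200,
    boundary_bin_bp: int = 10,
    span: float = 0.3,
) -> pd.DataFrame:
    """Quartile-stratified methylation profile over a genic unit.

    Scaled units ('gene', 'utr5', 'utr3', 'exon', 'intron') use
    percentile-scaled bodies (``n_bins`` bins) with fixed-bp flanks
    (``flank_bins`` bins each side); boundary units ('exon_boundary',
    'intron_boundary') use fixed +/-``boundary_bp`` windows around
    each unit start at ``boundary_bin_bp`` resolution.  Positions are
    strand-aware.  Per-bin means are LOESS-smoothed (tri-cube local
    linear regression at fraction ``span``).

    Returns a long DataFrame: quartile, bin, x, mean_meth, n, smooth.
    """
    by_chrom = {c: sub.sort_values("pos") for c, sub in cpg_levels.groupby("chrom")}
    if unit in BOUNDARY_UNITS:
        return _boundary_profile(
            genes, by_chrom, quartiles, unit, boundary_bp, boundary_bin_bp, span
        )
    if unit not in METAGENE_UNITS:
        raise ValueError(f"unknown metagene unit {unit!r}")

    edges = np.concatenate(
        [
            np.linspace(-1.0, 0.0, flank_bins + 1)[:-1],
            np.linspace(0.0, 1.0, n_bins + 1)[:-1],
            np.linspace(1.0, 2.0, flank_bins + 1),
        ]
    )
    centers = (edges[:-1] + edges[1:]) / 2
    rows = []
    for q in QUARTILES:
        tx = set(quartiles.index[quartiles == q])
        if not tx:
            continue
        sums = np.zeros(len(centers))
        counts = np.zeros(len(centers), dtype=int)
        for gene in genes.itertuples(index=False):
            if gene.transcript_id not in tx:
                continue
            sub = by_chrom.get(gene.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            lev = sub["level"].to_numpy()
            coords = _relative_positions(gene, unit, pos, flank_bp)
            ok = ~np.isnan(coords)
            if not ok.any():
                continue
            b = np.clip(np.searchsorted(edges, coords[ok], side="right") - 1,
                        0, len(centers) - 1)
            np.add.at(sums, b, lev[ok])
            np.add.at(counts, b, 1)
        if counts.sum() == 0:
            warnings.warn(f"quartile {q}: no covered CpGs for unit {unit!r}", stacklevel=2)
            continue
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {"quartile": q, "bin": np.arange(len(centers)), "x": centers,
                 "mean_meth": mean, "n": counts}
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["quartile", "bin", "x", "mean_meth", "n"]
    )
    return _smooth(out, span)


def _boundary_profile(genes, by_chrom, quartiles, unit, boundary_bp, bin_bp, span):
    half = boundary_bp // bin_bp
    centers = (np.arange(-half, half) + 0.5) * bin_bp
    edges = np.arange(-half, half + 1) * bin_bp
    rows = []
    inner = "exon" if unit == "exon_boundary" else "intron"
    for q in QUARTILES:
        tx = set(quartiles.index[quartiles == q])
        if not tx:
            continue
        sums = np.zeros(len(centers))
        counts = np.zeros(len(centers), dtype=int)
        for gene in genes.itertuples(index=False):
            if gene.transcript_id not in tx:
                continue
            sub = by_chrom.get(gene.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            lev = sub["level"].to_numpy()
            for s, e in _unit_intervals(gene, inner):
                # boundary at the unit's 5' end, strand-aware
                anchor, sign = (s, 1) if gene.strand == "+" else (e - 1, -1)
                rel = (pos - anchor) * sign
                ok = (rel >= -boundary_bp) & (rel < boundary_bp)
                if not ok.any():
                    continue
                b = np.clip(np.searchsorted(edges, rel[ok], side="right") - 1,
                            0, len(centers) - 1)
                np.add.at(sums, b, lev[ok])
                np.add.at(counts, b, 1)
        if counts.sum() == 0:
            warnings.warn(f"quartile {q}: no covered CpGs for unit {unit!r}", stacklevel=2)
            continue
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {"quartile": q, "bin": np.arange(len(centers)), "x": centers,
                 "mean_meth": mean, "n": counts}
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["quartile", "bin", "x", "mean_meth", "n"]
    )
    return _smooth(out, span)


def _smooth(profile: pd.DataFrame, span: float) -> pd.DataFrame:
    if profile.empty:
        profile["smooth"] = pd.Series(dtype=float)
        return profile
    parts = []
    for _, sub in profile.groupby("quartile", sort=False):
        sub = sub.copy()
        ok = sub["mean_meth"].notna()
        if ok.sum() >= 3:
            sm = lowess(
                sub.loc[ok, "mean_meth"].to_numpy(),
                sub.loc[ok, "x"].to_numpy(),
                frac=span, return_sorted=False,
            )
            sub.loc[ok, "smooth"] = sm
        else:
            sub["smooth"] = sub["mean_meth"]
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
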