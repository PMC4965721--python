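"""Tile aggregation and per-sample-pair DMR calling.

Per-CpG counts are pooled on fixed, genome-anchored 1000-bp tiles
(step 1000 bp).  A CpG contributes to a tile in a sample only if its
coverage is at least ``min_depth`` reads there, and a tile is retained
for a sample only if at least ``min_cpgs`` CpGs contribute.  Every case
sample is then compared against a single control with a two-sided
Fisher exact test on pooled methylated/unmethylated counts; q-values
are Benjamini-Hochberg within each (case, control) comparison batch,
and a tile is called hyper/hypo when q < q_thresh and the methylation
difference exceeds diff_thresh percentage points in that direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact import bh_fdr, fisher_exact_two_sided

__all__ = ["aggregate_tiles", "fisher_dmr", "compare_cohort", "CohortComparison", "calls_to_bed"]


def aggregate_tiles(
    coverage: dict,
    tile_size: int = 1000,
    min_cpgs: int = 3,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Pool per-CpG counts into per-sample tile statistics.

    Parameters
    ----------
    coverage
        Mapping sample_id -> coverage DataFrame (chrom, pos,
        meth_reads, total_reads), as returned by
        :func:`conmeth.io.read_coverage`.

    Returns
    -------
    Long DataFrame with columns chrom, start, end, sample_id,
    n_cpgs_pass, meth_reads, total_reads, level.  Tiles failing the
    min_cpgs filter for a sample are simply absent for that sample.
    """
    frames = []
    for sid, df in coverage.items():
        ok = df[df["total_reads"] >= min_depth]
        if ok.empty:
            continue
        start = (ok["pos"] // tile_size) * tile_size
        g = (
            ok.assign(start=start)
            .groupby(["chrom", "start"], sort=True)
            .agg(
                n_cpgs_pass=("pos", "size"),
                meth_reads=("meth_reads", "sum"),
                total_reads=("total_reads", "sum"),
            )
            .reset_index()
        )
        g = g[g["n_cpgs_pass"] >= min_cpgs]
        g["end"] = g["start"] + tile_size
        g["sample_id"] = sid
        frames.append(g)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "sample_id", "n_cpgs_pass",
                     "meth_reads", "total_reads", "level"]
        )
    tiles = pd.concat(frames, ignore_index=True)
    tiles["level"] = tiles["meth_reads"] / tiles["total_reads"]
    cols = ["chrom", "start", "end", "sample_id", "n_cpgs_pass",
            "meth_reads", "total_reads", "level"]
    return tiles[cols].sort_values(["chrom", "start", "sample_id"]).reset_index(drop=True)


def fisher_dmr(meth_case, total_case, meth_ctrl, total_ctrl):
    """Fisher p and signed methylation difference (percentage points).

    Vectorised; tables with a zero total in either sample are undefined
    and the caller is expected to exclude them.
    """
    meth_case = np.asarray(meth_case)
    total_case = np.asarray(total_case)
    meth_ctrl = np.asarray(meth_ctrl)
    total_ctrl = np.asarray(total_ctrl)
    if np.any(total_case == 0) or np.any(total_ctrl == 0):
        raise ValueError("zero read total: the tile must be excluded upstream")
    p = fisher_exact_two_sided(meth_case, total_case, meth_ctrl, total_ctrl)
    diff = 100.0 * (meth_case / total_case - meth_ctrl / total_ctrl)
    return p, diff


@dataclass
class CohortComparison:
    """All case-vs-one-control DMR calls plus the common-region set."""

    control_id: str
    case_ids: list
    calls: pd.DataFrame  # chrom start end case_id control_id diff p q call
    common_regions: pd.Index  # MultiIndex (chrom, start, end) valid in every pair

    def call_matrix(self, direction: str) -> pd.DataFrame:
        """Boolean common-regions x case-samples matrix of calls in a direction."""
        sub = self.calls.set_index(["chrom", "start", "end"]).loc[
            list(self.common_regions)
        ]
        mat = (
            sub.reset_index()
            .pivot_table(
                index=["chrom", "start", "end"],
                columns="case_id",
                values="call",
                aggfunc="first",
            )
            .reindex(self.common_regions)
        )
        return (mat == direction).reindex(columns=self.case_ids, fill_value=False)


def compare_cohort(
    tiles: pd.DataFrame,
    case_ids,
    control_id: str,
    q_thresh: float = 0.01,
    diff_thresh: float = 25.0,
) -> CohortComparison:
    """Call DMRs for every case against one control sample.

    The common-region set contains the tiles retained (post coverage
    filters) in the control and in *every* case sample, so downstream
    consistency statistics compare like with like.
    """
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("need at least one case sample")
    by_sample = {
        sid: df.set_index(["chrom", "start", "end"])
        for sid, df in tiles.groupby("sample_id")
    }
    if control_id not in by_sample or by_sample[control_id].empty:
        raise ValueError(f"control sample {control_id!r} has no retained tiles")
    ctrl = by_sample[control_id]

    frames = []
    common: pd.Index | None = None
    for cid in case_ids:
        if cid not in by_sample:
            raise ValueError(f"case sample {cid!r} has no retained tiles")
        case = by_sample[cid]
        shared = case.index.intersection(ctrl.index)
        common = shared if common is None else common.intersection(shared)
        mc = case.loc[shared, "meth_reads"].to_numpy()
        tc = case.loc[shared, "total_reads"].to_numpy()
        mk = ctrl.loc[shared, "meth_reads"].to_numpy()
        tk = ctrl.loc[shared, "total_reads"].to_numpy()
        p, diff = fisher_dmr(mc, tc, mk, tk)
        q = bh_fdr(p)
        call = np.where(
            (q < q_thresh) & (diff >= diff_thresh),
            "hyper",
            np.where((q < q_thresh) & (diff <= -diff_thresh), "hypo", "ns"),
        )
        out = pd.DataFrame(
            {
                "chrom": shared.get_level_values(0),
                "start": shared.get_level_values(1),
                "end": shared.get_level_values(2),
                "case_id": cid,
                "control_id": control_id,
                "diff": diff,
                "p": p,
                "q": q,
                "call": call,
            }
        )
        frames.append(out)
    calls = pd.concat(frames, ignore_index=True)
    common = common.sortlevel()[0] if common is not None else pd.Index([])
    return CohortComparison(
        control_id=control_id, case_ids=case_ids, calls=calls, common_regions=common
    )


def calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """BED6 export of non-ns calls; score = -10*log10(q), name = call."""
    sig = calls[calls["call"] != "ns"].copy()
    with np.errstate(divide="ignore"):
        score = -10.0 * np.log10(np.maximum(sig["q"].to_numpy(), 1e-300))
    return pd.DataFrame(
        {
            "chrom": sig["chrom"],
            "start": sig["start"],
            "end": sig["end"],
            "name": sig["call"],
            "score": np.round(score, 2),
            "strand": ".",
        }
    )
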