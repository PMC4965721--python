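"""Per-region Shannon methylation entropy across case samples.

For region r with non-negative methylation vector m_r over N case
samples, the cross-sample entropy is

    H = -sum_s p_s log2(p_s),   p_s = m_{r,s} / sum_s m_{r,s}

so H ranges from 0 (all methylation in one sample) to log2(N) (spread
evenly).  The vector can be the raw per-sample methylation levels
(default, the literal definition) or the absolute case-vs-control
differences (``input_kind='diff'``); regions whose vector sums to zero
have undefined entropy and are skipped downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["region_entropy", "entropy_table", "entropy_change_correlation"]


def region_entropy(m, negative: str = "abs") -> float:
    """Shannon entropy (bits) of a region's cross-sample methylation vector.

    Zero entries contribute nothing; a vector summing to zero yields
    NaN (entropy undefined).  Negative entries are taken as absolute
    values (``negative='abs'``) or rejected (``negative='error'``).
    """
    m = np.asarray(m, dtype=np.float64)
    if np.any(m < 0):
        if negative == "error":
            raise ValueError("methylation vector has negative entries")
        m = np.abs(m)
    s = m.sum()
    if s == 0:
        return float("nan")
    p = m / s
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def entropy_table(
    tiles: pd.DataFrame,
    case_ids,
    control_id: str,
    regions: pd.Index,
    input_kind: str = "level",
) -> pd.DataFrame:
    """Per-region entropy and mean methylation change for one control batch.

    Parameters
    ----------
    tiles
        Long tile table from :func:`conmeth.dmr.aggregate_tiles`.
    regions
        The batch's common-region set (every case and the control
        retained the tile there).
    input_kind
        'level' uses the case samples' methylation levels as the
        entropy vector; 'diff' uses |case - control| differences.

    Returns
    -------
    DataFrame indexed by region with columns H (bits), mean_change
    (signed, percentage points), mean_abs_change, n_samples.
    """
    if input_kind not in ("level", "diff"):
        raise ValueError("input_kind must be 'level' or 'diff'")
    case_ids = list(case_ids)
    lv = tiles.pivot_table(
        index=["chrom", "start", "end"], columns="sample_id", values="level"
    )
    lv = lv.reindex(regions)
    case = lv[case_ids].to_numpy()
    ctrl = lv[control_id].to_numpy()[:, None]
    diffs = case - ctrl
    vec = case if input_kind == "level" else np.abs(diffs)
    H = np.apply_along_axis(region_entropy, 1, vec)
    return pd.DataFrame(
        {
            "H": H,
            "mean_change": 100.0 * diffs.mean(axis=1),
            "mean_abs_change": 100.0 * np.abs(diffs).mean(axis=1),
            "n_samples": len(case_ids),
        },
        index=lv.index,
    )


def entropy_change_correlation(table: pd.DataFrame):
    """Pearson correlation between entropy and mean |methylation change|.

    Regions with undefined entropy are dropped.  Returns (r, p); both
    NaN when either vector is constant (correlation undefined).
    """
    sub = table.dropna(subset=["H"])
    if len(sub) < 3:
        raise ValueError("need at least 3 regions with defined entropy")
    x = sub["H"].to_numpy()
    y = sub["mean_abs_change"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
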