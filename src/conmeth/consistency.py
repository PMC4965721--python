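"""Consistent-DMR (C-DMR) identification and validation.

A region is consistently differentially methylated when it is called in
the same direction in at least ``k_min`` of the N case samples and that
count is significant under a one-sided binomial test against the
genome-wide per-sample call rate (BH q < 0.01), in *every* control
batch.  Two permutation tests validate the set: one reassigns
case/control labels among all samples, the other shuffles per-region
calls across regions independently within each case sample.  Both use
the add-one empirical p-value (1 + #{T_perm >= T_obs}) / (1 + n_perm)
on the statistic T = min over control batches of the per-region
consistent-sample count, with BH across candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr import CohortComparison, compare_cohort
from .exact import bh_fdr, binom_tail_upper, fisher_exact_two_sided

__all__ = [
    "estimate_null_rate",
    "binomial_consistency",
    "intersect_control_batches",
    "call_cdmrs",
    "CDMRResult",
]

DIRECTIONS = ("hyper", "hypo")


def estimate_null_rate(call_matrix: pd.DataFrame) -> float:
    """Empirical per-sample, per-region call rate in one direction.

    The binomial null probability p0 = (#significant calls) /
    (#regions x #samples), clipped to [1e-6, 1 - 1e-6] so degenerate
    all-or-nothing call sets stay testable.
    """
    if call_matrix.size == 0:
        raise ValueError("cannot estimate a null call rate without any calls")
    rate = float(np.asarray(call_matrix, dtype=bool).mean())
    return float(np.clip(rate, 1e-6, 1.0 - 1e-6))


def binomial_consistency(
    call_matrix: pd.DataFrame,
    k_min: int = 25,
    p0: float | None = None,
    q_thresh: float = 0.01,
) -> pd.DataFrame:
    """Test cross-sample consistency of calls in one direction.

    Parameters
    ----------
    call_matrix
        Boolean regions x case-samples matrix of directional calls,
        restricted to the common-region set of one control batch.
    p0
        Binomial null probability; defaults to the empirical call rate
        (:func:`estimate_null_rate`).

    Returns
    -------
    DataFrame indexed like ``call_matrix`` with columns n_consistent,
    n_total, binom_p, binom_q, significant.  Regions with fewer than
    ``k_min`` consistent samples are not tested (p and q are NaN).
    """
    mat = np.asarray(call_matrix, dtype=bool)
    n_total = mat.shape[1]
    n_consistent = mat.sum(axis=1)
    if p0 is None:
        p0 = estimate_null_rate(call_matrix)
    tested = n_consistent >= k_min
    p = np.full(mat.shape[0], np.nan)
    q = np.full(mat.shape[0], np.nan)
    if tested.any():
        p[tested] = binom_tail_upper(n_consistent[tested], n_total, p0)
        q[tested] = bh_fdr(p[tested])
    else:
        binom_tail_upper(k_min, n_total, p0)  # still validate p0
    return pd.DataFrame(
        {
            "n_consistent": n_consistent,
            "n_total": n_total,
            "binom_p": p,
            "binom_q": q,
            "p0": p0,
            "significant": tested & (q < q_thresh),
        },
        index=call_matrix.index,
    )


def intersect_control_batches(
    results_per_control: dict, q_thresh: float = 0.01
) -> pd.DataFrame:
    """Intersect per-batch consistency results into the candidate set.

    A region is a candidate C-DMR (in one direction) iff its binomial
    test is significant (q < q_thresh, same direction) in *every*
    control batch.  The result carries per-batch statistics on the
    shared region universe.
    """
    controls = list(results_per_control)
    if not controls:
        raise ValueError("no control batches given")
    if len(controls) == 1:
        warnings.warn(
            "single control batch: the intersection degenerates to that batch's list",
            stacklevel=2,
        )
    universe = None
    for tbl in results_per_control.values():
        universe = tbl.index if universe is None else universe.intersection(tbl.index)
    if len(universe) == 0:
        warnings.warn(
            "control batches have disjoint region universes; intersection is empty",
            stacklevel=2,
        )
    out = pd.DataFrame(index=universe.sortlevel()[0] if len(universe) else universe)
    sig_all = np.ones(len(out), dtype=bool)
    n_min = None
    for ctrl in controls:
        tbl = results_per_control[ctrl].reindex(out.index)
        out[f"n_consistent_{ctrl}"] = tbl["n_consistent"]
        out[f"binom_p_{ctrl}"] = tbl["binom_p"]
        out[f"binom_q_{ctrl}"] = tbl["binom_q"]
        sig_all &= tbl["significant"].fillna(False).to_numpy(dtype=bool)
        n = tbl["n_consistent"].to_numpy()
        n_min = n if n_min is None else np.minimum(n_min, n)
    out["n_min"] = n_min
    out["candidate"] = sig_all
    return out


@dataclass
class CDMRResult:
    """Full consistency-analysis output.

    ``table`` is long over (region, direction) with per-batch counts
    and binomial q-values, permutation p/q and the final ``is_cdmr``
    flag.  ``batches`` holds the per-control DMR comparisons.
    """

    table: pd.DataFrame
    batches: dict
    universe: pd.Index
    params: dict = field(default_factory=dict)

    def cdmrs(self, direction: str) -> pd.Index:
        sub = self.table[(self.table["direction"] == direction) & self.table["is_cdmr"]]
        return pd.MultiIndex.from_frame(sub[["chrom", "start", "end"]])


def _tile_matrices(tiles: pd.DataFrame, samples: list):
    """Pivot tile stats to regions x samples count matrices."""
    sub = tiles[tiles["sample_id"].isin(samples)]
    meth = sub.pivot_table(
        index=["chrom", "start", "end"], columns="sample_id", values="meth_reads"
    ).reindex(columns=samples)
    total = sub.pivot_table(
        index=["chrom", "start", "end"], columns="sample_id", values="total_reads"
    ).reindex(columns=samples)
    valid = total.notna().to_numpy() & (total.fillna(0).to_numpy() > 0)
    return meth, total, valid


def _pairwise_call_arrays(meth, total, valid, q_thresh, diff_thresh):
    """Directional DMR calls for every ordered sample pair.

    Returns (hyper, hypo): boolean arrays [n_samples, n_samples,
    n_regions] where entry [a, b, r] is the call for sample a treated
    as case against sample b as control.  q-values are BH within each
    unordered pair's shared-region batch (p is symmetric under role
    swap, the difference antisymmetric).
    """
    m = meth.fillna(0).to_numpy(dtype=np.int64)
    t = total.fillna(0).to_numpy(dtype=np.int64)
    R, S = m.shape
    hyper = np.zeros((S, S, R), dtype=bool)
    hypo = np.zeros((S, S, R), dtype=bool)
    for a in range(S):
        for b in range(a + 1, S):
            rows = np.nonzero(valid[:, a] & valid[:, b])[0]
            if rows.size == 0:
                continue
            p = fisher_exact_two_sided(m[rows, a], t[rows, a], m[rows, b], t[rows, b])
            q = bh_fdr(p)
            diff = 100.0 * (m[rows, a] / t[rows, a] - m[rows, b] / t[rows, b])
            sig = q < q_thresh
            up = sig & (diff >= diff_thresh)
            down = sig & (diff <= -diff_thresh)
            hyper[a, b, rows] = up
            hypo[a, b, rows] = down
            hyper[b, a, rows] = down
            hypo[b, a, rows] = up
    return hyper, hypo


def _min_counts(arr, case_idx, ctrl_idx, region_rows):
    """T = min over controls of the per-region consistent-case count."""
    counts = np.stack(
        [arr[np.ix_(case_idx, [c], region_rows)][:, 0, :].sum(axis=0) for c in ctrl_idx]
    )
    return counts.min(axis=0)


def _empirical_p(exceed: np.ndarray, n_perm: int) -> np.ndarray:
    return (1.0 + exceed) / (1.0 + n_perm)


def call_cdmrs(
    tiles: pd.DataFrame,
    case_ids,
    control_ids,
    *,
    q_dmr: float = 0.01,
    diff_thresh: float = 25.0,
    k_min: int = 25,
    q_cdmr: float = 0.01,
    p0: float | None = None,
    n_perm: int = 100,
    perm_q_thresh: float = 0.05,
    seed: int = 0,
    permutation: bool = True,
) -> CDMRResult:
    """Run the full consistency pipeline on aggregated tiles.

    Stages: per-control cohort DMR calling -> per-batch binomial
    consistency (null rate estimated per batch and direction unless
    ``p0`` is given) -> intersection across control batches -> the two
    permutation tests (skipped when ``permutation`` is False, in which
    case ``is_cdmr`` reflects the binomial criterion alone).
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if permutation and n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve p < 0.05")

    batches: dict[str, CohortComparison] = {}
    per_dir_results: dict[str, dict] = {d: {} for d in DIRECTIONS}
    for ctrl in control_ids:
        cmp = compare_cohort(tiles, case_ids, ctrl, q_thresh=q_dmr, diff_thresh=diff_thresh)
        batches[ctrl] = cmp
        for direction in DIRECTIONS:
            mat = cmp.call_matrix(direction)
            per_dir_results[direction][ctrl] = binomial_consistency(
                mat, k_min=k_min, p0=p0, q_thresh=q_cdmr
            )

    parts = []
    for direction in DIRECTIONS:
        inter = intersect_control_batches(per_dir_results[direction], q_thresh=q_cdmr)
        inter = inter.reset_index()
        inter["direction"] = direction
        parts.append(inter)
    universe = pd.MultiIndex.from_frame(
        parts[0][["chrom", "start", "end"]]
    )
    table = pd.concat(parts, ignore_index=True)
    table["n_total"] = len(case_ids)

    if permutation and len(universe):
        samples = case_ids + control_ids
        meth, total, valid = _tile_matrices(tiles, samples)
        region_rows = meth.index.get_indexer(universe)
        hyper, hypo = _pairwise_call_arrays(meth, total, valid, q_dmr, diff_thresh)
        arrs = {"hyper": hyper, "hypo": hypo}
        case_idx = np.arange(len(case_ids))
        ctrl_idx = np.arange(len(case_ids), len(samples))
        t_obs = {
            d: _min_counts(arrs[d], case_idx, ctrl_idx, region_rows) for d in DIRECTIONS
        }

        rng_s = np.random.default_rng([int(seed), 11])
        exceed_s = {d: np.zeros(len(universe)) for d in DIRECTIONS}
        S = len(samples)
        for _ in range(n_perm):
            order = rng_s.permutation(S)
            pc, pk = order[len(control_ids):], order[: len(control_ids)]
            for d in DIRECTIONS:
                t_perm = _min_counts(arrs[d], pc, pk, region_rows)
                exceed_s[d] += t_perm >= t_obs[d]

        # region permutation acts on the observed per-batch call matrices
        rng_r = np.random.default_rng([int(seed), 12])
        mats = {
            d: [
                batches[ctrl].call_matrix(d).reindex(universe).to_numpy(dtype=bool)
                for ctrl in control_ids
            ]
            for d in DIRECTIONS
        }
        t_obs_r = {
            d: np.stack([m.sum(axis=1) for m in mats[d]]).min(axis=0) for d in DIRECTIONS
        }
        exceed_r = {d: np.zeros(len(universe)) for d in DIRECTIONS}
        Rn = len(universe)
        for _ in range(n_perm):
            perms = [
                np.stack([rng_r.permutation(Rn) for _ in case_ids], axis=1)
                for _ in control_ids
            ]
            for d in DIRECTIONS:
                counts = np.stack(
                    [
                        np.take_along_axis(mats[d][bi], perms[bi], axis=0).sum(axis=1)
                        for bi in range(len(control_ids))
                    ]
                )
                exceed_r[d] += counts.min(axis=0) >= t_obs_r[d]

        for d in DIRECTIONS:
            sel = table["direction"] == d
            table.loc[sel, "perm_sample_p"] = _empirical_p(exceed_s[d], n_perm)
            table.loc[sel, "perm_region_p"] = _empirical_p(exceed_r[d], n_perm)
        for col in ("perm_sample", "perm_region"):
            table[f"{col}_q"] = np.nan
            for d in DIRECTIONS:
                cand = (table["direction"] == d) & table["candidate"]
                if cand.any():
                    table.loc[cand, f"{col}_q"] = bh_fdr(table.loc[cand, f"{col}_p"])
        table["is_cdmr"] = (
            table["candidate"]
            & (table["perm_sample_q"] < perm_q_thresh)
            & (table["perm_region_q"] < perm_q_thresh)
        )
    else:
        for col in ("perm_sample_p", "perm_sample_q", "perm_region_p", "perm_region_q"):
            table[col] = np.nan
        table["is_cdmr"] = table["candidate"]

    params = dict(
        q_dmr=q_dmr, diff_thresh=diff_thresh, k_min=k_min, q_cdmr=q_cdmr,
        p0=p0, n_perm=n_perm if permutation else 0,
        perm_q_thresh=perm_q_thresh, seed=seed,
    )
    return CDMRResult(table=table, batches=batches, universe=universe, params=params)
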