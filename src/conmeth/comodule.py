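"""Correlation-network modules and their cross-omics comparison.

Differential expression and differential 3'UTR-methylation matrices
(transcripts x case samples, each case compared against one common
control) are clustered into modules via an unsigned weighted
correlation network: adjacency a_ij = |cor(x_i, x_j)|^beta,
dissimilarity 1 - a_ij, average-linkage hierarchical clustering with a
static cut.  Module detection here is a deliberately simple variant of
the weighted-network framework (no topological-overlap transform, no
dynamic tree cut); the comparison machinery is the point:

* cross-tabulation overlap with hypergeometric (Fisher upper-tail)
  p-values, BH across module pairs;
* module eigengenes (first principal component of the standardized
  member matrix) and their all-pairs Pearson correlation;
* permutation preservation statistics: density and connectivity of a
  reference module re-measured in a test matrix against random
  same-size variable sets, summarised as Z_summary (mean of the two
  Z-scores; > 10 strong, 2-10 weak-to-moderate, < 2 no evidence) and a
  permutation-free medianRank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exact import bh_fdr

__all__ = [
    "build_differential_matrices",
    "detect_modules",
    "module_eigengene",
    "ModuleSet",
    "crosstab_overlap",
    "preservation_z",
    "eigengene_correlation",
]

# conventional module colour aliases, size-ranked; label 0 is the grey pool
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]


def build_differential_matrices(
    expression: pd.DataFrame,
    tiles_or_cpg_levels,
    genes: pd.DataFrame,
    case_ids,
    control_id: str,
    coverage: dict | None = None,
    min_depth: int = 10,
):
    """Per-case differential expression and 3'UTR-methylation matrices.

    Expression differential is log2((FPKM_case + 1) / (FPKM_control + 1));
    methylation differential is the percentage-point difference of the
    mean 3'UTR CpG methylation level between each case and the common
    control.  Transcripts are restricted to those with both expression
    and 3'UTR CpG coverage in every sample.

    Parameters
    ----------
    tiles_or_cpg_levels
        Either a coverage mapping (sample_id -> coverage DataFrame)
        passed as ``coverage`` is None, or ignored if ``coverage`` is
        given explicitly.

    Returns
    -------
    (expr_diff, meth_diff): DataFrames, transcripts x case samples.
    """
    from .expr_meth import _unit_intervals  # interval logic shared with profiles

    case_ids = list(case_ids)
    cov = coverage if coverage is not None else tiles_or_cpg_levels
    if control_id not in cov or control_id not in expression.columns:
        raise ValueError(f"no common control sample {control_id!r} in both data sets")

    # per-sample mean 3'UTR methylation per transcript
    def utr3_means(sample_df):
        ok = sample_df[sample_df["total_reads"] >= min_depth]
        by_chrom = {c: s.sort_values("pos") for c, s in ok.groupby("chrom")}
        vals = {}
        for gene in genes.itertuples(index=False):
            sub = by_chrom.get(gene.chrom)
            if sub is None:
                continue
            pos = sub["pos"].to_numpy()
            meth = sub["meth_reads"].to_numpy()
            tot = sub["total_reads"].to_numpy()
            num = den = 0.0
            nc = 0
            for s, e in _unit_intervals(gene, "utr3"):
                i, j = np.searchsorted(pos, [s, e])
                if j > i:
                    lv = meth[i:j] / tot[i:j]
                    num += lv.sum()
                    nc += j - i
            if nc:
                vals[gene.transcript_id] = num / nc
        return pd.Series(vals)

    meth_by_sample = {sid: utr3_means(cov[sid]) for sid in case_ids + [control_id]}
    meth_wide = pd.DataFrame(meth_by_sample).dropna()

    common = meth_wide.index.intersection(expression.index)
    if len(common) == 0:
        raise ValueError("no transcripts with both 3'UTR CpG coverage and expression")
    meth_wide = meth_wide.loc[common]
    expr = expression.loc[common]

    meth_diff = 100.0 * meth_wide[case_ids].sub(meth_wide[control_id], axis=0)
    expr_diff = np.log2(expr[case_ids] + 1.0).sub(
        np.log2(expr[control_id] + 1.0), axis=0
    )
    return expr_diff, meth_diff


def _adjacency(matrix: np.ndarray, beta: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix)
    np.fill_diagonal(corr, 1.0)
    return np.abs(np.clip(corr, -1.0, 1.0)) ** beta


@dataclass
class ModuleSet:
    """Labelled variable clusters with eigengenes.

    ``labels`` maps variable -> integer label (0 = grey pool of
    unassigned variables); ``colors`` aliases labels to the
    conventional colour names; ``eigengenes`` is samples x modules
    (unit-norm, sign-anchored to correlate positively with members on
    average).
    """

    labels: pd.Series
    matrix: pd.DataFrame
    colors: dict = field(default_factory=dict)
    eigengenes: pd.DataFrame = None

    def __post_init__(self):
        mods = self.module_labels()
        if not self.colors:
            self.colors = {0: "grey"}
            for lab in mods:
                self.colors[lab] = (
                    MODULE_COLORS[lab - 1]
                    if lab - 1 < len(MODULE_COLORS)
                    else f"module{lab}"
                )
        if self.eigengenes is None:
            eg = {
                lab: module_eigengene(self.members(lab), self.matrix) for lab in mods
            }
            self.eigengenes = pd.DataFrame(eg, index=self.matrix.columns)

    def module_labels(self) -> list:
        return sorted(set(self.labels) - {0})

    def members(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()


def detect_modules(
    matrix: pd.DataFrame,
    beta: float = 6.0,
    cut_height: float = 0.75,
    min_size: int = 30,
) -> ModuleSet:
    """Detect correlation modules by static-cut hierarchical clustering.

    Variables with zero variance are dropped with a warning before the
    correlation step.  Clusters below ``min_size`` are pooled into the
    grey (label 0) set; surviving modules are labelled 1, 2, ... by
    decreasing size.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate variables")
    sd = matrix.std(axis=1, ddof=0)
    keep = matrix[sd > 0]
    if len(keep) < len(matrix):
        warnings.warn(
            f"dropped {len(matrix) - len(keep)} constant variable rows before "
            "correlation", stacklevel=2,
        )
    if len(keep) < min_size:
        raise ValueError("fewer variables than min_size after filtering")
    adj = _adjacency(keep.to_numpy(dtype=float), beta)
    diss = 1.0 - adj
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size].index
    order = sorted(big, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [remap.get(c, 0) for c in raw], index=keep.index, name="module"
    )
    dropped = matrix.index.difference(keep.index)
    if len(dropped):
        labels = pd.concat([labels, pd.Series(0, index=dropped, name="module")])
        labels = labels.reindex(matrix.index)
    return ModuleSet(labels=labels, matrix=keep)


def module_eigengene(members, matrix: pd.DataFrame) -> np.ndarray:
    """First principal component of the standardized member matrix.

    Unit-norm vector over samples, sign chosen so the mean correlation
    with member profiles is non-negative.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("module must have at least 2 members")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for an eigengene")
    X = matrix.loc[members].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    # sign anchor: positive mean correlation with members
    cors = Z @ eig
    if cors.mean() < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


def crosstab_overlap(
    modules_a: ModuleSet, modules_b: ModuleSet, universe=None
) -> pd.DataFrame:
    """Member-overlap significance for every module pair.

    Hypergeometric upper-tail p for the observed overlap out of the
    shared variable universe, BH across all pairs.  Raises when the two
    module sets do not share a universe.
    """
    ua = set(modules_a.labels.index)
    ub = set(modules_b.labels.index)
    if universe is None:
        if ua != ub:
            raise ValueError(
                f"module sets have different universes "
                f"(symmetric difference {len(ua ^ ub)} variables)"
            )
        universe = ua
    n_u = len(universe)
    rows = []
    for la in modules_a.module_labels():
        ma = set(modules_a.members(la)) & universe
        for lb in modules_b.module_labels():
            mb = set(modules_b.members(lb)) & universe
            k = len(ma & mb)
            p = stats.hypergeom.sf(k - 1, n_u, len(ma), len(mb))
            rows.append(
                dict(module_a=la, module_b=lb, size_a=len(ma), size_b=len(mb),
                     overlap_count=k, fisher_p=float(p))
            )
    out = pd.DataFrame(rows)
    out["fisher_q"] = bh_fdr(out["fisher_p"].to_numpy())
    return out


def _density(adj: np.ndarray, idx: np.ndarray) -> float:
    sub = adj[np.ix_(idx, idx)]
    n = len(idx)
    if n < 2:
        return float("nan")
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def _connectivity(adj: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = adj[np.ix_(idx, idx)]
    return sub.sum(axis=1) - np.diag(sub)


def preservation_z(
    reference: ModuleSet,
    test_matrix: pd.DataFrame,
    beta: float = 6.0,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Density/connectivity module preservation in a test data set.

    For each reference module: density = mean off-diagonal adjacency
    among members in the test matrix; connectivity = Pearson
    correlation of members' intramodular connectivity between reference
    and test.  The permutation null redraws module-sized random
    variable sets from the shared universe; Z = (obs - mean) / sd per
    statistic, Z_summary their mean.  medianRank ranks modules by the
    observed statistics alone (rank 1 = strongest preservation).
    """
    shared = reference.matrix.index.intersection(test_matrix.index)
    if len(shared) != len(reference.matrix.index) or len(shared) != len(test_matrix.index):
        raise ValueError("reference and test matrices must share the variable universe")
    ref = reference.matrix.loc[shared]
    tst = test_matrix.loc[shared]
    adj_ref = _adjacency(ref.to_numpy(dtype=float), beta)
    adj_tst = _adjacency(tst.to_numpy(dtype=float), beta)
    pos = pd.Series(np.arange(len(shared)), index=shared)

    rng = np.random.default_rng([int(seed), 21])
    rows = []
    for lab in reference.module_labels():
        idx = pos[reference.members(lab)].to_numpy()
        n = len(idx)
        obs_density = _density(adj_tst, idx)
        k_ref = _connectivity(adj_ref, idx)
        k_tst = _connectivity(adj_tst, idx)
        obs_conn = (
            float(stats.pearsonr(k_ref, k_tst)[0])
            if np.ptp(k_ref) > 0 and np.ptp(k_tst) > 0
            else float("nan")
        )
        perm_d = np.empty(n_perm)
        perm_c = np.empty(n_perm)
        for i in range(n_perm):
            ridx = rng.choice(len(shared), size=n, replace=False)
            perm_d[i] = _density(adj_tst, ridx)
            kr = _connectivity(adj_ref, ridx)
            kt = _connectivity(adj_tst, ridx)
            perm_c[i] = (
                stats.pearsonr(kr, kt)[0]
                if np.ptp(kr) > 0 and np.ptp(kt) > 0
                else np.nan
            )
        z_d = _zscore(obs_density, perm_d, f"module {lab} density")
        z_c = _zscore(obs_conn, perm_c, f"module {lab} connectivity")
        rows.append(
            dict(module=lab, size=n, density=obs_density, connectivity=obs_conn,
                 Z_density=z_d, Z_connectivity=z_c,
                 Z_summary=np.nanmean([z_d, z_c]))
        )
    out = pd.DataFrame(rows).set_index("module")
    # medianRank: rank observed statistics across modules, 1 = strongest
    rank_d = out["density"].rank(ascending=False)
    rank_c = out["connectivity"].rank(ascending=False)
    out["medianRank"] = pd.concat([rank_d, rank_c], axis=1).median(axis=1)
    return out


def _zscore(obs: float, perm: np.ndarray, what: str) -> float:
    perm = perm[~np.isnan(perm)]
    if len(perm) < 2:
        warnings.warn(f"{what}: no usable permutations; Z missing", stacklevel=3)
        return float("nan")
    sd = perm.std(ddof=1)
    if sd == 0:
        warnings.warn(f"{what}: zero permutation spread; Z missing", stacklevel=3)
        return float("nan")
    return float((obs - perm.mean()) / sd)


def eigengene_correlation(modules_a: ModuleSet, modules_b: ModuleSet) -> pd.DataFrame:
    """All-pairs Pearson correlation between two sets of eigengenes.

    Requires identical sample order in both matrices; returns r, p and
    BH q per (module_a, module_b) pair.
    """
    if list(modules_a.matrix.columns) != list(modules_b.matrix.columns):
        raise ValueError("sample order differs between the two module sets")
    rows = []
    for la in modules_a.module_labels():
        ea = modules_a.eigengenes[la].to_numpy()
        for lb in modules_b.module_labels():
            eb = modules_b.eigengenes[lb].to_numpy()
            r, p = stats.pearsonr(ea, eb)
            rows.append(dict(module_a=la, module_b=lb, r=float(r), p=float(p)))
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
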