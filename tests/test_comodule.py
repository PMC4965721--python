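"""Correlation-module detection, overlap, eigengenes, preservation."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from conmeth.comodule import (
    ModuleSet,
    build_differential_matrices,
    crosstab_overlap,
    detect_modules,
    eigengene_correlation,
    module_eigengene,
    preservation_z,
)
from conmeth.sim import simulate_comodule_matrices


def hypergeom_oracle(k, n_u, n_a, n_b):
    """Upper-tail overlap probability by exact enumeration."""
    return float(
        sum(
            Fraction(comb(n_a, i) * comb(n_u - n_a, n_b - i), comb(n_u, n_b))
            for i in range(k, min(n_a, n_b) + 1)
        )
    )


def modules_from_labels(labels: dict, matrix: pd.DataFrame) -> ModuleSet:
    return ModuleSet(labels=pd.Series(labels).reindex(matrix.index).fillna(0).astype(int),
                     matrix=matrix)


@pytest.fixture()
def tiny_matrices():
    rng = np.random.default_rng(0)
    idx = [f"v{i}" for i in range(10)]
    cols = [f"s{i}" for i in range(6)]
    a = pd.DataFrame(rng.normal(size=(10, 6)), index=idx, columns=cols)
    b = pd.DataFrame(rng.normal(size=(10, 6)), index=idx, columns=cols)
    return a, b


def test_crosstab_matches_enumeration(tiny_matrices):
    a, b = tiny_matrices
    ma = modules_from_labels({f"v{i}": 1 for i in range(5)}, a)
    mb = modules_from_labels({f"v{i}": 1 for i in range(5)}, b)
    out = crosstab_overlap(ma, mb)
    assert out.loc[0, "overlap_count"] == 5
    assert out.loc[0, "fisher_p"] == pytest.approx(1 / 252, rel=1e-10)
    assert out.loc[0, "fisher_p"] == pytest.approx(hypergeom_oracle(5, 10, 5, 5), rel=1e-10)


def test_crosstab_enumeration_on_random_small_universes(tiny_matrices):
    a, b = tiny_matrices
    rng = np.random.default_rng(2)
    for _ in range(30):
        na, nb = rng.integers(2, 8, size=2)
        sa = rng.choice(10, size=na, replace=False)
        sb = rng.choice(10, size=nb, replace=False)
        ma = modules_from_labels({f"v{i}": 1 for i in sa}, a)
        mb = modules_from_labels({f"v{i}": 1 for i in sb}, b)
        out = crosstab_overlap(ma, mb)
        k = len(set(sa) & set(sb))
        assert out.loc[0, "overlap_count"] == k
        assert out.loc[0, "fisher_p"] == pytest.approx(
            hypergeom_oracle(k, 10, na, nb), rel=1e-9
        )


def test_crosstab_identity_and_disjoint(tiny_matrices):
    a, _ = tiny_matrices
    ma = modules_from_labels({**{f"v{i}": 1 for i in range(5)},
                              **{f"v{i}": 2 for i in range(5, 9)}}, a)
    out = crosstab_overlap(ma, ma)
    diag = out[out["module_a"] == out["module_b"]]
    off = out[out["module_a"] != out["module_b"]]
    assert (diag["overlap_count"] == diag["size_a"]).all()
    assert (off["overlap_count"] == 0).all()
    assert (off["fisher_p"] >= 0.9).all()


def test_crosstab_universe_mismatch_raises(tiny_matrices):
    a, b = tiny_matrices
    ma = modules_from_labels({"v0": 1, "v1": 1}, a)
    mb = modules_from_labels({"v0": 1, "v1": 1}, b.iloc[:8])
    with pytest.raises(ValueError, match="universe"):
        crosstab_overlap(ma, mb)


def test_detect_modules_recovers_planted_blocks():
    rng = np.random.default_rng(3)
    n_s = 20
    f1, f2 = rng.normal(size=(2, n_s))
    rows = []
    for i in range(50):
        rows.append(0.95 * f1 + 0.3 * rng.normal(size=n_s))
    for i in range(50):
        rows.append(0.95 * f2 + 0.3 * rng.normal(size=n_s))
    mat = pd.DataFrame(rows, index=[f"v{i:03d}" for i in range(100)])
    mods = detect_modules(mat, min_size=30)
    assert len(mods.module_labels()) == 2
    truth = np.array([0] * 50 + [1] * 50)
    got = mods.labels.to_numpy()
    # Rand index vs truth
    same_t = truth[:, None] == truth[None, :]
    same_g = got[:, None] == got[None, :]
    iu = np.triu_indices(100, 1)
    rand = (same_t[iu] == same_g[iu]).mean()
    assert rand >= 0.95


def test_iid_noise_yields_no_modules():
    rng = np.random.default_rng(4)
    mat = pd.DataFrame(rng.normal(size=(100, 20)),
                       index=[f"v{i:03d}" for i in range(100)])
    mods = detect_modules(mat, min_size=30)
    assert mods.module_labels() == []
    assert (mods.labels == 0).all()


def test_duplicate_variables_cluster_together():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(30, 10))
    mat = pd.DataFrame(np.vstack([base, base]),
                       index=[f"v{i}" for i in range(60)])
    mods = detect_modules(mat, min_size=10)
    lab = mods.labels
    for i in range(30):
        assert lab[f"v{i}"] == lab[f"v{i + 30}"]


def test_constant_rows_dropped_with_warning():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.normal(size=(40, 10)), index=[f"v{i}" for i in range(40)])
    mat.loc["v0"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        mods = detect_modules(mat, min_size=5)
    assert mods.labels["v0"] == 0


def test_eigengene_rank_one_case():
    profile = np.array([1.0, -1.0, 2.0, 0.5, -2.5])
    mat = pd.DataFrame(np.tile(profile, (4, 1)), index=list("abcd"))
    eig = module_eigengene(["a", "b", "c", "d"], mat)
    z = (profile - profile.mean()) / profile.std()
    cor = np.corrcoef(eig, z)[0, 1]
    assert abs(cor) == pytest.approx(1.0)
    assert cor > 0  # sign anchored to member profiles
    assert np.linalg.norm(eig) == pytest.approx(1.0)


def test_eigengene_sign_flips_with_members():
    rng = np.random.default_rng(7)
    mat = pd.DataFrame(rng.normal(size=(5, 8)) + 2 * rng.normal(size=(1, 8)),
                       index=list("abcde"))
    e1 = module_eigengene(list("abcde"), mat)
    e2 = module_eigengene(list("abcde"), -mat)
    assert e1 == pytest.approx(-e2, abs=1e-10)


def test_eigengene_invariant_to_member_scaling():
    rng = np.random.default_rng(8)
    f = rng.normal(size=12)
    mat = pd.DataFrame([f + 0.1 * rng.normal(size=12) for _ in range(6)],
                       index=list("abcdef"))
    scaled = mat.copy()
    scaled.loc["a"] *= 37.0
    e1 = module_eigengene(list("abcdef"), mat)
    e2 = module_eigengene(list("abcdef"), scaled)
    assert abs(np.dot(e1, e2)) == pytest.approx(1.0, abs=1e-9)


def test_eigengene_recovers_latent_factor():
    rng = np.random.default_rng(9)
    f = rng.normal(size=20)
    mat = pd.DataFrame([f + 0.1 * rng.normal(size=20) for _ in range(30)],
                       index=[f"v{i}" for i in range(30)])
    eig = module_eigengene(mat.index, mat)
    assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.95


def test_eigengene_needs_samples_and_members(tiny_matrices):
    a, _ = tiny_matrices
    with pytest.raises(ValueError):
        module_eigengene(["v0"], a)
    with pytest.raises(ValueError):
        module_eigengene(["v0", "v1"], a.iloc[:, :2])


def test_preservation_null_calibrated_near_zero():
    # over 20 pure-noise simulations the mean Z_summary stays in (-1, 1)
    rng = np.random.default_rng(10)
    zs = []
    for _ in range(20):
        ref = pd.DataFrame(rng.normal(size=(60, 15)),
                           index=[f"v{i}" for i in range(60)])
        tst = pd.DataFrame(rng.normal(size=(60, 15)),
                           index=[f"v{i}" for i in range(60)])
        members = [f"v{i}" for i in rng.choice(60, size=20, replace=False)]
        mods = modules_from_labels({m: 1 for m in members}, ref)
        res = preservation_z(mods, tst, n_perm=50, seed=int(rng.integers(1 << 30)))
        zs.append(res.loc[1, "Z_summary"])
    assert -1.0 < float(np.mean(zs)) < 1.0


def test_preservation_universe_mismatch_raises(tiny_matrices):
    a, b = tiny_matrices
    mods = modules_from_labels({f"v{i}": 1 for i in range(5)}, a)
    with pytest.raises(ValueError, match="universe"):
        preservation_z(mods, b.iloc[:8])


def test_eigengene_correlation_identity_and_order_check():
    meth, expr, _ = simulate_comodule_matrices(seed=2)
    mm = detect_modules(meth)
    ec = eigengene_correlation(mm, mm)
    diag = ec[ec["module_a"] == ec["module_b"]]
    assert diag["r"].to_numpy() == pytest.approx(1.0)
    shuffled = ModuleSet(labels=mm.labels, matrix=mm.matrix[mm.matrix.columns[::-1]])
    with pytest.raises(ValueError, match="order"):
        eigengene_correlation(mm, shuffled)


def test_differential_matrix_values(small_fixture):
    cfg = small_fixture.config
    expr_diff, meth_diff = build_differential_matrices(
        small_fixture.expression, small_fixture.coverage,
        small_fixture.annotation.genes, cfg.case_ids, cfg.control_ids[0],
    )
    assert list(expr_diff.columns) == cfg.case_ids
    assert expr_diff.index.equals(meth_diff.index)
    # hand-check one cell against the raw tables
    tx = expr_diff.index[0]
    e_case = small_fixture.expression.loc[tx, cfg.case_ids[0]]
    e_ctrl = small_fixture.expression.loc[tx, cfg.control_ids[0]]
    assert expr_diff.loc[tx, cfg.case_ids[0]] == pytest.approx(
        np.log2(e_case + 1) - np.log2(e_ctrl + 1)
    )
    assert meth_diff.abs().to_numpy().max() <= 100.0


def test_differential_matrix_requires_common_control(small_fixture):
    cfg = small_fixture.config
    with pytest.raises(ValueError, match="control"):
        build_differential_matrices(
            small_fixture.expression, small_fixture.coverage,
            small_fixture.annotation.genes, cfg.case_ids, "nope",
        )
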