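"""Generator contracts: determinism, planted truth, count-model calibration."""

import numpy as np
import pandas as pd
import pytest

from conmeth.sim import (
    ConfigurationError,
    PlantedRegion,
    SimConfig,
    build_genome_annotation,
    simulate_cohort,
    simulate_expression,
    simulate_methylation,
    write_fixture,
)

from conftest import small_config


def test_promoter_is_minus_2kb_to_tss(small_fixture):
    feats = small_fixture.annotation.features
    genes = small_fixture.annotation.genes
    for g in genes.itertuples(index=False):
        prom = feats[(feats["feature_class"] == "promoter") &
                     (feats["transcript_id"] == g.transcript_id)].iloc[0]
        if g.strand == "+":
            assert (prom.start, prom.end) == (g.txStart - 2000, g.txStart)
        else:
            assert (prom.start, prom.end) == (g.txEnd, g.txEnd + 2000)


def test_fixture_is_byte_identical_under_fixed_seed(tmp_path):
    cfg = small_config(seed=3)
    for d in ("a", "b"):
        write_fixture(simulate_cohort(small_config(seed=3)), tmp_path / d)
    for f in sorted((tmp_path / "a").rglob("*")):
        if f.is_file():
            g = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == g.read_bytes(), f.name


def test_truth_context_matches_tile_layout(small_fixture):
    truth = small_fixture.truth
    # intron tiles sit fully inside a gene and carry only intron features
    feats = small_fixture.annotation.features
    introns = truth[truth["context"] == "intron"]
    assert len(introns) > 0
    for row in introns.head(5).itertuples(index=False):
        over = feats[(feats["chrom"] == row.chrom) & (feats["start"] < row.end)
                     & (feats["end"] > row.start)]
        assert set(over["feature_class"]) == {"intron"}


def test_truth_has_one_row_per_tile(small_fixture):
    assert len(small_fixture.truth) == len(small_fixture.annotation.tiles)


def test_depth_mean_within_5_percent(small_fixture):
    # law of large numbers on > 1e4 draws from the truncated NB model
    totals = np.concatenate(
        [df["total_reads"].to_numpy() for df in small_fixture.coverage.values()]
    )
    assert totals.size > 10_000
    assert totals.min() >= 10
    mean = totals.mean()
    assert abs(mean - 50.0) / 50.0 < 0.05


def test_consistent_regions_have_exact_carrier_counts(small_fixture):
    truth = small_fixture.truth
    cons = truth[truth["region_class"].str.endswith("consistent")]
    assert (cons["n_carriers"] == 11).all()
    spor = truth[truth["region_class"].str.endswith("sporadic")]
    assert (spor["n_carriers"] == 4).all()


def test_null_tiles_match_baseline_within_3_se(small_fixture):
    truth = small_fixture.truth.set_index("tile_id")
    nulls = truth[truth["region_class"] == "null"]
    theta = small_fixture.theta.loc[nulls.index]
    resid = theta.to_numpy() - nulls["baseline"].to_numpy()[:, None]
    se = resid.std() / np.sqrt(resid.size)
    assert abs(resid.mean()) < 3 * se + 1e-12


def test_out_of_range_effect_warns_and_clamps():
    cfg = small_config(seed=1)
    ann = build_genome_annotation(cfg)
    bad_tile = int(ann.tiles.loc[ann.tiles["context"] == "intron", "tile_id"].iloc[0])
    cfg.planted = [PlantedRegion(bad_tile, "hyper_consistent", 40.0, 1.0, "intron")]
    with pytest.warns(UserWarning, match="clamped"):
        _, _, theta = simulate_methylation(cfg, ann)
    assert float(theta.max().max()) <= 1.0


def test_empty_genic_class_raises_naming_class():
    cfg = SimConfig(n_chroms=1, chrom_length=10_000, gene_unit_tiles=20)
    with pytest.raises(ConfigurationError, match="promoter"):
        build_genome_annotation(cfg)


def test_unknown_coupling_class_rejected():
    with pytest.raises(ConfigurationError, match="coupling"):
        SimConfig(coupling={"flank": 1.0})


def test_zero_coupling_decouples_expression(small_fixture):
    cfg = small_config(seed=5)
    cfg.coupling = {k: 0.0 for k in cfg.coupling}
    fx = simulate_cohort(cfg)
    # per-transcript mean 3'UTR latent deviation vs log expression
    tiles = fx.annotation.tiles
    theta = fx.theta
    base = tiles.set_index("tile_id")["context"].map(cfg.baseline_meth)
    dev = theta.sub(base, axis=0)
    rows = []
    for gid, sub in tiles[tiles["context"] == "utr3"].groupby("gene_id"):
        if not gid:
            continue
        tx = fx.annotation.genes.set_index("gene_id").loc[gid, "transcript_id"]
        rows.append((np.log(fx.expression.loc[tx, cfg.case_ids]).mean(),
                     dev.loc[sub["tile_id"], cfg.case_ids].mean().mean()))
    x, y = np.array(rows).T
    r = np.corrcoef(x, y)[0, 1]
    assert abs(r) < 0.25  # small cohort; no systematic coupling


def test_expression_deterministic_under_seed(small_fixture):
    cfg = small_config()
    ann = small_fixture.annotation
    e1 = simulate_expression(cfg, ann, small_fixture.theta)
    e2 = simulate_expression(cfg, ann, small_fixture.theta)
    pd.testing.assert_frame_equal(e1, e2)


def test_planted_effect_recoverable_at_depth(small_fixture):
    # mean observed tile delta-meth among carriers within +/-5 points
    truth = small_fixture.truth
    cov = small_fixture.coverage
    cpgs = small_fixture.annotation.cpgs
    cons = truth[truth["region_class"] == "hyper_consistent"]
    deltas = []
    ctrl_ids = small_fixture.config.control_ids
    for row in cons.itertuples(index=False):
        sites = cpgs[cpgs["tile_id"] == row.tile_id]
        carriers = row.carriers.split(",")
        for sid in carriers:
            sub = cov[sid].merge(sites, on=["chrom", "pos"])
            lvl = sub["meth_reads"].sum() / sub["total_reads"].sum()
            ctl = np.mean(
                [
                    (cov[c].merge(sites, on=["chrom", "pos"])["meth_reads"].sum()
                     / cov[c].merge(sites, on=["chrom", "pos"])["total_reads"].sum())
                    for c in ctrl_ids
                ]
            )
            deltas.append(100 * (lvl - ctl))
    assert abs(np.mean(deltas) - 40.0) < 5.0


def test_planted_region_invariants_enforced():
    with pytest.raises(ConfigurationError):
        PlantedRegion(0, "hyper_consistent", 40.0, 0.5, "promoter")
    with pytest.raises(ConfigurationError):
        PlantedRegion(0, "hypo_sporadic", -40.0, 0.9, "intron")
    with pytest.raises(ConfigurationError):
        PlantedRegion(0, "null", 10.0, 0.0, "intron")
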