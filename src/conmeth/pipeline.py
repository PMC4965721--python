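"""End-to-end orchestration with a single config and an output manifest.

Stages: simulate (optional) -> dmr -> cdmr -> entropy -> annotate ->
profile -> comodule.  Every stage writes plain TSV/BED so each is
independently re-runnable; the manifest records package version,
parameters, seed and input checksums.  Any stage failure aborts with
the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    FeatureIndex,
    gene_features,
    interval_enrichment,
    location_distribution,
    select_reference_isoform,
)
from .comodule import (
    build_differential_matrices,
    crosstab_overlap,
    detect_modules,
    eigengene_correlation,
    preservation_z,
)
from .consistency import call_cdmrs
from .dmr import aggregate_tiles, calls_to_bed, compare_cohort
from .entropy import entropy_change_correlation, entropy_table
from .expr_meth import assign_quartiles, average_cpg_methylation, metagene_profile
from .sim import Fixture, SimConfig, read_fixture, simulate_cohort, write_fixture

__all__ = ["RunConfig", "StageError", "run_all", "ALL_STAGES"]

ALL_STAGES = ("simulate", "dmr", "cdmr", "entropy", "annotate", "profile", "comodule")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters.

    Defaults match the published analysis thresholds where stated:
    1000-bp tiles with >=3 CpGs at >=10 reads each, pairwise Fisher
    q < 0.01, binomial consistency in >= 25 of 30 cases at q < 0.01,
    permutation q < 0.05.
    """

    input_dir: str | None = None
    simulate: dict | None = None
    stages: tuple = ALL_STAGES
    tile_size: int = 1000
    min_cpgs: int = 3
    min_depth: int = 10
    dmr_q: float = 0.01
    diff_thresh: float = 25.0
    k_min: int = 25
    cdmr_q: float = 0.01
    perm: int = 100
    perm_q: float = 0.05
    entropy_input: str = "level"
    beta: float = 6.0
    cut_height: float = 0.75
    min_module_size: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the configured stages and return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "conmeth",
        "version": __version__,
        "parameters": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "inputs": {},
        "outputs": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage, *outputs):
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(o.relative_to(outdir)) for o in outputs)

    fixture: Fixture | None = None
    stage = "simulate"
    try:
        if "simulate" in config.stages and config.simulate is not None:
            sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
            fixture = simulate_cohort(sim_cfg)
            fdir = write_fixture(fixture, outdir / "fixture")
            record(stage, *sorted(fdir.rglob("*.tsv")))
        elif config.input_dir is not None:
            fixture = read_fixture(config.input_dir)
            for f in sorted(Path(config.input_dir).rglob("*")):
                if f.is_file():
                    manifest["inputs"][str(f.name)] = _sha256(f)
            manifest["stages"].append("simulate(skipped: external input)")
        else:
            raise ValueError("need either an input_dir or a simulate block")
    except Exception as e:  # noqa: BLE001 - stage failures must name the stage
        raise StageError(f"stage '{stage}' failed: {e}") from e

    case_ids = fixture.config.case_ids
    control_ids = fixture.config.control_ids

    stage = "dmr"
    tiles = None
    comparisons = {}
    if stage in config.stages:
        try:
            tiles = aggregate_tiles(
                fixture.coverage, config.tile_size, config.min_cpgs, config.min_depth
            )
            tiles.to_csv(outdir / "tiles.tsv", sep="\t", index=False)
            outs = [outdir / "tiles.tsv"]
            for ctrl in control_ids:
                cmp = compare_cohort(
                    tiles, case_ids, ctrl, q_thresh=config.dmr_q,
                    diff_thresh=config.diff_thresh,
                )
                comparisons[ctrl] = cmp
                f = outdir / f"dmr_{ctrl}.tsv"
                cmp.calls.to_csv(f, sep="\t", index=False)
                outs.append(f)
            record(stage, *outs)
        except Exception as e:
            raise StageError(f"stage '{stage}' failed: {e}") from e

    stage = "cdmr"
    cdmr = None
    if stage in config.stages:
        try:
            if tiles is None:
                raise ValueError("cdmr requires the dmr stage")
            cdmr = call_cdmrs(
                tiles, case_ids, control_ids,
                q_dmr=config.dmr_q, diff_thresh=config.diff_thresh,
                k_min=config.k_min, q_cdmr=config.cdmr_q,
                n_perm=config.perm, perm_q_thresh=config.perm_q,
                seed=config.seed, permutation=config.perm > 0,
            )
            f = outdir / "cdmr.tsv"
            cdmr.table.to_csv(f, sep="\t", index=False)
            sig = cdmr.table[cdmr.table["is_cdmr"]]
            bed = pd.DataFrame(
                {"chrom": sig["chrom"], "start": sig["start"], "end": sig["end"],
                 "name": sig["direction"]}
            )
            fb = outdir / "cdmr.bed"
            bed.to_csv(fb, sep="\t", header=False, index=False)
            record(stage, f, fb)
        except Exception as e:
            raise StageError(f"stage '{stage}' failed: {e}") from e

    stage = "entropy"
    if stage in config.stages:
        try:
            if not comparisons:
                raise ValueError("entropy requires the dmr stage")
            outs = []
            summary = []
            for ctrl, cmp in comparisons.items():
                tbl = entropy_table(
                    tiles, case_ids, ctrl, cmp.common_regions,
                    input_kind=config.entropy_input,
                )
                f = outdir / f"entropy_{ctrl}.tsv"
                tbl.reset_index().to_csv(f, sep="\t", index=False)
                outs.append(f)
                r, p = entropy_change_correlation(tbl)
                summary.append(dict(control_id=ctrl, pearson_r=r, p=p))
            fs = outdir / "entropy_summary.tsv"
            pd.DataFrame(summary).to_csv(fs, sep="\t", index=False)
            record(stage, *outs, fs)
        except Exception as e:
            raise StageError(f"stage '{stage}' failed: {e}") from e

    stage = "annotate"
    if stage in config.stages:
        try:
            if cdmr is None:
                raise ValueError("annotate requires the cdmr stage")
            genes = select_reference_isoform(fixture.annotation.genes)
            feats = gene_features(genes)
            index = FeatureIndex(
                feats,
                {k: v for k, v in fixture.annotation.tracks.items()
                 if k in ("cpg_island", "repeat", "enhancer") and len(v)},
            )
            background = cdmr.table[cdmr.table["direction"] == "hyper"][
                ["chrom", "start", "end"]
            ].drop_duplicates()
            outs = []
            for direction in ("hyper", "hypo"):
                sig = cdmr.table[
                    (cdmr.table["direction"] == direction) & cdmr.table["is_cdmr"]
                ][["chrom", "start", "end"]]
                if len(sig) == 0:
                    continue
                dist = location_distribution(sig, background, index)
                f = outdir / f"context_{direction}.tsv"
                dist.reset_index().to_csv(f, sep="\t", index=False)
                outs.append(f)
                tracks = {
                    k: v for k, v in fixture.annotation.tracks.items()
                    if k in ("cpg_island", "repeat", "enhancer") and len(v)
                }
                enr = interval_enrichment(sig, tracks, background)
                f2 = outdir / f"enrichment_{direction}.tsv"
                enr.reset_index().to_csv(f2, sep="\t", index=False)
                outs.append(f2)
            record(stage, *outs)
        except Exception as e:
            raise StageError(f"stage '{stage}' failed: {e}") from e

    stage = "profile"
    if stage in config.stages:
        try:
            expr = fixture.expression
            if expr is None or expr.empty:
                raise ValueError("profile requires an expression table")
            quart = assign_quartiles(expr[case_ids].mean(axis=1))
            levels = average_cpg_methylation(
                fixture.coverage, case_ids, min_depth=config.min_depth
            )
            genes = select_reference_isoform(fixture.annotation.genes)
            prof = metagene_profile(genes, levels, quart, unit="gene")
            f = outdir / "profile_gene.tsv"
            prof.to_csv(f, sep="\t", index=False)
            record(stage, f)
        except Exception as e:
            raise StageError(f"stage '{stage}' failed: {e}") from e

    stage = "comodule"
    if stage in config.stages:
        try:
            expr = fixture.expression
            if expr is None or expr.empty:
                raise ValueError("comodule requires an expression table")
            genes = select_reference_isoform(fixture.annotation.genes)
            expr_diff, meth_diff = build_differential_matrices(
                expr, fixture.coverage, genes, case_ids, control_ids[0],
                min_depth=config.min_depth,
            )
            mod_e = detect_modules(expr_diff, beta=config.beta,
                                   cut_height=config.cut_height,
                                   min_size=config.min_module_size)
            mod_m = detect_modules(meth_diff, beta=config.beta,
                                   cut_height=config.cut_height,
                                   min_size=config.min_module_size)
            outs = []
            for name, mod in (("expression", mod_e), ("methylation", mod_m)):
                f = outdir / f"modules_{name}.tsv"
                mod.labels.rename("module").reset_index().to_csv(f, sep="\t", index=False)
                outs.append(f)
            if mod_e.module_labels() and mod_m.module_labels():
                ov = crosstab_overlap(mod_m, mod_e)
                f = outdir / "module_overlap.tsv"
                ov.to_csv(f, sep="\t", index=False)
                outs.append(f)
                pres = preservation_z(mod_e, meth_diff, beta=config.beta,
                                      n_perm=config.perm, seed=config.seed)
                f = outdir / "module_preservation.tsv"
                pres.reset_index().to_csv(f, sep="\t", index=False)
                outs.append(f)
                ec = eigengene_correlation(mod_m, mod_e)
                f = outdir / "module_eigengene_cor.tsv"
                ec.to_csv(f, sep="\t", index=False)
                outs.append(f)
            record(stage, *outs)
        except Exception as e:
            raise StageError(f"stage '{stage}' failed: {e}") from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
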