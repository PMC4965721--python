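"""Synthetic bisulfite cohort generator with planted ground truth.

Emulates the shape of an RRBS case/control study: ~30 case and 3
control samples, per-CpG methylated/total read counts over a toy
genome, annotation tracks (genes with UTR/exon/intron structure,
promoters, CpG islands and shores, repeats, enhancers), and a matched
per-transcript expression table whose coupling to methylation is
region-class specific.  Every tile of the genome carries a truth label
(region class, effect size, carrier samples) so downstream stages can
be scored against a known answer.

Genome layout
-------------
The toy genome is built from 1000-bp tiles.  Genes occupy 7 consecutive
tiles in a fixed pattern (promoter, promoter, 5'UTR exon, intron,
coding exon, intron, 3'UTR exon on the plus strand; mirrored on the
minus strand) followed by intergenic spacer tiles, so each tile has a
single designed genic context.  CpG islands sit over promoter/5'UTR
boundaries; repeats and enhancers are placed on a deterministic subset
of intergenic and intronic tiles.

Randomness is consumed from named substreams seeded as
``default_rng([seed, k])`` in a fixed order (genome, carriers,
methylation noise, read counts, expression), so a config reproduces
every output bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio

__all__ = [
    "SimConfig",
    "PlantedRegion",
    "GenomeAnnotation",
    "Fixture",
    "ConfigurationError",
    "build_genome_annotation",
    "simulate_methylation",
    "simulate_expression",
    "simulate_cohort",
    "write_fixture",
    "read_fixture",
    "standard_config",
    "null_config",
    "coupling_config",
    "simulate_comodule_matrices",
]

REGION_CLASSES = (
    "hyper_consistent",
    "hypo_consistent",
    "hyper_sporadic",
    "hypo_sporadic",
    "null",
)

GENIC_CONTEXTS = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic")

_PLUS_LAYOUT = ("promoter", "promoter", "utr5", "intron", "exon", "intron", "utr3")
_MINUS_LAYOUT = tuple(reversed(_PLUS_LAYOUT))

PROMOTER_BP = 2000
SHORE_BP = 2000


class ConfigurationError(ValueError):
    """A simulation config that cannot produce a valid fixture."""


@dataclass
class PlantedRegion:
    """A tile with a planted methylation effect.

    effect is in percentage points (signed); carrier_fraction is the
    fraction of case samples carrying the effect.  Consistent classes
    must have carrier_fraction >= 25/30, sporadic < 0.5, null has
    effect 0.
    """

    tile_id: int
    region_class: str
    effect: float
    carrier_fraction: float
    context: str

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise ConfigurationError(f"unknown region class {self.region_class!r}")
        if self.region_class.endswith("consistent") and self.carrier_fraction < 25 / 30:
            raise ConfigurationError(
                "consistent planted regions need carrier_fraction >= 25/30"
            )
        if self.region_class.endswith("sporadic") and self.carrier_fraction >= 0.5:
            raise ConfigurationError(
                "sporadic planted regions need carrier_fraction < 0.5"
            )
        if self.region_class == "null" and self.effect != 0:
            raise ConfigurationError("null regions must have effect 0")


def _default_baselines() -> dict:
    # CpG-dense promoter/5'UTR contexts start lowly methylated; gene
    # bodies and intergenic space highly methylated, as in somatic tissue.
    return {
        "promoter": 0.15,
        "utr5": 0.15,
        "exon": 0.40,
        "intron": 0.75,
        "utr3": 0.75,
        "intergenic": 0.75,
    }


def _default_coupling() -> dict:
    # Methylation-expression coupling signs: promoter/5'UTR/exon
    # negative, 3'UTR positive, intron ~ none.
    return {"promoter": -1.5, "utr5": -1.5, "exon": -1.0, "intron": 0.0, "utr3": 1.0}


@dataclass
class SimConfig:
    n_case: int = 30
    n_control: int = 3
    n_chroms: int = 2
    chrom_length: int = 500_000
    tile_size: int = 1000
    cpgs_per_tile: tuple = (3, 8)
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    depth_floor: int = 10
    baseline_meth: dict = field(default_factory=_default_baselines)
    sample_noise_sd: float = 0.02
    control_heterogeneity: float = 0.02
    planted: list = field(default_factory=list)
    coupling: dict = field(default_factory=_default_coupling)
    expr_base_mean: float = 1.0
    expr_base_sd: float = 1.0
    expr_noise_sd: float = 0.3
    gene_unit_tiles: int = 10
    minus_strand_every: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length < 10 * self.tile_size:
            raise ConfigurationError("chrom_length must be >= 10 * tile_size")
        if self.depth_mean < self.depth_floor:
            raise ConfigurationError("depth_mean below achievable depth floor")
        for ctx, b in self.baseline_meth.items():
            if not 0.0 <= b <= 1.0:
                raise ConfigurationError(f"baseline for {ctx!r} outside [0, 1]")
        for ctx in self.coupling:
            if ctx not in GENIC_CONTEXTS:
                raise ConfigurationError(f"unknown genic class in coupling map: {ctx!r}")
        self.planted = [
            p if isinstance(p, PlantedRegion) else PlantedRegion(**p)
            for p in self.planted
        ]

    @property
    def case_ids(self) -> list:
        return [f"case_{i + 1:02d}" for i in range(self.n_case)]

    @property
    def control_ids(self) -> list:
        return [f"control_{i + 1:02d}" for i in range(self.n_control)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cpgs_per_tile"] = list(self.cpgs_per_tile)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["cpgs_per_tile"] = tuple(d["cpgs_per_tile"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GenomeAnnotation:
    """Tile map, CpG sites, gene models and annotation tracks."""

    tiles: pd.DataFrame  # tile_id chrom start end context gene_id
    cpgs: pd.DataFrame  # chrom pos tile_id
    genes: pd.DataFrame  # gene-model TSV columns + gene_id
    features: pd.DataFrame  # chrom start end strand feature_class gene_id transcript_id
    tracks: dict  # name -> BED DataFrame (islands, shores, repeats, enhancers, promoters)


@dataclass
class Fixture:
    """A complete simulated cohort plus its ground truth."""

    config: SimConfig
    annotation: GenomeAnnotation
    coverage: dict  # sample_id -> coverage DataFrame
    truth: pd.DataFrame
    theta: pd.DataFrame  # latent per-tile methylation probability, tiles x samples
    expression: pd.DataFrame  # transcripts x samples

    @property
    def sample_ids(self) -> list:
        return self.config.case_ids + self.config.control_ids


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def build_genome_annotation(config: SimConfig) -> GenomeAnnotation:
    """Lay out the toy genome: tiles, genes, CpG sites and tracks.

    Raises :class:`ConfigurationError` naming the class if any genic
    class ends up with no tile.
    """
    ts = config.tile_size
    if ts != 1000:
        raise ConfigurationError(
            "the generator's gene layout is tile-aligned and requires tile_size=1000"
        )
    unit = config.gene_unit_tiles
    if unit < len(_PLUS_LAYOUT) + 1:
        raise ConfigurationError("gene_unit_tiles must leave at least one spacer tile")

    tile_rows = []
    gene_rows = []
    feature_rows = []
    islands = []
    repeats = []
    enhancers = []
    promoters = []

    gidx = 0
    tile_id = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_tiles = config.chrom_length // ts
        contexts = ["intergenic"] * n_tiles
        gene_of_tile = [""] * n_tiles
        for unit_start in range(0, n_tiles - unit + 1, unit):
            strand = "-" if (gidx % config.minus_strand_every == config.minus_strand_every - 1) else "+"
            layout = _PLUS_LAYOUT if strand == "+" else _MINUS_LAYOUT
            gene_id = f"gene_{gidx + 1:04d}"
            tx_id = f"tx_{gidx + 1:04d}"
            for k, ctx in enumerate(layout):
                contexts[unit_start + k] = ctx
                if ctx != "promoter":
                    gene_of_tile[unit_start + k] = gene_id
            u = unit_start * ts
            if strand == "+":
                tx_start, tx_end = u + 2 * ts, u + 7 * ts
                cds_start, cds_end = u + 4 * ts, u + 5 * ts
                exon_starts = (u + 2 * ts, u + 4 * ts, u + 6 * ts)
                prom = (tx_start - PROMOTER_BP, tx_start)
                island = (tx_start - ts // 2, tx_start + ts)
            else:
                tx_start, tx_end = u, u + 5 * ts
                cds_start, cds_end = u + 2 * ts, u + 3 * ts
                exon_starts = (u, u + 2 * ts, u + 4 * ts)
                prom = (tx_end, tx_end + PROMOTER_BP)
                island = (tx_end - ts, tx_end + ts // 2)
            exon_ends = tuple(s + ts for s in exon_starts)
            gene_rows.append(
                dict(
                    transcript_id=tx_id,
                    chrom=chrom,
                    strand=strand,
                    txStart=tx_start,
                    txEnd=tx_end,
                    cdsStart=cds_start,
                    cdsEnd=cds_end,
                    exonStarts=exon_starts,
                    exonEnds=exon_ends,
                    gene_id=gene_id,
                )
            )
            promoters.append(dict(chrom=chrom, start=prom[0], end=prom[1], name=gene_id))
            islands.append(dict(chrom=chrom, start=island[0], end=island[1], name=gene_id))
            # deterministic repeat/enhancer placement on spacer and intron tiles
            spacer0 = unit_start + len(layout)
            if spacer0 < n_tiles:
                if gidx % 2 == 0:
                    repeats.append(
                        dict(chrom=chrom, start=spacer0 * ts, end=(spacer0 + 1) * ts)
                    )
                else:
                    enhancers.append(
                        dict(chrom=chrom, start=spacer0 * ts, end=(spacer0 + 1) * ts)
                    )
            intron_tile = unit_start + (3 if strand == "+" else 1)
            if gidx % 2 == 0:
                enhancers.append(
                    dict(chrom=chrom, start=intron_tile * ts, end=(intron_tile + 1) * ts)
                )
            gidx += 1
        for k in range(n_tiles):
            tile_rows.append(
                dict(
                    tile_id=tile_id,
                    chrom=chrom,
                    start=k * ts,
                    end=(k + 1) * ts,
                    context=contexts[k],
                    gene_id=gene_of_tile[k],
                )
            )
            tile_id += 1

    tiles = pd.DataFrame(tile_rows)
    present = set(tiles["context"].unique())
    for ctx in GENIC_CONTEXTS:
        if ctx not in present:
            raise ConfigurationError(f"configuration leaves genic class '{ctx}' empty")

    genes = pd.DataFrame(gene_rows)
    feature_rows = _gene_feature_rows(genes)
    features = pd.DataFrame(feature_rows)

    shores = []
    for isl in islands:
        shores.append(
            dict(chrom=isl["chrom"], start=max(0, isl["start"] - SHORE_BP), end=isl["start"])
        )
        shores.append(dict(chrom=isl["chrom"], start=isl["end"], end=isl["end"] + SHORE_BP))
    tracks = {
        "cpg_island": pd.DataFrame(islands),
        "shore": pd.DataFrame(shores),
        "repeat": pd.DataFrame(repeats),
        "enhancer": pd.DataFrame(enhancers),
        "promoter": pd.DataFrame(promoters),
    }

    rng = _rng(config, 0)
    lo, hi = config.cpgs_per_tile
    n_per_tile = rng.integers(lo, hi + 1, size=len(tiles))
    cpg_rows = []
    for (tid, chrom, start), n in zip(
        tiles[["tile_id", "chrom", "start"]].itertuples(index=False), n_per_tile
    ):
        offs = np.sort(rng.choice(ts, size=int(n), replace=False))
        for o in offs:
            cpg_rows.append((chrom, start + int(o), tid))
    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "tile_id"])
    return GenomeAnnotation(tiles=tiles, cpgs=cpgs, genes=genes, features=features, tracks=tracks)


def _gene_feature_rows(genes: pd.DataFrame) -> list:
    """Derive promoter/utr5/exon/intron/utr3 intervals per gene model."""
    rows = []
    for g in genes.itertuples(index=False):
        tss_prom = (
            (g.txStart - PROMOTER_BP, g.txStart)
            if g.strand == "+"
            else (g.txEnd, g.txEnd + PROMOTER_BP)
        )
        rows.append(
            dict(chrom=g.chrom, start=max(0, tss_prom[0]), end=tss_prom[1], strand=g.strand,
                 feature_class="promoter", gene_id=g.gene_id, transcript_id=g.transcript_id)
        )
        exons = list(zip(g.exonStarts, g.exonEnds))
        for s, e in exons:
            rows.append(
                dict(chrom=g.chrom, start=s, end=e, strand=g.strand,
                     feature_class="exon", gene_id=g.gene_id, transcript_id=g.transcript_id)
            )
            # UTR portions of this exon
            if s < g.cdsStart:
                u_s, u_e = s, min(e, g.cdsStart)
                cls = "utr5" if g.strand == "+" else "utr3"
                rows.append(
                    dict(chrom=g.chrom, start=u_s, end=u_e, strand=g.strand,
                         feature_class=cls, gene_id=g.gene_id, transcript_id=g.transcript_id)
                )
            if e > g.cdsEnd:
                u_s, u_e = max(s, g.cdsEnd), e
                cls = "utr3" if g.strand == "+" else "utr5"
                rows.append(
                    dict(chrom=g.chrom, start=u_s, end=u_e, strand=g.strand,
                         feature_class=cls, gene_id=g.gene_id, transcript_id=g.transcript_id)
                )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            rows.append(
                dict(chrom=g.chrom, start=e1, end=s2, strand=g.strand,
                     feature_class="intron", gene_id=g.gene_id, transcript_id=g.transcript_id)
            )
    return rows


def simulate_methylation(config: SimConfig, annotation: GenomeAnnotation):
    """Draw per-sample CpG counts under the planted-effect model.

    Returns (coverage dict, truth DataFrame, theta DataFrame).  The
    latent per-tile methylation probability is baseline(context) plus
    the planted effect for carrier case samples, plus small per-sample
    noise; read totals are depth_floor + NegBin(depth_mean - floor,
    dispersion) and methylated reads are Binomial(total, theta).
    """
    tiles = annotation.tiles
    samples = config.case_ids + config.control_ids
    n_tiles, n_samples = len(tiles), len(samples)

    base = tiles["context"].map(config.baseline_meth).to_numpy(float)
    theta = np.repeat(base[:, None], n_samples, axis=1)

    planted_by_tile = {p.tile_id: p for p in config.planted}
    if len(planted_by_tile) != len(config.planted):
        raise ConfigurationError("duplicate tile_id in planted regions")

    rng_carriers = _rng(config, 1)
    carriers: dict = {}
    tile_index = pd.Index(tiles["tile_id"])
    for p in config.planted:
        if p.tile_id not in tile_index:
            raise ConfigurationError(f"planted tile_id {p.tile_id} not in genome")
        k = int(round(p.carrier_fraction * config.n_case))
        chosen = sorted(
            rng_carriers.choice(config.n_case, size=k, replace=False).tolist()
        )
        carriers[p.tile_id] = [config.case_ids[i] for i in chosen]
        row = tile_index.get_loc(p.tile_id)
        target = base[row] + p.effect / 100.0
        if not 0.0 <= target <= 1.0:
            warnings.warn(
                f"tile {p.tile_id}: baseline+effect {target:.3f} outside [0, 1]; clamped",
                stacklevel=2,
            )
        theta[row, chosen] += p.effect / 100.0

    rng_noise = _rng(config, 2)
    sds = np.array(
        [config.sample_noise_sd] * config.n_case
        + [config.control_heterogeneity] * config.n_control
    )
    theta = theta + rng_noise.normal(0.0, 1.0, size=(n_tiles, n_samples)) * sds[None, :]
    theta = np.clip(theta, 0.0, 1.0)

    # read counts
    rng_counts = _rng(config, 3)
    cpg_tile_row = tile_index.get_indexer(annotation.cpgs["tile_id"])
    n_cpgs = len(annotation.cpgs)
    mu = config.depth_mean - config.depth_floor
    r = config.depth_dispersion
    if mu > 0:
        totals = config.depth_floor + rng_counts.negative_binomial(
            r, r / (r + mu), size=(n_cpgs, n_samples)
        )
    else:
        totals = np.full((n_cpgs, n_samples), config.depth_floor, dtype=np.int64)
    meth = rng_counts.binomial(totals, theta[cpg_tile_row, :])

    coverage = {}
    for j, sid in enumerate(samples):
        coverage[sid] = pd.DataFrame(
            {
                "chrom": annotation.cpgs["chrom"].to_numpy(),
                "pos": annotation.cpgs["pos"].to_numpy(),
                "meth_reads": meth[:, j],
                "total_reads": totals[:, j],
            }
        )

    truth = tiles.copy()
    truth["region_class"] = [
        planted_by_tile[t].region_class if t in planted_by_tile else "null"
        for t in truth["tile_id"]
    ]
    truth["effect"] = [
        planted_by_tile[t].effect if t in planted_by_tile else 0.0
        for t in truth["tile_id"]
    ]
    truth["carriers"] = [
        ",".join(carriers.get(t, [])) for t in truth["tile_id"]
    ]
    truth["n_carriers"] = [len(carriers.get(t, [])) for t in truth["tile_id"]]
    truth["baseline"] = base

    theta_df = pd.DataFrame(theta, index=tiles["tile_id"].to_numpy(), columns=samples)
    return coverage, truth, theta_df


def simulate_expression(
    config: SimConfig, annotation: GenomeAnnotation, theta: pd.DataFrame
) -> pd.DataFrame:
    """Simulate an FPKM-like expression table coupled to methylation.

    log expression = base + sum_class coupling[class] * mean latent
    methylation deviation of the gene's tiles in that class + noise;
    expression = exp(.) so all values are positive.
    """
    tiles = annotation.tiles
    samples = list(theta.columns)
    genes = annotation.genes
    rng = _rng(config, 4)
    base_t = rng.normal(config.expr_base_mean, config.expr_base_sd, size=len(genes))
    noise = rng.normal(0.0, config.expr_noise_sd, size=(len(genes), len(samples)))

    baseline = tiles["context"].map(config.baseline_meth).to_numpy(float)
    dev = theta.to_numpy() - baseline[:, None]  # tiles x samples

    log_expr = np.repeat(base_t[:, None], len(samples), axis=1) + noise
    tile_gene = tiles["gene_id"].to_numpy()
    tile_ctx = tiles["context"].to_numpy()
    for gi, g in enumerate(genes.itertuples(index=False)):
        mask_g = tile_gene == g.gene_id
        for ctx, strength in config.coupling.items():
            if strength == 0.0:
                continue
            m = mask_g & (tile_ctx == ctx)
            if m.any():
                log_expr[gi] += strength * dev[m].mean(axis=0)
    expr = pd.DataFrame(
        np.exp(log_expr), index=genes["transcript_id"].to_numpy(), columns=samples
    )
    expr.index.name = "transcript_id"
    return expr


def simulate_cohort(config: SimConfig) -> Fixture:
    """Run the full generator: annotation, methylation, expression."""
    annotation = build_genome_annotation(config)
    coverage, truth, theta = simulate_methylation(config, annotation)
    expression = simulate_expression(config, annotation, theta)
    return Fixture(
        config=config,
        annotation=annotation,
        coverage=coverage,
        truth=truth,
        theta=theta,
        expression=expression,
    )


def write_fixture(fixture: Fixture, outdir) -> Path:
    """Serialise a fixture to plain-text files that round-trip losslessly."""
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    for sid, df in fixture.coverage.items():
        cio.write_coverage(df, outdir / "coverage" / f"{sid}.tsv")
    cio.write_gene_models(fixture.annotation.genes, outdir / "genes.tsv")
    for name, fname in [
        ("cpg_island", "islands.bed"),
        ("shore", "shores.bed"),
        ("repeat", "repeats.bed"),
        ("enhancer", "enhancers.bed"),
        ("promoter", "promoters.bed"),
    ]:
        cio.write_bed(fixture.annotation.tracks[name], outdir / fname)
    cio.write_expression(fixture.expression, outdir / "expression.tsv")
    fixture.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": fixture.sample_ids,
            "group": ["case"] * fixture.config.n_case
            + ["control"] * fixture.config.n_control,
        }
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    fixture.config.to_yaml(outdir / "sim.yaml")
    return outdir


def read_fixture(indir) -> Fixture:
    """Load a fixture written by :func:`write_fixture`."""
    indir = Path(indir)
    config = SimConfig.from_yaml(indir / "sim.yaml")
    annotation = build_genome_annotation(config)
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    coverage = {
        sid: cio.read_coverage(indir / "coverage" / f"{sid}.tsv")
        for sid in samples["sample_id"]
    }
    truth = pd.read_csv(
        indir / "truth.tsv", sep="\t", keep_default_na=False, dtype={"carriers": str}
    )
    expr_path = indir / "expression.tsv"
    # stages that need expression raise there, not at load time
    expression = cio.read_expression(expr_path) if expr_path.exists() else pd.DataFrame()
    # latent theta is not serialised; regenerate it from the config
    _, _, theta = simulate_methylation(config, annotation)
    return Fixture(
        config=config,
        annotation=annotation,
        coverage=coverage,
        truth=truth,
        theta=theta,
        expression=expression,
    )


# ---------------------------------------------------------------------------
# study-condition config factories


def standard_config(
    seed: int = 0,
    *,
    n_case: int = 30,
    n_control: int = 3,
    n_chroms: int = 2,
    chrom_length: int = 500_000,
    n_hyper: int = 50,
    n_hypo: int = 50,
    n_hyper_sporadic: int = 50,
    n_hypo_sporadic: int = 50,
    effect: float = 40.0,
    consistent_carriers: int = 28,
    sporadic_carriers: int = 10,
) -> SimConfig:
    """The standard benchmark cohort: 30+3 samples over 1000 tiles with
    50 hyper- and 50 hypo-consistent regions (40-point effects carried
    by 28/30 cases), 100 sporadic regions (10/30 carriers), rest null.

    Hyper effects are placed in CpG-island/promoter-biased contexts,
    hypo effects in intron/3'UTR/intergenic contexts.
    """
    cfg = SimConfig(
        n_case=n_case, n_control=n_control, n_chroms=n_chroms,
        chrom_length=chrom_length, seed=seed,
    )
    tiles = build_genome_annotation(cfg).tiles
    rng = np.random.default_rng([int(seed), 99])
    hyper_pool = tiles.loc[tiles["context"].isin(["promoter", "utr5"]), "tile_id"].to_numpy()
    hypo_pool = tiles.loc[
        tiles["context"].isin(["intron", "utr3", "intergenic"]), "tile_id"
    ].to_numpy()
    need_hyper, need_hypo = n_hyper + n_hyper_sporadic, n_hypo + n_hypo_sporadic
    if len(hyper_pool) < need_hyper or len(hypo_pool) < need_hypo:
        raise ConfigurationError("genome too small for the requested planted regions")
    hyper_tiles = rng.choice(hyper_pool, size=need_hyper, replace=False)
    hypo_tiles = rng.choice(hypo_pool, size=need_hypo, replace=False)
    ctx = tiles.set_index("tile_id")["context"]
    planted = []
    cf_cons = consistent_carriers / n_case
    cf_spor = sporadic_carriers / n_case
    for t in hyper_tiles[:n_hyper]:
        planted.append(PlantedRegion(int(t), "hyper_consistent", effect, cf_cons, ctx[t]))
    for t in hyper_tiles[n_hyper:]:
        planted.append(PlantedRegion(int(t), "hyper_sporadic", effect, cf_spor, ctx[t]))
    for t in hypo_tiles[:n_hypo]:
        planted.append(PlantedRegion(int(t), "hypo_consistent", -effect, cf_cons, ctx[t]))
    for t in hypo_tiles[n_hypo:]:
        planted.append(PlantedRegion(int(t), "hypo_sporadic", -effect, cf_spor, ctx[t]))
    cfg.planted = planted
    return cfg


def null_config(seed: int = 0, *, n_tiles: int = 500, n_case: int = 30, n_control: int = 3) -> SimConfig:
    """A cohort with no planted effects (type-I error calibration)."""
    return SimConfig(
        n_case=n_case,
        n_control=n_control,
        n_chroms=1,
        chrom_length=n_tiles * 1000,
        seed=seed,
    )


def coupling_config(
    seed: int = 0,
    *,
    n_transcripts: int = 500,
    n_case: int = 30,
    n_control: int = 3,
    max_effect: float = 50.0,
) -> SimConfig:
    """A cohort tuned for methylation-expression coupling analysis.

    Every gene's 5'UTR tile carries a hypermethylation effect and its
    3'UTR tile a hypomethylation effect, with per-gene magnitudes drawn
    uniformly from [0, max_effect] points and all case samples as
    carriers, so per-transcript methylation varies across the cohort.
    The between-transcript base-abundance spread is halved relative to
    the cohort default so the deliberately weak positive 3'UTR coupling
    stays detectable at a few hundred transcripts.
    """
    n_chroms = 5
    chrom_length = int(np.ceil(n_transcripts * 10 / n_chroms)) * 1000
    cfg = SimConfig(
        n_case=n_case, n_control=n_control, n_chroms=n_chroms,
        chrom_length=chrom_length, expr_base_sd=0.5, seed=seed,
    )
    ann = build_genome_annotation(cfg)
    rng = np.random.default_rng([int(seed), 98])
    tiles = ann.tiles
    planted = []
    for gene_id, sub in tiles[tiles["gene_id"] != ""].groupby("gene_id", sort=True):
        u5 = sub.loc[sub["context"] == "utr5", "tile_id"]
        u3 = sub.loc[sub["context"] == "utr3", "tile_id"]
        if len(u5):
            planted.append(
                PlantedRegion(int(u5.iloc[0]), "hyper_consistent",
                              float(rng.uniform(0, max_effect)), 1.0, "utr5")
            )
        if len(u3):
            planted.append(
                PlantedRegion(int(u3.iloc[0]), "hypo_consistent",
                              -float(rng.uniform(0, max_effect)), 1.0, "utr3")
            )
    cfg.planted = planted
    return cfg


def simulate_comodule_matrices(
    seed: int = 0,
    *,
    n_samples: int = 30,
    block_size: int = 50,
    n_noise: int = 70,
    loading: float = 0.98,
    shared_sign: float = -1.0,
):
    """Differential matrices with planted correlation-module structure.

    Returns ``(meth, expr, truth)`` where both matrices are variables x
    samples DataFrames over the same transcript universe:

    * block ``shared``  -- driven by one latent factor in both matrices
      (sign flipped in the methylation matrix by ``shared_sign``);
    * block ``expr_only`` -- a factor only in the expression matrix;
    * block ``meth_only`` -- a factor only in the methylation matrix;
    * remaining variables are i.i.d. noise in both.

    ``truth`` maps variable -> block label.
    """
    rng = np.random.default_rng([int(seed), 97])
    blocks = [("shared", block_size), ("expr_only", block_size - 10), ("meth_only", block_size - 10)]
    n_var = sum(b for _, b in blocks) + n_noise
    var_ids = [f"t{i:04d}" for i in range(n_var)]
    labels = []
    for name, size in blocks:
        labels += [name] * size
    labels += ["noise"] * n_noise

    f = rng.normal(size=(3, n_samples))  # latent factors
    expr = rng.normal(size=(n_var, n_samples))
    meth = rng.normal(size=(n_var, n_samples))
    i = 0
    for b, (name, size) in enumerate(blocks):
        sl = slice(i, i + size)
        # hub structure: per-variable loadings, shared between data sets for
        # the shared block so intramodular connectivity is preserved too;
        # the range keeps every pairwise dissimilarity below the default
        # static cut (1 - (lam_i*lam_j)^beta < 0.75 needs lam ~ >= 0.88)
        lam = rng.uniform(loading - 0.10, loading, size=(size, 1))
        sq = np.sqrt(1.0 - lam**2)
        if name in ("shared", "expr_only"):
            expr[sl] = lam * f[b] + sq * rng.normal(size=(size, n_samples))
        if name == "shared":
            meth[sl] = shared_sign * lam * f[b] + sq * rng.normal(size=(size, n_samples))
        if name == "meth_only":
            meth[sl] = lam * f[b] + sq * rng.normal(size=(size, n_samples))
        i += size

    cols = [f"case_{j + 1:02d}" for j in range(n_samples)]
    meth_df = pd.DataFrame(meth, index=var_ids, columns=cols)
    expr_df = pd.DataFrame(expr, index=var_ids, columns=cols)
    truth = pd.Series(labels, index=var_ids, name="block")
    return meth_df, expr_df, truth
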