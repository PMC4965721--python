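# conmeth

Consistent differentially-methylated-region (C-DMR) discovery and
characterisation for case/control bisulfite methylation cohorts.

Tumour methylomes drift relative to normal tissue, but most per-sample
differences are private noise: a region that is hypo- or hypermethylated
in one patient is often unchanged in the next. The scientifically
interesting regions are the *consistent* ones — tiles of the genome
called in the same direction in nearly every patient against every
control. `conmeth` implements that discovery chain for reduced
representation bisulfite sequencing (RRBS) cohorts of roughly 30 cases
and a few controls, together with the downstream characterisation:
where the consistent changes fall in the genome, how heterogeneous they
are across patients, and how they couple to gene expression.

## What it computes

**Tiling and per-pair DMR calls.** Per-CpG methylated/total read counts
are pooled on fixed 1000-bp tiles (step 1000 bp); a CpG contributes only
with ≥ 10 reads, a tile only with ≥ 3 contributing CpGs. Each case
sample is tested against each control with a two-sided Fisher exact test
on the pooled 2×2 count table, Benjamini–Hochberg corrected within each
(case, control) batch; a tile is a DMR for that pair when *q* < 0.01 and
the methylation difference exceeds 25 percentage points.

**Consistency (the C-DMR test).** For each control batch, restricted to
the tiles retained in every comparison, the number of case samples
calling a tile in one direction is tested against the genome-wide
per-sample call rate p₀ with a one-sided binomial tail,

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ k), X ~ Binomial(N, p₀), tested only when k ≥ 25 of N = 30,

BH-corrected (q < 0.01) and intersected across all control batches.
Two permutation tests validate the surviving set: re-assigning
case/control labels among all samples, and shuffling each case sample's
calls across regions; both use add-one empirical p-values on the
statistic min-over-batches of the consistent-sample count, with q < 0.05
required.

**Methylation entropy.** Per region, the Shannon entropy of the
cross-sample methylation vector, H = −Σ p_s log₂ p_s with
p_s = m_s / Σ m_s, quantifies how evenly a region's methylation is
spread over patients; its correlation with the mean absolute
methylation change is reported per control batch.

**Annotation.** Regions are labelled (≥ 1-bp overlap, non-exclusive) by
promoter (−2 kb..TSS), 5′UTR/exon/intron/3′UTR of the longest isoform,
CpG island / shore (± 2 kb) / repeat / enhancer tracks, with a 1-df
chi-square co-localisation test against a background region set.

**Expression coupling.** Transcripts are stratified into expression
quartiles; methylation is profiled over percentile-scaled metagene
axes with LOESS smoothing, and per-genic-class mean methylation is
correlated (Pearson) with mean expression across transcripts.

**Correlation modules.** Differential expression and differential
3′UTR-methylation matrices (each case vs one common control) are
clustered into modules via an unsigned weighted correlation network
(|cor|^β adjacency, average-linkage, static cut), compared by
cross-tabulation (hypergeometric overlap p), module-eigengene
correlation, and permutation preservation statistics Z_density,
Z_connectivity and Z_summary (mean of the two; > 10 strong evidence,
2–10 weak-to-moderate, < 2 none) plus a permutation-free medianRank.

Because every stage needs ground truth to be testable, the package
ships a first-class synthetic cohort generator: a toy genome of
1000-bp tiles with genes (promoter/UTR/exon/intron structure), CpG
islands, repeats and enhancers; per-CpG counts drawn from an
overdispersed depth model with planted consistent, sporadic and null
regions; and a matched expression table with region-class-specific
methylation–expression coupling. The truth table records every tile's
class, effect and carrier samples.

## Worked example

```python
from conmeth.sim import standard_config, simulate_cohort
from conmeth.dmr import aggregate_tiles
from conmeth.consistency import call_cdmrs
from conmeth.entropy import entropy_table, entropy_change_correlation

cfg = standard_config(seed=101)          # 30 cases + 3 controls, 1000 tiles
fx = simulate_cohort(cfg)
tiles = aggregate_tiles(fx.coverage)     # 1000-bp tiles, >=3 CpGs at >=10x
res = call_cdmrs(tiles, cfg.case_ids, cfg.control_ids, n_perm=100, seed=1)

print("hyper C-DMRs:", len(res.cdmrs("hyper")))
print("hypo  C-DMRs:", len(res.cdmrs("hypo")))
ctrl = cfg.control_ids[0]
tbl = entropy_table(tiles, cfg.case_ids, ctrl, res.batches[ctrl].common_regions)
r, p = entropy_change_correlation(tbl)
print(f"entropy vs |change| ({ctrl}): r = {r:.2f}, p = {p:.1e}")
```

prints

```
hyper C-DMRs: 50
hypo  C-DMRs: 50
entropy vs |change| (control_01): r = -0.32, p = 1.2e-25
```

The generator planted 50 hyper- and 50 hypo-consistent regions
(40-point effects carried by 28 of 30 cases) among 100 sporadic and 800
null tiles; the pipeline recovers exactly the planted consistent set,
and regions with larger average methylation change are less
heterogeneous across patients (negative entropy correlation).

The same stages are available from the shell:

```bash
conmeth simulate --config sim.yaml --out fixture/
conmeth dmr     --fixture fixture/ --out out/ --tiles 1000 --min-cpgs 3 --min-depth 10
conmeth cdmr    --fixture fixture/ --out out/ --k-min 25 --perm 100 --seed 1
conmeth run     --config run.yaml --out out/        # full pipeline + manifest
```

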