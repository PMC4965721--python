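# Methods

This note records the statistical procedures, the synthetic-data model,
the parameter defaults and the open design choices behind `conmeth`.

## DMR calling on fixed tiles

Methylation is summarised on genome-anchored, non-overlapping 1000-bp
tiles (`[k·1000, (k+1)·1000)` per chromosome). Within a sample, a CpG
contributes to its tile only if covered by ≥ `min_depth` (default 10)
reads, and the tile is retained only with ≥ `min_cpgs` (default 3)
contributing CpGs; retained tiles carry pooled methylated/total counts
and their ratio as the methylation level.

Each case sample is compared with each control on the pooled 2×2 table
`[[meth_case, unmeth_case], [meth_ctrl, unmeth_ctrl]]` using the
two-sided Fisher exact test under the minimum-likelihood definition
(the p-value sums all hypergeometric outcomes whose point probability
does not exceed the observed one, with a 1e-7 relative slack absorbing
floating-point ties — the same convention as scipy). The
implementation enumerates the hypergeometric support through a cached
log-factorial table so that the ~5·10⁵ tables of a full cohort run
(and of the sample-permutation null) evaluate in seconds; it agrees
with exact rational enumeration to < 1e-10.

Benjamini–Hochberg adjustment is applied within each (case, control)
comparison batch, because each pairwise comparison is an independent
test family. A tile is called hyper/hypo for a pair when q <
`dmr_q` (default 0.01) **and** |level difference| ≥ `diff_thresh`
percentage points (default 25, configurable down to 0). The q
threshold is the published operating point; the 25-point difference
floor is the convention of tiling-based DMR frameworks and is exposed
because the source analysis does not state whether one was applied —
treat it as an assumption.

The *common-region set* of a control batch contains the tiles retained
in the control and in every case sample, so cross-sample statistics
always compare the same regions.

## Consistency: the C-DMR test

Within one control batch, let k be the number of case samples calling
a region in one direction among N cases. The null call probability p₀
defaults to the empirical genome-wide rate: total directional calls
divided by (regions × samples), clipped to [1e-6, 1−1e-6]. This makes
"significant consistency" mean "more consistent than the genome-wide
background of that direction"; a fixed p₀ (e.g. 0.5) can be configured
instead. Regions with k ≥ `k_min` (default 25 of 30) are tested with
the one-sided upper binomial tail P(X ≥ k), BH-corrected over tested
regions; regions below `k_min` are not tested. A region is a
*candidate* C-DMR when significant (q < 0.01) in the same direction in
**every** control batch; the binomial filter is applied per batch
first and the lists are then intersected.

### Permutation validation

Two permutation tests guard the candidate set, both with the add-one
empirical p-value (1 + #{T_perm ≥ T_obs}) / (1 + n_perm), n_perm
default 100:

* **Sample permutation** re-assigns the control labels uniformly among
  *all* samples (preserving group sizes) and recomputes the
  consistency counts. Because permuted batches no longer correspond to
  the original controls, the per-region statistic is
  T = min over control batches of the consistent-sample count,
  computed identically for the observed and permuted labelings. All
  pairwise Fisher calls among the full sample set are precomputed once
  (p is symmetric under role swap, the difference antisymmetric, and
  the BH batch is the pair's shared-region set), so each permutation
  is a table lookup.
* **Region permutation** shuffles, independently within each case
  sample (and per batch), the directional calls across the common
  regions, then recomputes T.

Empirical p-values are BH-adjusted **across candidate regions** per
direction, not across the whole region universe: with n_perm = 100 the
smallest attainable p is 1/101, and adjusting over all R regions would
bound every q below by (1/101)·R/#candidates, mechanically pushing q
past 0.05 whenever candidates are sparse — the flag would measure the
universe size, not the evidence. A region is a C-DMR when it is a
candidate and both permutation q-values are < `perm_q` (default 0.05).

The whole chain is antisymmetric by construction: replacing every
methylation count m by (total − m) swaps the hyper and hypo C-DMR sets
exactly (the tests verify this).

## Methylation entropy

For region r with non-negative vector m over the N case samples,
H = −Σ p_s log₂ p_s with p_s = m_s/Σ m_s (0·log 0 = 0); H ∈ [0, log₂ N]
and is undefined (missing) when Σ m = 0. Entropy is scale- and
permutation-invariant and maximal exactly for constant vectors.

Two inputs are supported. The default uses the per-sample methylation
**levels** (the formula's literal definition); the `diff` option uses
|case − control| differences. The choice matters: on cohorts where
large consistent effects coexist with small-subset sporadic effects,
the |difference| vector of a consistent region is nearly uniform
(maximal entropy), so entropy *rises* with mean |change| and the
correlation comes out positive; the level vectors instead become more
concentrated as a shared effect pulls carriers away from the
non-carriers and controls, reproducing the expected negative
entropy-vs-|mean change| relationship in every control batch. The
level input is therefore the default; both are computed per control
batch over that batch's common regions, with a two-sided Pearson test.

## Genomic-context annotation

One reference isoform per gene: the longest span (txEnd − txStart),
ties broken by lexicographically smallest transcript id. Promoters are
[TSS − 2 kb, TSS) on the plus strand and the mirrored interval
downstream of txEnd on the minus strand. Introns are the gene span
minus the reference isoform's exons; UTRs are exon portions outside
the CDS, oriented by strand. All coordinates are 0-based half-open.

Region labels use the ≥ 1-bp overlap rule and are non-exclusive
(reported percentages may sum past 100%). `intergenic` = no gene-body
or promoter overlap; `shore` = within 2 kb of a CpG island without
overlapping one, inclusive at exactly 2 kb in half-open gap
arithmetic; `non_repeat` complements the repeat track. The
co-localisation statistic is a 1-df chi-square without continuity
correction on [[query hit, miss], [background−query hit, miss]], BH
over tracks, falling back to the Fisher exact test (flagged) when any
expected cell is below 1. The default background is the common-region
tile set, configurable — the appropriate universe depends on how the
query set was ascertained.

## Expression in relation to methylation

Transcripts are quartiled (Q1 lowest … Q4 highest) by mean expression
across case samples, rank-based with stable transcript-id tie-breaks
and group sizes differing by ≤ 1 — invariant under monotone
transforms. Metagene profiles map CpGs onto a percentile-scaled unit
axis (40 body bins) with fixed 2-kb flanks (10 bins each side),
strand-reflected for minus-strand genes; boundary profiles use fixed
±200 bp at 10-bp bins around exon/intron 5′ boundaries. Per-bin means
are smoothed with LOESS (tri-cube local linear regression,
`statsmodels.lowess`, span 0.3); the bin means, not the smoother, are
the tested quantity, and a constant input yields a flat profile to
1e-6. The percentile x-axis is the default; absolute-bp flanks are the
only fixed-scale part, since scaled bodies plus fixed flanks is the
common convention for such figures.

Per-genic-class correlation pairs each transcript's mean CpG
methylation within the class (averaged over case samples, coverage
≥ 10) with its mean expression, via two-sided Pearson.

## Correlation modules

Differential matrices over the jointly observed transcripts: expression
log2((FPKM_case+1)/(FPKM_ctrl+1)) — the +1 pseudocount gives a ratio
scale robust at zero FPKM — and 3′UTR methylation as the
percentage-point difference of mean 3′UTR CpG levels, each case against
one common control.

Module detection is a deliberately simple unsigned weighted-network
variant: adjacency |cor|^β (β = 6), dissimilarity 1 − a, average-linkage
hierarchical clustering, static cut at 0.75, clusters < 30 pooled into
the grey set, labels size-ranked with conventional colour aliases. The
full framework's topological-overlap transform and dynamic tree cut are
intentionally omitted — the comparison machinery, not the clustering
flavour, is the analysis target here. Eigengenes are the first right
singular vector of the row-standardised member matrix (unit norm, sign
anchored to positive mean member correlation), making them invariant to
member scaling.

Module comparison: (i) hypergeometric upper-tail overlap p per module
pair, BH across pairs; (ii) all-pairs eigengene Pearson correlations;
(iii) preservation statistics with reference modules re-measured in the
test matrix — density (mean off-diagonal adjacency among members) and
connectivity (Pearson correlation of members' intramodular connectivity
between reference and test) — against a null of n_perm random
same-size variable sets; Z = (obs − mean)/sd per statistic and
Z_summary their mean, read against the conventional bands (< 2 none,
2–10 weak/moderate, > 10 strong). The two-component mean is an explicit
simplification of the larger composite used by the reference
implementation of network preservation. medianRank is computed from
observed statistics only (rank 1 = strongest), without permutation.
Degenerate permutation spreads (sd = 0) yield missing Z with a warning.

## The synthetic cohort generator

The generator emulates the *shape* of an RRBS case/control study — 30
case and 3 control samples by default — not any real genome.

* **Genome**: chromosomes tiled at 1000 bp (the layout is tile-aligned
  and asserts tile_size = 1000). Genes occupy 7 tiles (promoter ×2,
  5′UTR exon, intron, coding exon, intron, 3′UTR exon; mirrored on the
  minus strand, every third gene) in 10-tile units, so each tile has
  one designed context. CpG islands span the promoter/5′UTR boundary
  of every gene; repeats and enhancers occupy a deterministic subset
  of spacer and intron tiles. 3–8 CpGs per tile at random positions,
  shared across samples (RRBS sites are shared by design).
* **Counts**: read depth = 10 + NegBin(mean − 10, dispersion 5), mean
  50 — overdispersed, with minimum achievable depth exactly at the
  coverage filter so the filter is live but the common-region set
  stays complete; methylated reads ~ Binomial(total, θ).
* **Effects**: θ = baseline(context) + effect for carrier case samples
  (effects act on the latent probability, keeping the binomial model
  coherent), plus N(0, 0.02) per-sample noise; controls get an
  analogous heterogeneity term (default 0.02) rather than being
  identical, since real controls vary. Baselines: 0.15 at
  promoters/5′UTRs, 0.40 in coding exons, 0.75 in introns/3′UTRs/
  intergenic space — the usual somatic pattern, leaving 40-point
  effects representable in both directions without clamping (out-of-
  range combinations are clamped with a warning).
* **Standard cohort** (`standard_config`): 1000 tiles; 50 hyper- and
  50 hypo-consistent regions (±40 points, 28/30 carriers; hyper placed
  in promoter/5′UTR i.e. CpG-island-biased contexts, hypo in
  intron/3′UTR/intergenic), 50+50 sporadic (10/30 carriers), rest
  null. Truth is recorded at tile resolution — the pipeline's unit.
* **Expression**: log expression = base + Σ_class coupling·(mean θ
  deviation of the gene's class tiles) + N(0, 0.3), exponentiated so
  values are positive FPKM-like numbers. Default coupling: promoter
  and 5′UTR −1.5, exon −1.0, intron 0, 3′UTR +1.0 — negative upstream
  coupling, weak positive 3′UTR coupling.
* **Coupling cohort** (`coupling_config`): 500 genes whose 5′UTR tile
  carries a hyper effect and 3′UTR tile a hypo effect with per-gene
  magnitudes uniform on [0, 50] points, all cases as carriers, so
  per-transcript methylation varies. The between-transcript base-
  abundance sd is halved (0.5) here so the deliberately weak positive
  3′UTR coupling remains detectable at a few hundred transcripts —
  with the cohort-wide sd of 1.0 the weak signal sits at the edge of
  detectability, which would make a sign test flaky rather than
  informative.
* **Module matrices** (`simulate_comodule_matrices`): 200 variables ×
  30 samples, one latent factor shared between the expression and
  methylation matrices (sign-flipped in methylation), one factor per
  matrix alone, the rest noise. Per-variable loadings uniform on
  [0.88, 0.98] give hub structure (so connectivity preservation is a
  real signal) while keeping every within-block dissimilarity under
  the 0.75 static cut.

All randomness flows through named substreams `default_rng([seed, k])`
consumed in a fixed order (genome, carriers, θ noise, read counts,
expression), so a config is bit-reproducible; fixtures serialise to
plain TSV/BED and round-trip through the package's readers.

### What the generator does not emulate

Read-level artefacts (no FASTQ, no bisulfite-conversion error, no
mapping bias), SNP-confounded methylation, spatial correlation of CpGs
beyond tile-level effects, realistic gene-length/isoform diversity,
copy-number effects on expression, and batch structure. Passing tests
therefore demonstrate that the *statistical machinery* behaves as
specified under a faithful sampling model — not that any particular
biological cohort would yield the same numbers; quantities like the
C-DMR counts or correlation magnitudes of real published cohorts are
properties of their data and are not targets here.

## Numerical and scale choices

* Benchmark sizes are chosen so the full suite and the reproduction
  script each run in minutes on one core: 1000-tile standard cohort,
  ten 500-tile null cohorts, 500-transcript coupling cohort, 100
  permutations throughout. All scale up by config.
* Empirical permutation p-values use the add-one estimator; n_perm <
  19 is rejected (cannot resolve p < 0.05).
* BH is the hand-vectorised step-up (sorted cumulative minimum),
  validated against statsmodels on random vectors.
* Fisher p-values clip to [0, 1]; two-sided tie slack 1e-7 relative.
* Degenerate inputs: zero-total tiles are excluded from testing; zero
  entropy vectors are missing; zero-variance correlations are missing;
  constant variables are dropped (with warning) before clustering.

## Known limitations

* The binomial consistency test treats case samples as exchangeable
  Bernoulli trials; clinical covariates or subtype structure are out
  of scope.
* The sample-permutation scheme (joint re-assignment of all control
  labels, min-over-batches statistic) is one reasonable reading of a
  one-sentence description; other schemes (per-batch pairing) would
  give slightly different empirical p-values.
* Module detection is intentionally minimal; module counts/sizes from
  the full weighted-network framework on real data are not comparable.
* With ~100 permutations the smallest empirical p is ~0.01; claims at
  much smaller FDR need proportionally more permutations.
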