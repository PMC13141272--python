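# Methods

This note documents the models, the numerical decisions, and what the
synthetic validation does and does not establish.

## Spike-in normalisation model

Foreign chromatin is assumed to be added at a fixed fraction *s* of total
input chromatin (default 0.05) before immunoprecipitation, and the foreign
genome's content of the target mark is assumed constant across genotypes.
If a genotype retains a fraction *f* of its target-mark chromatin, the
expected foreign share of sequenced reads is

    p_spike(f) = s / (s + f·(1 − s)),

so a depleted sample sequences proportionally more foreign reads at equal
depth (f = 0.5 at s = 0.05 gives a ≈ 1.9× spike-read gain). Scaling factors
follow the min-ratio convention within each antibody (mark) group:
`factor_i = min_j(spike_j) / spike_i`, so the sample with the fewest spike
reads is the reference (factor 1) and every factor lies in (0, 1]. Factors
are never compared across antibodies, since IP efficiency is
antibody-specific.

Factors are applied by **binomial thinning** of the integer counts rather
than deterministic rounding, preserving count statistics; thinning is
seeded and reproducible. After thinning, tracks are scaled to counts per
million using **one shared denominator per group** — the reference sample's
downsampled total. This is deliberate: a per-sample CPM denominator would
cancel the downsampling factor exactly (value·f·10⁶ / (f·total) =
value·10⁶ / total) and reduce the whole procedure to plain CPM, which is
blind to global differences. The shared scale keeps cross-sample ratios
equal to downsampled-count ratios while producing values on the familiar
CPM magnitude. Plain per-sample CPM remains available (`cpm_normalise`) and
serves as the negative control in the recovery experiment.

Under this model the normalised mutant/wild-type signal ratio equals the
true retention *f* independently of sequencing depth — the recovery
experiment plants d ∈ {0.1, 0.5} with a 2× depth imbalance and recovers it
to three decimals in expectation, while the CPM control's estimate is pulled
toward 1 by composition (how far depends on the signal-to-background share
of the library).

## Synthetic data

The generator is deliberately structural, not read-level: no FASTQ, no
fragment-length or GC model, no alignment noise.

* **Genome**: six 1-Mb chromosomes (I–V, X) by default; large enough for
  ±5 kb windows, small enough for sub-second stages. Tests use 300-kb
  chromosomes where window size permits.
* **Features**: TSS anchors (stranded, single-base) and 400-bp enhancer
  intervals placed without replacement on a 2-kb grid, ≥ 6 kb from
  chromosome ends. The enhancer width is a configuration knob; the upstream
  annotation's widths are not modelled.
* **Coverage**: per-bin intensity λ = background (1 unit) + Gaussian-kernel
  feature shapes; reads are Poisson with mean depth·λ/Σλ, i.e. sequencing is
  a composition sampler — which is exactly why plain CPM fails on global
  depletion. Shapes: me3 forms a double peak flanking the TSS (downstream
  peak 1.3× higher, giving strand-reversal something to detect); me2 a broad
  promoter dome; me1 a valley at the TSS with flanking enrichment and a
  strong central enhancer peak. Amplitudes put most reads into features
  (signal share ≈ 0.85–0.9 for wild-type me3), emulating an efficient IP.
* **Planted gene classes**: each TSS carries a persistent lognormal strength
  (sd 0.3 on the log scale) and a binary me3 class (half the genes me3-low
  at 0.1× me3, 0.6× me2 and 1.2× me1). The High/Low clustering stage
  recovers these classes at ≈ 98 % agreement — a ground-truth check that a
  separable-matrix unit test cannot provide.
* **Genotype effects** are multiplicative per (genotype, mark, feature
  class). Defaults: the rbbp-5-like genotype retains 5 % of every mark
  (near-complete loss); the wdr-5-like genotype loses me3 (0.25×), loses me2
  at TSS (0.5×) while gaining it at enhancers (1.6×), and gains me1
  (1.5×/1.3×).
* **DEG tables**: designated up/down genes receive |log₂FC| = 1 + |N(1,
  0.5)| and padj < 0.05 by construction; null genes log₂FC ~ N(0, 0.15) and
  padj uniform on (0.05, 1]. Per-condition means are exactly consistent
  (baseMeanB = baseMeanA·2^log₂FC, baseMean their mean). Default fractions
  follow the study structure: 11 % up, 5.5 % down, with down genes drawn one
  natural-log unit higher in baseMean — the configuration under which a
  mostly-up transcriptome still shows a negative net change. The
  rbbp-5-like fixture table uses 3.3 % up / 0.3 % down with a 2.5-log-unit
  down shift, reproducing the strong up-bias with a mildly negative net. The
  double-mutant table is derived from the single-mutant one: a seeded 20 %
  of its DEG revert to null behaviour ("restored"), a seeded 5 % of null
  genes become DEG, and wild-type means stay shared between contrasts.
* **Randomness**: every stage draws from a named stream
  (`SeedSequence(master, spawn_key=crc32(name))`), so adding or reordering
  stages never perturbs another stage's draws, and fixtures are
  byte-identical for a given configuration.

What passing on these data does **not** show: robustness to GC or
mappability artefacts, fragment-size effects, antibody cross-reactivity,
replicate structure in the DEG tables (the generator emits one table per
contrast, not per-replicate counts), or the behaviour of MACS2/DESeq2
themselves — their outputs are consumed, not modelled.

## Peak classification

BroadPeak column 9 stores −log₁₀(q); the q ≤ 0.005 filter is applied as
column ≥ 2.30103, and all filter boundaries are inclusive. Promoter windows
are half-open [p − 1000, p + 1000) per TSS and merged where overlapping
before overlap queries (membership is unaffected; merging avoids double
counting). The four-category classification is any-overlap based; the
six-feature annotation uses the **peak midpoint** with a fixed precedence
ladder (promoter-TSS > TTS > UTR exon > CDS > intron > intergenic) — the
upstream annotation tooling implies a precedence without printing one, so it
is an explicit, configurable decision here. The TTS feature is a ± 200 bp
window around the termination site (no width is given upstream; also
configurable). Peaks on chromosomes absent from the feature sets are
classified `Other`, not rejected. Strata (genotype, mark) never mix.

## Profiles

Matrix bins are anchored at the region (not the genome grid); where a
region bin straddles track bins the overlap-weighted mean is used, computed
exactly via per-chromosome prefix sums. Out-of-bounds bins are missing
(NaN), never zero — zero-filling would drag down edge profiles. Minus-strand
rows are reversed so downstream is always right. Clustering operates on the
raw binned vectors because the High/Low split is a split by *level*; a
row-mean mode exists for the cheaper variant. Missing cells are imputed with
the row mean before clustering. k-means uses 10 restarts and a fixed seed;
the cluster with the larger mean row-sum is labelled High. If all rows are
identical there is no second cluster: everything is labelled Low and the
result carries a degenerate flag.

## Chromosome statistics

"Size-weighted" goodness of fit means expected counts proportional to
chromosome length: E_i = N·L_i/ΣL, statistic Σ(O_i − E_i)²/E_i on
df = n − 1. The test assumes counts; real-valued (e.g. RPGC) totals must be
converted via the `value_scale` argument (totals are divided by it), and
the conversion choice is the caller's. The chrX/autosome ratio is
log₂(mean_X / length-weighted autosome mean). Calibration on the toy
genome: empirical type-I error 0.037 at α = 0.05 over 2000 uniform
multinomial draws of 100k counts.

## Transcriptome metrics

"Fold change > 2" is strict |log₂FC| > 1 and "adjusted p < 0.05" strict —
boundary genes are excluded, matching the reporting convention of
DESeq2-style tables. The expression floor of 50 uses the per-condition
normalised means with **or** semantics (baseMeanA ≥ 50 OR baseMeanB ≥ 50)
for DEG calling; the Cook's-distance analysis uses **and** semantics
(> 50 in both conditions) per its own definition. Genes with missing padj
are unchanged, never dropped.

The net change percent is a baseMean-weighted mean of DEG log₂FC times 100:
invariant to gene order and to rescaling all baseMeans, not bounded by
±100, and undefined (an error) when there are no DEG.

The rank test on wild-type baseline expression uses log₂(baseMeanA + 1);
the pseudocount admits zeros and cannot affect the test, which is invariant
under monotone transforms. Exact p-values are computed by enumerating the
permutation null of U conditional on the observed values (ties handled
exactly) whenever both groups have ≤ 8 observations — the within-subset
pair-sum identity reduces each subset's U to a score sum, which makes full
enumeration cheap — and by the tie-corrected normal approximation
otherwise. The two-sided exact p is twice the smaller tail, capped at 1.

Chromosome enrichment uses Wilson 95 % intervals for the observed DEG
proportion (mapped to the log₂ obs/exp scale), exact two-sided binomial
p-values, and Benjamini–Hochberg FDR across the chromosomes within one
direction; the flag requires both FDR ≤ 0.01 and |log₂ obs/exp| ≥ log₂ 1.2.
Wilson, the central binomial test and BH are explicit choices — the
procedure this reimplements names only "FDR" and "95 % CI". Venn overlap
significance is the upper-tail hypergeometric probability on the shared
universe, again a declared choice. Because per-contrast expression filters
can admit slightly different universes, `harmonize_universe` intersects
calls before any set comparison; the set operations themselves refuse
mismatched universes.

ΔΔCT: ΔCt = mean Ct(target) − mean Ct(reference) per condition, ΔΔCt
relative to the control condition, fold = 2^(−ΔΔCt); replicate SEMs combine
in quadrature and are reported as a fold interval (2^(−ΔΔCt ± SEM)).

## Problem sizes

The validation studies run at: 300-kb × 6 chromosomes with 60 TSS / 30
enhancers and 1–2 M reads per sample for the spike recovery (20 seeds per
depletion level); 100 simulated DEG tables of 5000 genes for the
directionality check; 2000 multinomial draws for χ² calibration; 200
simulations each for the enrichment null and power studies; and the full
1-Mb toy genome with 200 TSS / 100 enhancers for the end-to-end study.

## Known limitations

* The spike composition model ignores nonspecific (background) chromatin in
  the IP pool; the effective retention passed to the spike simulator is the
  ratio of total IP intensity, which keeps the generator and the
  normalisation contract exactly consistent but idealises real IP
  chemistry.
* bigWig is not read or written; bedGraph is the interchange format.
* The χ² uniformity test on real-valued coverage depends on an honest
  count-scale conversion supplied by the caller.
* Cook's distances are consumed, never computed; there is no model of the
  underlying GLM.
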