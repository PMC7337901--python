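# Methods

## Coordinate and naming conventions

All intervals are 0-based half-open (BED convention); GTF input (1-based,
closed) is converted on read and back on write, nowhere else. Chromosome
names are normalised by stripping an optional `chr` prefix so UCSC- and
ENSEMBL-style inputs can be mixed. Overlap operations are strand-specific
wherever the biology is stranded (CLIP clusters vs transcript features);
the conservation track is unstranded.

## Differential expression

The engine is a deliberately compact DESeq2-style NB pipeline:

- **Size factors**: median of ratios to the per-gene geometric mean, over
  genes expressed in every sample. Factors are identified only up to a
  common constant; that constant is absorbed by the GLM intercept.
- **Dispersion** (α in Var = μ + αμ²): per-gene method of moments on
  normalized counts within design groups (dataset × genotype), pooled by
  residual degrees of freedom, then shrunk 50/50 toward a mean–dispersion
  trend a/μ + b fit by least squares. Floored at 1e-8; all-zero genes sit
  at the floor. This replaces Cox–Reid adjusted profile likelihood and
  empirical-Bayes shrinkage: at the simulated group sizes the moment
  estimator plus trend shrinkage is adequate and fully testable.
- **Per-gene GLM**: NB log-link with offset log(size factor), design
  `1 + genotype` (per-dataset) or `1 + genotype + dataset` (joint),
  fitted by IRLS (statsmodels GLM; tolerance 1e-8, 100 iterations).
  Genotype is coded WT vs non-WT within one arm; heterozygotes and
  homozygotes are analysed as separate comparisons. With a single dataset
  the joint design reduces exactly to the per-dataset one.
- **Inference**: Wald statistic on the genotype coefficient referred to a
  *t* distribution with residual degrees of freedom. The usual normal
  reference is anti-conservative at these sample sizes (9–18 per group
  across three datasets): in global-null simulations it rejects at
  0.057–0.067 instead of 0.05, while the t reference stays at 0.04–0.05.
  BH adjustment runs across genes; non-converged genes are reported NA and
  excluded from the adjustment.
- **No fold-change shrinkage**: estimates are plain MLEs. A normal-prior
  ridge variant could be slotted in at the IRLS weights, but recovery on
  synthetic data is assessed against unbiased estimates, where shrinkage
  would only add a calibration step.

Genes with zero counts across all samples of any design group are removed
before fitting (GLM stability); the threshold is configurable.

## Differential splicing usage

Events are inclusion/exclusion count pairs with a junction descriptor and
the encompassing intron's coordinates. PSI is inclusion / total, NA when
the total is zero, flagged low-coverage below 10 reads (configurable; the
event is excluded from testing only if *every* sample is below the
threshold).

The usage test models inclusion given total on the logit scale with
design `1 + genotype [+ dataset]`. Overdispersion is assessed per event
from the Pearson statistic of the binomial fit; the beta-binomial
likelihood (intra-class correlation ρ from the variance-inflation moment
estimate, ρ = (φ−1)/(m̄−1)) is used only when the lack of fit is
significant at 5%, otherwise the binomial likelihood stands. Fitting
noise-level overdispersion unconditionally deflates the
likelihood-ratio statistic — in 1,000-event null simulations it pushed
the rejection rate to 0.028 at nominal 0.05, while the pre-tested switch
restores ~0.05. The genotype effect is tested by likelihood ratio
against χ²(1); `log2_usage_fc` is the genotype log-odds coefficient / ln 2.

Event classification is a total function of the descriptor: retained
intron (inclusion form is the unspliced single donor–acceptor pair),
cassette exon (two inclusion junctions sharing outer coordinates with one
exclusion junction), alt 5'/3' (single alternative donor/acceptor),
complex (more than one elementary alternative, including the
both-sites-differ case), other (degenerate descriptors). Cryptic/skiptic
cassette exons use mean group PSI with defaults low = 0.05, high = 0.95,
minimum gain 0.10; these thresholds are conventions of the earlier
TDP-43 splicing literature and are configurable since the precise
original cutoffs are not restated here.

## Arm comparison and attenuation

Overlap labels: strict sharing needs FDR < α in both joint models;
relaxed-only sharing FDR < α in exactly one and raw p < α in the other;
arm-specific features are significant on one side with raw p ≥ α on the
other. Ties at exactly FDR = α are non-significant. The regression set is
strict ∪ relaxed.

The attenuation fit is OLS of NLS effects on KO effects *with intercept*:
a near-zero fitted intercept is itself a check that the mutant arm is a
scaled copy of the knockout arm, and the through-origin slope is reported
alongside for transparency. The dose-response fit is identical with
heterozygote effects on homozygote effects. Direction concordance counts
sign disagreements among shared features; exact zeros count as
concordant. Set intersections use the two-sided Fisher exact test.

## Enrichment with matched nulls

CLIP-cluster overlap scales with region length and transcript abundance,
so every test set is compared against a null set with no evidence of
change (raw p > 0.05 in both joint models) whose length and expression
fall within the closed [Q1, Q3] bounds of the test set. Gene expression
is the mean size-factor-normalized wild-type count; for splice events it
is the mean normalized total (inclusion + exclusion) in control samples
— which control samples define expression is a parameter, since multi-
dataset designs leave the choice open. Proportions (cluster overlap;
median phyloP strictly > 0.5) are compared with the two-proportion χ²
without continuity correction (a Yates variant is available by flag);
families of tests are Bonferroni corrected. Region medians are computed
over scored bases only — unscored bases are missing, not zero, since
zero-filling would bias sparse tracks toward neutrality.

The feature partition per gene: CDS from the union of coding transcripts;
UTR exonic sequence split into 5'/3' by overlap with annotated polyA
sites when provided, else by position relative to the CDS; introns are
transcript gaps; the 3'UTR is extended exactly 5 kb downstream (clamped
at contig ends) and the promoter-antisense region flanks the 5' end by
5 kb with the strand inverted. On collisions across transcripts the
precedence is CDS > UTR > intron. Genes with no coding transcript are
skipped with a warning because the UTR split is undefined.

## The simulator

The generator emulates the statistical structure the joint analysis
assumes — it is the oracle for every recovery and calibration test:

- Three datasets (`fratta`, `dupuis`, `bozzoni`), each with KO and NLS
  arms vs wild-type controls; 3 samples per group by default, matching
  small animal-model designs. Heterozygotes (half the homozygote log2
  effect, additive on the log scale — the simplest testable dose model)
  exist in the `fratta` dataset only, mirroring designs where only one
  lab sequenced heterozygotes.
- Gene counts: NB(μ = sizefactor · baseline · 2^(effect·dose), α = 0.05)
  with baselines log-normal(5, 1.5) (median ≈ 150 counts) and per-sample
  size factors log-uniform in [0.5, 2] — drawn per sample, not per
  dataset, so normalisation is genuinely exercised. 10% of genes are
  shared-DE with NLS effect exactly 0.76 × the KO effect, 5% KO-specific,
  1% NLS-specific (KO-specific ≫ NLS-specific, as observed in this class
  of experiments); true KO effects are N(0, 1) on the log2 scale.
- Splice events: totals Poisson(depth 100 × size factor), inclusion
  binomial with logit(PSI) = logit(base) + shift·dose; base PSI uniform
  in [0.3, 0.7]. 10% of events are regulated retained introns with logit
  shift ±2 (80% negative — retention predominantly drops when FUS is
  lost), NLS shift = 0.76 × KO shift on the logit scale. Unregulated
  events draw types at proportions retained_intron 0.30 / complex 0.30 /
  cassette 0.18 / alt5 0.15 / alt3 0.07 (intron retention and complex
  events dominate; alt5 at twice alt3).
- Annotation: one synthetic chromosome of three-exon genes (200 bp exons,
  400 bp introns, CDS mid-exon1 to mid-exon3) on alternating strands,
  spaced so 5 kb flanks never collide. This keeps interval logic simple
  while exercising strand handling; it does not attempt realistic gene
  architecture, sequence content, or overlapping loci.
- Tracks: each intron receives a cluster with probability 0.15,
  multiplied by 5 (capped at 0.95) over regulated introns; clusters
  inherit the host gene's strand. Conservation scores are N(0, 0.5) per
  tile (20 bp by default; per-base scores in adjacent tiles share a value,
  a compromise that keeps bedGraph output tractable without changing any
  median-based statistic's null), shifted +2 over regulated introns.

One `numpy` Generator seeded from the config drives everything; a fixed
seed reproduces the whole bundle byte-for-byte. What passing tests on
these bundles do *not* show: robustness to outlier samples, batch effects
beyond a dataset mean shift, correlated genes, length-biased coverage, or
mis-annotated events — none of which the generator produces.

## Problem sizes and numerical choices

Calibration suites run at 2,000 genes / 1,000 events under the global
null; recovery suites at 150–500 genes with three samples per group; the
end-to-end determinism check at 80 genes / 50 events. Enrichment-null
uniformity uses 500 track replicates over 800 regulated vs 800 matched
introns with background cluster probability 0.3 — counts large enough
that the χ² approximation holds and the discrete p-value lattice is fine
against a continuous-uniform reference; the detection-power check uses
the defaults (background 0.15, enrichment 5×, 100 regions per set, 100
bundles). Attenuation recovery averages 50 seeds at n = 1,300
(expression, ratio 0.76, R² = 0.90) and n = 405 (splicing, 0.7, 0.89),
and 100 seeds for the dose-response slopes (0.57 at n = 34, 0.67 at
n = 115, σ = 0.25), with noise variance set analytically from the target
R² via σ² = ratio²(1 − R²)/R².

Degenerate inputs: zero-total event/sample pairs are NA; all-NA groups
propagate NA; empty result tables write header-only files with a warning;
NaN serialises as `NA` and floats at 12 significant digits (lossless for
these statistics). GLM non-convergence or separation yields NA, counted
and logged, never a crash.

## Known limitations

- The NB engine omits Cook's-distance outlier handling, independent
  filtering and posterior fold-change shrinkage.
- The event-descriptor grammar is a simplification of read-level event
  discovery; events are consumed as given, never discovered from
  alignments.
- The beta-binomial LRT uses a plug-in ρ rather than profiling it; at the
  simulated depths this is immaterial, at very low depth it would
  understate uncertainty.
- Size-factor equivariance under rescaling one sample's counts is exact
  for the factors but only approximate for NB coefficients (IRLS weights
  depend on the absolute count scale).
- The bigWig conservation format is not parsed; bedGraph stands in.
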