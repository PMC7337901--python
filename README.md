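# lofsplice

Joint multi-dataset differential expression and splicing analysis for
loss-of-function studies of the RNA-binding protein FUS, with matched-null
CLIP-cluster and conservation enrichment over retained introns, and a
ground-truth simulator that makes every stage testable without external
downloads.

## The problem

ALS-causing FUS mutations cluster in the nuclear localization signal (NLS)
and reduce nuclear FUS. Knockin mouse and cellular models pair each NLS
mutant with a FUS knockout (KO), so the mutant's transcriptomic footprint
can be compared with genuine loss of function. With several such datasets,
per-dataset two-group tests are underpowered and discordant; the remedy is
a *joint model* per comparison arm: one regression over all samples of that
arm with a dataset covariate.

The package provides, for gene-level counts and splice-event
inclusion/exclusion counts:

- **Differential expression** — median-of-ratios size factors, per-gene
  method-of-moments NB dispersion shrunk toward a mean trend, and a
  per-gene NB GLM (log link, size-factor offset) with design
  `genotype [+ dataset]`, Wald test on genotype, BH FDR.
- **Differential splicing usage** — PSI = inclusion / (inclusion +
  exclusion); per-event beta-binomial regression on the logit scale
  (binomial when there is no evidence of overdispersion), likelihood-ratio
  test on genotype; event-type classification (retained intron, cassette
  exon, alt 5'/3' site, complex) from junction descriptors;
  cryptic/skiptic cassette-exon calling from group PSI.
- **Arm comparison** — strict (FDR < α in both models) and relaxed
  (FDR < α in one, raw p < α in the other) overlap labels, direction
  concordance, and the attenuation regression: OLS of NLS effects on KO
  effects, whose slope β < 1 quantifies a partial loss of function. The
  same machinery gives the heterozygote-on-homozygote dose-response slope
  and Fisher's exact test for the DE × DS gene-set intersection.
- **Enrichment** — genomic feature partition (5'UTR / CDS / intron / 3'UTR
  extended 5 kb / promoter-antisense with inverted strand), null features
  matched on length and expression to the test set's interquartile range,
  strand-specific CLIP-cluster overlap and median-phyloP (> 0.5)
  proportions compared with a two-proportion χ² test, Bonferroni corrected;
  cluster proximity flags (overlapping / within 1 kb / none).
- **Simulator** — three datasets × two arms with NB counts where the NLS
  effect is exactly `attenuation` × the KO effect for shared genes,
  heterozygotes carry half the homozygote log2 effect, regulated splice
  events are retained introns with logit-scale PSI shifts, and CLIP /
  conservation tracks are enriched over regulated introns. Fixed seed ⇒
  byte-identical bundles.

## Worked example

```python
from lofsplice.diffexpr import fit_de
from lofsplice.overlap import classify_overlap, direction_concordance, \
    fit_attenuation, shared_ids
from lofsplice.simulate import SimulationConfig, combine_datasets, simulate_counts

config = SimulationConfig(n_genes=500, samples_per_group=3, seed=4)
per_dataset, truth = simulate_counts(config)
counts, sheet = combine_datasets(per_dataset)

ko = fit_de(counts, sheet.select_comparison("KO", "HOM"), joint=True)
nls = fit_de(counts, sheet.select_comparison("NLS", "HOM"), joint=True)
labels = classify_overlap(ko, nls, alpha=0.05)
shared = shared_ids(labels)
fit = fit_attenuation(ko.set_index("gene_id").loc[shared, "log2fc"],
                      nls.set_index("gene_id").loc[shared, "log2fc"])
```

This prints (see `examples/04_overlap_attenuation.py`):

```
overlap labels: {'neither': 452, 'shared_strict': 21, 'ko_specific': 19,
                 'shared_relaxed_only': 5, 'nls_specific': 3}
shared genes: 26 (0 discordant in direction)
attenuation fit on 26 shared genes: beta = 0.738 (intercept -0.001, R^2 = 0.967)
```

The simulator generated NLS effects at exactly 0.76 × the KO effects for
shared genes; the fitted slope 0.738 recovers that ratio from noisy count
data, the near-zero intercept confirms no systematic offset, and zero
direction-discordant genes reflects the pure loss-of-function structure.
Each `examples/` script exercises one capability the same way
(simulation, expression, splicing, overlap, enrichment).

The full pipeline also runs from the shell:

```sh
lofsplice run-all --out-dir run1 --seed 4
lofsplice report --out-dir run1
```

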