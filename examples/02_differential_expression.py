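"""Joint negative-binomial differential expression across three datasets.

Simulates counts with known effects, fits the joint model (genotype +
dataset covariate) for the knockout arm, and compares the estimates with
the generative truth.  The correlation near 1 shows the joint GLM recovers
the true log2 fold changes; the significant-gene count reflects the 16% of
genes simulated as differentially expressed in the KO arm.
"""

import numpy as np

from lofsplice.diffexpr import fit_de
from lofsplice.simulate import SimulationConfig, combine_datasets, simulate_counts

config = SimulationConfig(n_genes=400, samples_per_group=3, seed=2)
per_dataset, truth = simulate_counts(config)
counts, sheet = combine_datasets(per_dataset)

results = fit_de(counts, sheet.select_comparison("KO", "HOM"), joint=True)

merged = results.set_index("gene_id").join(truth.genes.set_index("gene_id"))
ok = merged["log2fc"].notna()
r = np.corrcoef(merged.loc[ok, "log2fc"], merged.loc[ok, "ko_log2fc"])[0, 1]

n_sig = int((results["fdr"] < 0.05).sum())
print(f"genes tested: {len(results)}, significant at FDR < 0.05: {n_sig}")
print(f"correlation of estimated vs true log2FC: {r:.3f}")
print(results.sort_values("p").head(5)[["gene_id", "log2fc", "se", "p", "fdr"]]
      .to_string(index=False))
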