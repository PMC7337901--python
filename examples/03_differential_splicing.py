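"""PSI quantification and the joint differential splicing-usage test.

Simulated events carry genotype-dependent PSI shifts concentrated in
retained introns (10% of events by default).  The beta-binomial usage test
with a dataset covariate recovers them: essentially all regulated events
reach FDR < 0.05 and their fitted log-odds shifts match the generative
sign.
"""

import numpy as np

from lofsplice.simulate import SimulationConfig, simulate_counts, simulate_events
from lofsplice.splicing import compute_psi, fit_usage

config = SimulationConfig(n_genes=300, n_events=150, samples_per_group=3, seed=3)
_, truth = simulate_counts(config)
events = simulate_events(config, truth)["all"]

psi = compute_psi(events)
print(f"PSI values computed for {psi['event_id'].nunique()} events x "
      f"{psi['sample_id'].nunique()} samples; "
      f"{psi['low_coverage'].mean():.1%} flagged low-coverage (< 10 reads)")

results = fit_usage(events, truth.samples.select_comparison("KO", "HOM"), joint=True)
print("\nevent types:", results["type"].value_counts().to_dict())

merged = results.set_index("event_id").join(
    truth.events.set_index("event_id")[["regulated", "ko_shift"]])
reg = merged[merged["regulated"]]
sign_match = (np.sign(reg["log2_usage_fc"]) == np.sign(reg["ko_shift"])).mean()
print(f"\nregulated events detected at FDR < 0.05: "
      f"{(reg['fdr'] < 0.05).sum()}/{len(reg)}")
print(f"sign agreement with the true logit shift: {sign_match:.1%}")
print(f"mean |delta PSI| over regulated events: {reg['delta_psi'].abs().mean():.3f}")
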