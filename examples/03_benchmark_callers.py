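"""Benchmark four DMP-calling strategies by discrimination power.

Each caller (signal detection, pooled Fisher exact, replicate Wald,
root-mean-square Monte-Carlo) produces a site set at the shared
thresholds (level difference > 0.25, p < 0.05); a held-out logistic
classifier on per-sample divergence features then measures how well each
set discriminates treatment from control samples.
"""

import pandas as pd

from memsig.bsio import SampleManifest
from memsig.dmpbench import run_benchmark
from memsig.synthdata import SyntheticConfig, build_toy_genome, simulate_counts

config = SyntheticConfig(seed=1)
annotation = build_toy_genome(config)
rows = [(f"WT_{i}", "control", 1, "WT") for i in range(5)] + [
    (f"MM_{i}", "treatment", 1, "MM") for i in range(5)
]
manifest = SampleManifest(
    pd.DataFrame(rows, columns=["sample_id", "group", "generation", "phenotype"])
)
tables, truth = simulate_counts(annotation, config, manifest)

ranking, reports = run_benchmark(tables, manifest, n_boot=999, seed=1)
print(ranking.round(3).to_string(index=False))
best = ranking.iloc[0]
print(f"\nbest caller: {best['method']} "
      f"(accuracy {best['accuracy']:.3f}, 95% CI "
      f"[{best['accuracy_ci_low']:.3f}, {best['accuracy_ci_high']:.3f}])")
print("accuracy ~0.95 means the called sites separate the groups almost "
      "perfectly at the level of individual samples.")
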