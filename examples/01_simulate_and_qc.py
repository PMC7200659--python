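"""Simulate a transgenerational bisulfite study and run sequencing QC.

Builds the default toy genome (one ~50-kb chromosome: genes, TEs, small
RNAs), simulates six generations of wild-type (WT), memory (MM) and
first-generation nonmemory (NM) plants, then shows the QC rules applied
to real coverage files: the PCR-bias coverage cap and the chloroplast
bisulfite-conversion check.
"""

import pandas as pd

from memsig.bsio import CytosineCountTable, conversion_rate, filter_coverage
from memsig.divergence import context_summary
from memsig.synthdata import SyntheticConfig, build_toy_genome, simulate_generations

config = SyntheticConfig(seed=1)
annotation = build_toy_genome(config)
study = simulate_generations(annotation, config)

print(f"genome: {len(annotation.genes())} genes, "
      f"{len(annotation.by_class('TE_related'))} TE-related features")
print(f"samples: {len(study.tables)} across {config.n_generations} generations")
print(f"induced truth sites: {len(study.truth.induced_sites)} "
      f"in {len(study.truth.target_genes)} target genes")

# Genome-wide weighted methylation level per context for one WT sample:
# Arabidopsis-like ordering CG > CHG > CHH is built into the baselines.
summary = context_summary([study.tables["WT_g1_1"]])
print(summary.to_string(index=False))

# QC: coverage>500 sites are removed (PCR bias); a chloroplast with almost
# no methylated calls gives a conversion rate > 99% and passes.
chloro = CytosineCountTable(
    "WT_g1_1_chrC",
    pd.DataFrame({"chrom": ["ChrC"], "pos": [1], "strand": ["+"],
                  "context": ["CG"], "n_meth": [4], "n_unmeth": [996]}),
)
rate, ok = conversion_rate(chloro, "ChrC")
print(f"conversion rate {rate:.3f} -> {'pass' if ok else 'fail'} (threshold 0.99)")
filtered = filter_coverage(study.tables["WT_g1_1"], max_cov=500, min_cov=4)
print(f"coverage filter kept {len(filtered)} of {len(study.tables['WT_g1_1'])} sites")
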