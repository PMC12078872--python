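"""Diversity, differentiation, sweep regions, and fate overlap.

Simulates a small panel, computes per-locus nucleotide diversity and
Weir-Cockerham F_ST between the first and last stage, calls top-5%
sweep regions from a synthetic per-window score, and asks how much of
each allele fate lies inside those regions.
"""

import tempfile

import numpy as np
import pandas as pd

from glac import pipeline, synthetic
from glac.popgen_stats import (
    call_sweep_regions,
    diversity_fst_table,
    genome_fst,
    genome_pi,
    overlap_fates,
)

with tempfile.TemporaryDirectory() as tmp:
    config = synthetic.SimConfig.default(seed=7)
    sim = synthetic.simulate_history(config, tmp)
    panel = pipeline.build_panel(
        sim.vcf_path, sim.manifest_path, min_maf=0.0, rare_threshold=0.0
    )
    fates = pipeline.classify_stage_graph(panel.freqs, config.transition_specs())

table = diversity_fst_table(panel.calls, panel.manifest, "WA", "RC")
print(f"{len(table)} loci: genome pi(WA)={genome_pi(table['pi_WA']):.3f}, "
      f"pi(RC)={genome_pi(table['pi_RC']):.3f}, "
      f"Fst(WA,RC)={genome_fst(table['fst']):.3f}")
# Diversity drops from the wild to the cultivar stage (planted exclusions
# and locus fixation remove alleles) and the two stages differentiate.

# synthetic sliding-window score peaking over the first chromosome arm
rng = np.random.default_rng(7)
windows = pd.DataFrame({
    "chrom": ["Chr01"] * 200,
    "start": [i * 10_000 for i in range(200)],
    "end": [i * 10_000 + 100_000 for i in range(200)],
    "score": rng.gamma(2.0, 1.0, 200) + np.where(np.arange(200) < 12, 8.0, 0.0),
})
regions = call_sweep_regions(windows, top_fraction=0.05)
print(f"\ntop-5% sweep calling: {regions.n_selected_windows} windows >= "
      f"{regions.threshold:.2f} merged into {len(regions.regions)} region(s), "
      f"{regions.total_length / 1e6:.2f} Mb total")

overlap = overlap_fates(
    fates[fates["transition"] == "WA->LR"], panel.loci, regions
)
print("\nshare of each WA->LR fate inside sweep regions:")
print(overlap.round(2).to_string())
# Only the fates whose loci happen to sit under the score peak overlap:
# sweep scans see a small slice of the genome, while zero/one changes
# are counted genome-wide - the motivation for locus-allele comparison.
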