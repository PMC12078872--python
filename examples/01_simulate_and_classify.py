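"""Simulate a three-stage soybean-like panel and classify every allele.

Builds a wild -> landrace -> cultivar panel with planted allele fates,
reconstructs SNPLDB haplotype-block loci from the emitted VCF, classifies
each allele of the shared universe at both transitions, and checks the
calls against the planted ground truth.
"""

import tempfile

from glac import pipeline, synthetic
from glac.glac_core import derive_locus_fates
from glac.synthetic import verify_recovery

with tempfile.TemporaryDirectory() as tmp:
    config = synthetic.SimConfig.default(seed=42)
    sim = synthetic.simulate_history(config, tmp)
    print(f"simulated {config.n_loci} loci for "
          f"{sum(s.n_accessions for s in config.stages)} accessions "
          f"({' -> '.join(s.label for s in config.stages)})")

    panel = pipeline.build_panel(
        sim.vcf_path, sim.manifest_path, min_maf=0.0, rare_threshold=0.0
    )
    print(f"reconstructed {len(panel.loci)} SNPLDB loci "
          f"({sum(1 for l in panel.loci if l.n_snps > 1)} multi-SNP blocks, "
          f"{panel.freqs.freq.shape[0]} alleles in the universe)")

    fates = pipeline.classify_stage_graph(panel.freqs, config.transition_specs())
    locus_fates = derive_locus_fates(fates)
    for label, grp in fates.groupby("transition"):
        counts = grp["category"].value_counts()
        print(f"\n{label}: " + ", ".join(
            f"{cat}={n}" for cat, n in counts.sort_index().items()))

    report = verify_recovery(sim.truth, fates)
    print(f"\nrecovery: {report.n_mismatch} mismatches of {report.n_total} "
          f"allele-transition calls ({100 * report.recovery_rate:.1f}% exact)")
    # 0 mismatches: in the noiseless setting the pipeline recovers every
    # planted exclusion, emergence, restoration and locus zero/one change.
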