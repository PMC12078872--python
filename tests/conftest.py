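import numpy as np
import pandas as pd
import pytest

from glac.genotype_io import GenotypeMatrix, SampleManifest
from glac.snpldb import WHOLE_SAMPLE, AlleleFrequencyTable


def write_vcf(path, samples, records):
    """Write a minimal VCF 4.2; records are (chrom, pos, ref, alt, gts)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


def make_genotypes(calls2d, pos=None, chrom="Chr01"):
    """GenotypeMatrix from a (n_snps, n_accessions) call-code array."""
    calls = np.asarray(calls2d, dtype=np.int8)
    n = calls.shape[0]
    if pos is None:
        pos = np.arange(1000, 1000 + n * 100, 100)
    return GenotypeMatrix(
        chroms=[chrom],
        chrom_idx=np.zeros(n, dtype=np.int32),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["T"] * n, dtype=object),
        calls=calls,
        samples=[f"S{i:02d}" for i in range(calls.shape[1])],
    )


def make_freq_table(rows, pops):
    """AlleleFrequencyTable from (locus, allele, {pop: freq}) rows.

    The whole-sample column is the mean of the subpopulation columns
    unless a row supplies it explicitly.
    """
    index = pd.MultiIndex.from_tuples(
        [(r[0], r[1]) for r in rows], names=["locus_id", "allele_id"]
    )
    data = {}
    for pop in pops:
        data[pop] = [r[2].get(pop, 0.0) for r in rows]
    freq = pd.DataFrame(data, index=index)
    freq[WHOLE_SAMPLE] = [
        r[2].get(WHOLE_SAMPLE, np.nanmean([r[2].get(p, 0.0) for p in pops]))
        for r in rows
    ]
    loci = sorted(set(r[0] for r in rows))
    n = pd.DataFrame(
        {p: [10] * len(loci) for p in [*pops, WHOLE_SAMPLE]}, index=loci
    )
    n.index.name = "locus_id"
    return AlleleFrequencyTable(freq=freq, n_nonmissing=n)


def make_manifest(mapping):
    return SampleManifest(labels=dict(mapping))


@pytest.fixture(scope="session")
def sim_panel(tmp_path_factory):
    """Noiseless three-stage simulated panel, run through the pipeline."""
    from glac import pipeline, synthetic
    from glac.glac_core import derive_locus_fates

    cfg = synthetic.SimConfig.default(seed=11)
    res = synthetic.simulate_history(cfg, tmp_path_factory.mktemp("sim_panel"))
    panel = pipeline.build_panel(
        res.vcf_path, res.manifest_path, min_maf=0.0, rare_threshold=0.0
    )
    specs = cfg.transition_specs()
    fates = pipeline.classify_stage_graph(panel.freqs, specs)
    locus_fates = derive_locus_fates(fates)
    return {
        "config": cfg,
        "result": res,
        "panel": panel,
        "specs": specs,
        "fates": fates,
        "locus_fates": locus_fates,
    }
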