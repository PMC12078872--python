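"""High-level wiring: VCF + manifest + stage graph -> fate tables.

Convenience layer used by the command-line interface, the examples and
the acceptance computations; everything here is a thin composition of
the module-level operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from glac.genotype_io import GenotypeMatrix, SampleManifest, read_manifest, read_vcf
from glac.glac_core import ConfigError, TransitionSpec, classify_transition
from glac.snpldb import (
    AlleleFrequencyTable,
    SnpldbLocus,
    allele_frequencies,
    call_haplotypes,
    partition_blocks,
)


@dataclass
class PanelData:
    """Everything derived from one VCF + manifest pass."""

    genotypes: GenotypeMatrix
    manifest: SampleManifest
    loci: list[SnpldbLocus]
    calls: pd.DataFrame
    freqs: AlleleFrequencyTable


def build_panel(
    vcf_path: str | Path,
    manifest_path: str | Path,
    min_maf: float = 0.01,
    max_span_bp: int = 100_000,
    strong_ld: float = 0.70,
    strong_pair_prop: float = 0.95,
    rare_threshold: float = 0.01,
) -> PanelData:
    """Read genotypes, build SNPLDB loci, and compute allele frequencies."""
    geno = read_vcf(str(vcf_path), min_maf=min_maf)
    manifest = read_manifest(str(manifest_path), geno)
    partition = partition_blocks(
        geno,
        max_span_bp=max_span_bp,
        strong_ld=strong_ld,
        strong_pair_prop=strong_pair_prop,
    )
    loci, calls = call_haplotypes(geno, partition, rare_threshold=rare_threshold)
    freqs = allele_frequencies(calls, manifest)
    return PanelData(
        genotypes=geno, manifest=manifest, loci=loci, calls=calls, freqs=freqs
    )


def classify_stage_graph(
    freqs: AlleleFrequencyTable, specs: list[TransitionSpec]
) -> pd.DataFrame:
    """Classify every transition of a stage graph; concatenated fates."""
    return pd.concat(
        [classify_transition(freqs, s) for s in specs], ignore_index=True
    )


def load_stage_graph(path: str | Path) -> list[TransitionSpec]:
    """Stage-graph config: ordered transitions with years and sources.

    YAML layout::

        transitions:
          - parent: WA
            child: LR
            years: 5000
          - parent: LR
            child: RC
            years: 100
            restoration_sources: [WA]
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "transitions" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'transitions' list")
    specs = []
    for i, t in enumerate(doc["transitions"]):
        try:
            specs.append(
                TransitionSpec(
                    parent=t["parent"],
                    child=t["child"],
                    years=float(t.get("years", 1.0)),
                    restoration_sources=tuple(t.get("restoration_sources", ())),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: transition {i} missing key {exc}") from exc
    return specs


def freq_table_long(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    """Long-format frequency table for TSV export."""
    out = freqs.freq.stack().rename("freq").reset_index()
    out.columns = ["locus_id", "allele_id", "subpopulation", "freq"]
    return out
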