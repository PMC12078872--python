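"""SNPLDB construction: LD-block partition and multi-allelic haplotype calling.

A SNPLDB locus is a run of tightly linked SNPs (pairwise |D'| >= 0.70)
whose observed haplotypes serve as multiple alleles; SNPs that join no
block become biallelic singleton loci. The panel is assumed inbred:
haplotypes are read directly off homozygous calls, and heterozygous or
missing constituent calls make the locus call missing for that accession.

The partition rule is a simplified Gabriel-style contiguous scan: a
multi-SNP block is a maximal contiguous run, spanning at most
``max_span_bp``, in which at least ``strong_pair_prop`` of the
informative pairwise |D'| values are >= ``strong_ld``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glac.genotype_io import HOM_ALT, HOM_REF, GenotypeMatrix, SampleManifest

WHOLE_SAMPLE = "ALL"


@dataclass
class DprimeEstimate:
    """Normalised LD coefficient |D'| with an informativeness flag."""

    value: float
    informative: bool
    n_pairs: int = 0


@dataclass
class SnpldbLocus:
    """A genomic block (or singleton SNP) with its haplotype alleles.

    ``catalogue`` maps every observed haplotype string to its allele id;
    rare haplotypes merged away map to the id of their absorbing
    haplotype. Allele ids are the representative haplotype strings
    ('0'/'1' per constituent SNP in record order).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    snp_indices: list[int]
    snp_positions: list[int]
    catalogue: dict[str, str]
    alleles: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class AlleleFrequencyTable:
    """Frequency of every universe allele in every subpopulation.

    ``freq`` is indexed by (locus_id, allele_id) with one column per
    subpopulation plus the whole-sample column ``ALL``; a cell is NaN
    when the subpopulation has zero non-missing calls at the locus.
    ``n_nonmissing`` is indexed by locus_id with the same columns.
    """

    freq: pd.DataFrame
    n_nonmissing: pd.DataFrame

    @property
    def populations(self) -> list[str]:
        return [c for c in self.freq.columns if c != WHOLE_SAMPLE]

    def population(self, label: str) -> pd.Series:
        if label not in self.freq.columns:
            raise KeyError(f"no subpopulation {label!r} in frequency table")
        return self.freq[label]


def dprime(joint_counts, min_informative: int = 4) -> DprimeEstimate:
    """|D'| from a 2x2 table of joint haplotype counts.

    ``joint_counts[i][j]`` is the number of accessions carrying allele i
    at the first site and allele j at the second (homozygous calls only;
    pairs with a het or missing call at either site are skipped upstream).
    A site monomorphic in the usable subset yields informative=False and
    a NaN value, never a silent 0.
    """
    n = np.asarray(joint_counts, dtype=float)
    if n.shape != (2, 2) or (n < 0).any():
        raise ValueError("joint_counts must be a non-negative 2x2 table")
    total = n.sum()
    if total == 0:
        return DprimeEstimate(np.nan, False, 0)
    p = n / total
    pA, pB = p[0].sum(), p[:, 0].sum()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return DprimeEstimate(np.nan, False, int(total))
    d = p[0, 0] - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    value = abs(d) / dmax if dmax > 0 else np.nan
    return DprimeEstimate(
        value=value,
        informative=bool(total >= min_informative and np.isfinite(value)),
        n_pairs=int(total),
    )


def _pair_dprime(calls_i: np.ndarray, calls_j: np.ndarray,
                 min_informative: int) -> DprimeEstimate:
    """|D'| between two SNPs from homozygous calls of inbred accessions."""
    usable = ((calls_i == HOM_REF) | (calls_i == HOM_ALT)) & (
        (calls_j == HOM_REF) | (calls_j == HOM_ALT)
    )
    a = (calls_i[usable] == HOM_ALT).astype(int)
    b = (calls_j[usable] == HOM_ALT).astype(int)
    counts = np.bincount(2 * a + b, minlength=4).reshape(2, 2)
    return dprime(counts, min_informative=min_informative)


def partition_blocks(
    genotypes: GenotypeMatrix,
    max_span_bp: int = 100_000,
    strong_ld: float = 0.70,
    strong_pair_prop: float = 0.95,
    min_informative: int = 4,
) -> list[list[int]]:
    """Partition each chromosome into an ordered list of SNP runs.

    Returns a list of blocks, each a list of record indices into
    ``genotypes``; singletons are single-element lists. The partition is
    exhaustive and disjoint. Blocks are grown greedily left to right: a
    candidate SNP joins the current run while the block span stays within
    ``max_span_bp`` and the proportion of informative pairwise |D'|
    values >= ``strong_ld`` remains >= ``strong_pair_prop``.
    """
    blocks: list[list[int]] = []
    for _, idx in genotypes.snp_indices_by_chrom().items():
        i = 0
        while i < len(idx):
            run = [idx[i]]
            n_strong = n_informative = 0
            j = i + 1
            while j < len(idx):
                cand = idx[j]
                if genotypes.pos[cand] - genotypes.pos[run[0]] > max_span_bp:
                    break
                add_strong = add_info = 0
                for member in run:
                    est = _pair_dprime(
                        genotypes.calls[member], genotypes.calls[cand],
                        min_informative,
                    )
                    if est.informative:
                        add_info += 1
                        if est.value >= strong_ld:
                            add_strong += 1
                tot_info = n_informative + add_info
                tot_strong = n_strong + add_strong
                if tot_info == 0 or tot_strong / tot_info < strong_pair_prop:
                    break
                run.append(cand)
                n_strong, n_informative = tot_strong, tot_info
                j += 1
            blocks.append([int(k) for k in run])
            i += len(run)
    return blocks


def _haplotype_strings(genotypes: GenotypeMatrix, block: list[int]) -> np.ndarray:
    """Per-accession haplotype over the block's SNPs; None where any
    constituent call is het or missing."""
    sub = genotypes.calls[block]  # (k, n_acc)
    ok = np.all((sub == HOM_REF) | (sub == HOM_ALT), axis=0)
    bits = (sub == HOM_ALT).astype(np.uint8)
    haps = np.empty(genotypes.n_samples, dtype=object)
    for s in range(genotypes.n_samples):
        haps[s] = "".join("1" if b else "0" for b in bits[:, s]) if ok[s] else None
    return haps


def _merge_rare(counts: dict[str, int], total: int,
                rare_threshold: float) -> dict[str, str]:
    """Map each haplotype to its surviving representative.

    Haplotypes with whole-sample frequency below ``rare_threshold`` are
    merged into the nearest frequent haplotype by Hamming distance
    (ties: the more frequent target, then the lexicographically smallest).
    If no haplotype is frequent, nothing is merged.
    """
    mapping = {h: h for h in counts}
    if rare_threshold <= 0 or total == 0:
        return mapping
    frequent = [h for h, c in counts.items() if c / total >= rare_threshold]
    if not frequent:
        return mapping
    for h, c in counts.items():
        if c / total >= rare_threshold:
            continue
        best = min(
            frequent,
            key=lambda t: (
                sum(x != y for x, y in zip(h, t)),
                -counts[t],
                t,
            ),
        )
        mapping[h] = best
    return mapping


def call_haplotypes(
    genotypes: GenotypeMatrix,
    partition: list[list[int]],
    rare_threshold: float = 0.01,
) -> tuple[list[SnpldbLocus], pd.DataFrame]:
    """Call multi-allelic haplotype alleles per block.

    Returns the locus list and a call matrix (index locus_id, columns
    accessions, values allele id or NaN). Rare-haplotype merging never
    changes which calls are non-missing, only their labels. Blocks with
    every call missing are dropped with a warning.
    """
    loci: list[SnpldbLocus] = []
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for block in partition:
        haps = _haplotype_strings(genotypes, block)
        observed = [h for h in haps if h is not None]
        chrom = genotypes.chrom_of(block[0])
        positions = [int(genotypes.pos[k]) for k in block]
        locus_id = f"{chrom}:{positions[0]}-{positions[-1]}"
        if not observed:
            warnings.warn(f"locus {locus_id}: all calls missing; dropped")
            continue
        counts: dict[str, int] = {}
        for h in observed:
            counts[h] = counts.get(h, 0) + 1
        mapping = _merge_rare(counts, len(observed), rare_threshold)
        merged_counts: dict[str, int] = {}
        for h, c in counts.items():
            rep = mapping[h]
            merged_counts[rep] = merged_counts.get(rep, 0) + c
        # allele ids ordered by descending frequency, then lexicographic
        alleles = sorted(merged_counts, key=lambda h: (-merged_counts[h], h))
        loci.append(
            SnpldbLocus(
                locus_id=locus_id,
                chrom=chrom,
                start=positions[0],
                end=positions[-1],
                snp_indices=block,
                snp_positions=positions,
                catalogue=mapping,
                alleles=alleles,
            )
        )
        rows.append(
            np.array(
                [mapping[h] if h is not None else None for h in haps], dtype=object
            )
        )
        ids.append(locus_id)
    calls = pd.DataFrame(rows, index=ids, columns=genotypes.samples, dtype=object)
    calls.index.name = "locus_id"
    return loci, calls


def allele_frequencies(
    calls: pd.DataFrame, manifest: SampleManifest
) -> AlleleFrequencyTable:
    """Per-subpopulation allele frequencies from the locus call matrix.

    Frequency = carrier count / non-missing count within the
    subpopulation; the allele universe is every allele observed in the
    whole sample. A subpopulation with zero non-missing calls at a locus
    gets NaN frequencies there (flagged via ``n_nonmissing``).
    """
    groups = {lab: manifest.members(lab) for lab in manifest.subpopulations}
    groups[WHOLE_SAMPLE] = list(calls.columns)
    pops = list(groups)

    freq_rows: dict[str, dict[tuple[str, str], float]] = {p: {} for p in pops}
    n_rows: dict[str, dict[str, int]] = {p: {} for p in pops}
    for locus_id, row in calls.iterrows():
        universe = sorted(set(v for v in row.values if v is not None))
        for pop, members in groups.items():
            vals = row[members].values
            nonmiss = [v for v in vals if v is not None]
            n = len(nonmiss)
            n_rows[pop][locus_id] = n
            if n == 0:
                for a in universe:
                    freq_rows[pop][(locus_id, a)] = np.nan
                continue
            counts: dict[str, int] = {}
            for v in nonmiss:
                counts[v] = counts.get(v, 0) + 1
            for a in universe:
                freq_rows[pop][(locus_id, a)] = counts.get(a, 0) / n

    index = pd.MultiIndex.from_tuples(
        list(freq_rows[WHOLE_SAMPLE].keys()), names=["locus_id", "allele_id"]
    )
    freq = pd.DataFrame(
        {p: [freq_rows[p][k] for k in index] for p in pops}, index=index
    )
    n_nonmissing = pd.DataFrame(n_rows)
    n_nonmissing.index.name = "locus_id"
    return AlleleFrequencyTable(freq=freq, n_nonmissing=n_nonmissing)


def loci_table(loci: list[SnpldbLocus]) -> pd.DataFrame:
    """Locus summary (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "n_snps": [l.n_snps for l in loci],
            "n_alleles": [l.n_alleles for l in loci],
        }
    ).set_index("locus_id")


def loci_bed(loci: list[SnpldbLocus]) -> pd.DataFrame:
    """BED-style export (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "start": [l.start - 1 for l in loci],
            "end": [l.end for l in loci],
            "name": [l.locus_id for l in loci],
        }
    )
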