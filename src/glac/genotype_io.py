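"""Read SNP genotypes and sample metadata into the internal matrix model.

The input boundary is a VCF of biallelic SNPs for a panel of inbred
accessions. Calls are stored as haploid-equivalent dosage codes; a
whole-sample minor-allele-frequency filter is applied on read. Sample
metadata (accession -> subpopulation label) comes from a two-column TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# per-accession call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1


class VcfFormatError(ValueError):
    """Malformed or unreadable VCF input."""


class EmptyResultError(ValueError):
    """A filter left zero usable records."""


class ManifestError(ValueError):
    """Sample manifest inconsistent with the genotype panel."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP records x accessions, sorted by (chrom, pos).

    ``calls`` is an int8 array of shape (n_snps, n_accessions) holding
    HOM_REF / HET / HOM_ALT / MISSING codes. Chromosome order follows the
    order of first appearance in the VCF; positions are 1-based.
    """

    chroms: list[str]
    chrom_idx: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    samples: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_of(self, i: int) -> str:
        return self.chroms[self.chrom_idx[i]]

    def snp_indices_by_chrom(self) -> dict[str, np.ndarray]:
        """Record indices per chromosome, in positional order."""
        return {
            chrom: np.flatnonzero(self.chrom_idx == ci)
            for ci, chrom in enumerate(self.chroms)
        }


@dataclass
class SampleManifest:
    """Accession -> subpopulation label mapping."""

    labels: dict[str, str]
    extra_rows: list[str] = field(default_factory=list)

    @property
    def subpopulations(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels.values():
            seen.setdefault(lab, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [acc for acc, lab in self.labels.items() if lab == label]

    def __getitem__(self, accession: str) -> str:
        return self.labels[accession]

    def __len__(self) -> int:
        return len(self.labels)


def allele_dosages(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (ref_dose, alt_dose, n_nonmissing); het counts half of each.

    Doses are in units of accessions (haploid-equivalent), so
    ref + alt = n_nonmissing at every site.
    """
    nonmissing = calls != MISSING
    n_nonmiss = nonmissing.sum(axis=1)
    alt = np.where(nonmissing, calls, 0).sum(axis=1) / 2.0
    ref = n_nonmiss - alt
    return ref, alt, n_nonmiss


def whole_sample_maf(calls: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site over non-missing calls only."""
    ref, alt, n = allele_dosages(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return np.fmin(p_alt, 1.0 - p_alt)


def _parse_gt(gt: str) -> int:
    """Decode a VCF GT field into a dosage code."""
    sep = "/" if "/" in gt else "|"
    fields = gt.split(sep)
    if "." in fields or gt == ".":
        return MISSING
    try:
        alleles = [int(a) for a in fields]
    except ValueError:
        return MISSING
    if len(alleles) == 1:  # haploid call
        return HOM_ALT if alleles[0] == 1 else HOM_REF
    return sum(alleles[:2])


def read_vcf(path: str, min_maf: float = 0.01) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF, applying a whole-sample MAF filter.

    Multi-allelic sites and non-SNP records (indels, symbolic alleles)
    are dropped rather than split. MAF is computed over non-missing calls
    with heterozygotes contributing half a dose of each allele; records
    with MAF >= ``min_maf`` are retained.

    Raises
    ------
    VcfFormatError
        If the file cannot be parsed (the offending record is named).
    EmptyResultError
        If no SNP survives filtering.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfFormatError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    chroms: list[str] = []
    chrom_index: dict[str, int] = {}
    chrom_idx, pos, ref, alt, calls = [], [], [], [], []
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            a_ref, a_alt = var.REF, var.ALT[0]
            if len(a_ref) != 1 or len(a_alt) != 1 or not a_alt.isalpha():
                continue
            if var.CHROM not in chrom_index:
                chrom_index[var.CHROM] = len(chroms)
                chroms.append(var.CHROM)
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            g = np.asarray(var.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            chrom_idx.append(chrom_index[var.CHROM])
            pos.append(var.POS)
            ref.append(a_ref)
            alt.append(a_alt)
            calls.append(g)
    except Exception as exc:
        raise VcfFormatError(
            f"malformed VCF record in {path!r} near line for "
            f"{chroms[-1] if chroms else '?'}:{pos[-1] if pos else '?'}: {exc}"
        ) from exc

    if not pos:
        raise EmptyResultError(f"no biallelic SNP records in {path!r}")

    geno = GenotypeMatrix(
        chroms=chroms,
        chrom_idx=np.asarray(chrom_idx, dtype=np.int32),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        calls=np.vstack(calls),
        samples=samples,
    )
    # sort by (chrom order of appearance, pos)
    order = np.lexsort((geno.pos, geno.chrom_idx))
    geno = GenotypeMatrix(
        chroms=geno.chroms,
        chrom_idx=geno.chrom_idx[order],
        pos=geno.pos[order],
        ref=geno.ref[order],
        alt=geno.alt[order],
        calls=geno.calls[order],
        samples=samples,
    )
    keep = whole_sample_maf(geno.calls) >= min_maf if min_maf > 0 else np.ones(
        geno.n_snps, dtype=bool
    )
    keep &= ~np.isnan(whole_sample_maf(geno.calls))
    if not keep.any():
        raise EmptyResultError(
            f"no SNP passes MAF >= {min_maf} (of {geno.n_snps} biallelic records)"
        )
    return GenotypeMatrix(
        chroms=geno.chroms,
        chrom_idx=geno.chrom_idx[keep],
        pos=geno.pos[keep],
        ref=geno.ref[keep],
        alt=geno.alt[keep],
        calls=geno.calls[keep],
        samples=samples,
    )


def read_manifest(path: str, genotypes: GenotypeMatrix) -> SampleManifest:
    """Read a two-column TSV (accession_id, subpopulation label).

    Every accession in the genotype panel must be present exactly once;
    manifest rows for accessions absent from the panel are kept in
    ``extra_rows`` and reported, not fatal.
    """
    labels: dict[str, str] = {}
    extra: list[str] = []
    panel = set(genotypes.samples)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ManifestError(f"{path}:{ln}: expected 'accession<TAB>label'")
            acc, lab = parts[0].strip(), parts[1].strip()
            if acc in labels or acc in extra:
                raise ManifestError(f"{path}:{ln}: duplicate accession {acc!r}")
            if acc in panel:
                labels[acc] = lab
            else:
                extra.append(acc)
    missing = [s for s in genotypes.samples if s not in labels]
    if missing:
        raise ManifestError(
            f"manifest {path} lacks {len(missing)} panel accession(s): "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    # preserve panel order
    ordered = {s: labels[s] for s in genotypes.samples}
    return SampleManifest(labels=ordered, extra_rows=extra)
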