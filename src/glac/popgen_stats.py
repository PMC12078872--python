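"""Diversity, differentiation, and selective-sweep region accounting.

Nucleotide diversity and the Weir-Cockerham F_ST estimator are computed
on haploid-equivalent calls (the panel is inbred; heterozygous calls are
treated as missing upstream). The sweep statistic itself (e.g. XP-CLR)
is consumed as a per-window score table, not computed: region calling
selects the top fraction of windows (ties included) and merges
overlapping or book-ended selections into single regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glac import glac_core as gc
from glac.snpldb import SnpldbLocus


def site_pi(allele_counts, n: int | None = None) -> float:
    """Unbiased nucleotide diversity at one site.

    pi = n/(n-1) * (1 - sum_i p_i^2): the average pairwise difference
    over the n haploid-equivalent non-missing calls. Undefined (NaN) for
    n < 2.
    """
    counts = np.asarray(allele_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("allele counts must be non-negative")
    if n is None:
        n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def locus_pi(snp_allele_counts: list) -> float:
    """Locus diversity = mean site pi over constituent SNPs."""
    vals = [site_pi(c) for c in snp_allele_counts]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def genome_pi(locus_values) -> float:
    """Whole-genome diversity = overall average across loci."""
    vals = np.asarray(list(locus_values), dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def _wc_components(counts1, counts2) -> tuple[float, float]:
    """Weir-Cockerham (1984) among/within variance components, haploid.

    Returns (a, a + b) summed over alleles: a is the among-population
    component (MSP - MSG) / n_c and b the within component MSG, from the
    one-way ANOVA on allele indicators with r = 2 populations.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("allele count vectors must align")
    n1, n2 = c1.sum(), c2.sum()
    if n1 < 2 or n2 < 2:
        return float("nan"), float("nan")
    n_tot = n1 + n2
    r = 2
    n_c = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1)
    a_sum = d_sum = 0.0
    for i in range(len(c1)):
        p1, p2 = c1[i] / n1, c2[i] / n2
        pbar = (c1[i] + c2[i]) / n_tot
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - r)
        a = (msp - msg) / n_c
        a_sum += a
        d_sum += a + msg
    return a_sum, d_sum


def wc_fst(counts_pop1, counts_pop2, clamp: bool = False) -> float:
    """Weir-Cockerham F_ST between two populations at one locus.

    ``counts_popX`` are per-allele carrier counts (haploid-equivalent,
    multi-allele capable). Negative estimates are reported as computed
    unless ``clamp`` is set. NaN when both populations are monomorphic
    for the same allele (the estimator is 0/0) or a sample has n < 2.
    """
    a, d = _wc_components(counts_pop1, counts_pop2)
    if math.isnan(a) or d == 0:
        return float("nan")
    theta = a / d
    return max(theta, 0.0) if clamp else theta


def locus_fst(per_snp_counts: list[tuple]) -> float:
    """Locus F_ST = ratio of variance components summed over SNPs."""
    a_tot = d_tot = 0.0
    any_ok = False
    for c1, c2 in per_snp_counts:
        a, d = _wc_components(c1, c2)
        if not math.isnan(a):
            a_tot += a
            d_tot += d
            any_ok = True
    if not any_ok or d_tot == 0:
        return float("nan")
    return a_tot / d_tot


def genome_fst(locus_values) -> float:
    """Whole-genome F_ST = overall average across loci."""
    return genome_pi(locus_values)


def diversity_fst_table(
    calls: pd.DataFrame, manifest, pop1: str, pop2: str
) -> pd.DataFrame:
    """Per-locus pi (each population) and pairwise F_ST from locus calls.

    Treats each multi-allelic SNPLDB locus as a single unit: pi and the
    F_ST components are computed over its haplotype alleles.
    """
    m1 = manifest.members(pop1)
    m2 = manifest.members(pop2)
    rows = []
    for locus_id, row in calls.iterrows():
        def _counts(members):
            vals = [v for v in row[members] if v is not None]
            alleles = sorted(set(v for v in row if v is not None))
            return np.array([vals.count(a) for a in alleles], dtype=float)

        c1, c2 = _counts(m1), _counts(m2)
        rows.append(
            {
                "locus_id": locus_id,
                f"pi_{pop1}": site_pi(c1),
                f"pi_{pop2}": site_pi(c2),
                "fst": wc_fst(c1, c2) if c1.sum() >= 2 and c2.sum() >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


@dataclass
class SweepRegionSet:
    """Merged high-score regions with the threshold that selected them."""

    regions: pd.DataFrame  # chrom, start, end, max_score (bp, half-open)
    threshold: float
    n_selected_windows: int

    @property
    def total_length(self) -> int:
        if not len(self.regions):
            return 0
        return int((self.regions["end"] - self.regions["start"]).sum())


def call_sweep_regions(windows: pd.DataFrame, top_fraction: float = 0.05) -> SweepRegionSet:
    """Select the top-scoring windows and merge them into regions.

    ``windows`` needs columns chrom, start, end, score (starts/ends in a
    consistent coordinate system; sliding windows may overlap). The
    threshold is the k-th largest score with k = ceil(top_fraction * N);
    every window with score >= threshold is selected (ties included).
    Overlapping or book-ended selected windows merge into single regions.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if len(windows) == 0:
        raise ValueError("empty window set")
    scores = windows["score"].to_numpy(float)
    k = math.ceil(top_fraction * len(scores))
    threshold = float(np.sort(scores)[::-1][k - 1])
    sel = windows[windows["score"] >= threshold].sort_values(["chrom", "start"])

    regions = []
    for chrom, grp in sel.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_max = -math.inf
        for w in grp.itertuples(index=False):
            if cur_start is None or w.start > cur_end:  # gap > 0: new region
                if cur_start is not None:
                    regions.append((chrom, cur_start, cur_end, cur_max))
                cur_start, cur_end, cur_max = w.start, w.end, w.score
            else:
                cur_end = max(cur_end, w.end)
                cur_max = max(cur_max, w.score)
        if cur_start is not None:
            regions.append((chrom, cur_start, cur_end, cur_max))
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "max_score"])
    return SweepRegionSet(
        regions=out, threshold=threshold, n_selected_windows=int(len(sel))
    )


def _locus_in_regions(locus: SnpldbLocus, regions: pd.DataFrame) -> bool:
    """Interval intersection of the locus [start, end] (1-based inclusive)
    with half-open regions."""
    sub = regions[regions["chrom"] == locus.chrom]
    for r in sub.itertuples(index=False):
        if locus.start <= r.end and locus.end >= r.start + 1:
            return True
    return False


def overlap_fates(
    fates: pd.DataFrame,
    loci: list[SnpldbLocus],
    regions: pd.DataFrame | SweepRegionSet,
) -> pd.DataFrame:
    """Per fate category: how many alleles sit in sweep regions.

    A locus is "in" a region when its interval intersects it; every
    allele of the locus inherits that status. Reports count, count in
    regions, and the percentage of each category's total.
    """
    if isinstance(regions, SweepRegionSet):
        regions = regions.regions
    in_region = {l.locus_id: _locus_in_regions(l, regions) for l in loci}
    sub = fates[fates["category"] != gc.UNCLASSIFIABLE]
    rows = []
    for cat, grp in sub.groupby("category"):
        n = len(grp)
        n_in = int(grp["locus_id"].map(in_region).fillna(False).sum())
        rows.append(
            {
                "category": cat,
                "count": n,
                "count_in_regions": n_in,
                "pct_in_regions": 100.0 * n_in / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")
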