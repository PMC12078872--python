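"""Summaries, frequency-class cross-tables, and chromosome-window densities.

Allele frequencies are binned into 12 classes that partition [0, 1]:
{0}, (0, 0.1], (0.1, 0.2], ..., (0.8, 0.9], (0.9, 1), {1}. Interior bins
are right-closed (0.1 falls in "0.0-0.1"); the "0.9-0.99" label denotes
the open interval (0.9, 1) so that small-n data bin identically to large
panels. The cross-table counts alleles by (child class, parent class);
its margins recover the zero/one tallies: the "0" row (minus the (0,0)
cell) is the excluded alleles, the "0" column the emerged plus restored
alleles, the "1" row (minus (1,1)) the locus-fixing alleles (LPD) and
the "1" column the first/restored decreases from 1 (LPE + LPR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glac import glac_core as gc
from glac.glac_core import TransitionSpec, per_year_rates
from glac.snpldb import SnpldbLocus

FREQ_CLASS_LABELS = [
    "0",
    "0.0-0.1",
    "0.1-0.2",
    "0.2-0.3",
    "0.3-0.4",
    "0.4-0.5",
    "0.5-0.6",
    "0.6-0.7",
    "0.7-0.8",
    "0.8-0.9",
    "0.9-0.99",
    "1",
]

_EPS = 1e-9


def bin_frequency(f: float) -> str:
    """Class label for one frequency; exact 0 and 1 are their own classes."""
    return FREQ_CLASS_LABELS[_bin_index(f)]


def _bin_index(f: float) -> int:
    if not 0 <= f <= 1 or math.isnan(f):
        raise ValueError(f"frequency outside [0, 1]: {f}")
    if f == 0:
        return 0
    if f == 1:
        return 11
    k = int(math.ceil(f * 10 - _EPS))
    return min(k, 10)


def bin_frequencies(freqs: np.ndarray) -> np.ndarray:
    """Vectorised class indices (see ``bin_frequency``)."""
    f = np.asarray(freqs, dtype=float)
    if np.isnan(f).any() or (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies outside [0, 1]")
    k = np.ceil(f * 10 - _EPS).astype(int)
    idx = np.clip(k, 1, 10)
    idx[f == 0] = 0
    idx[f == 1] = 11
    return idx


@dataclass
class CrossTable:
    """12x12 allele counts (child class x parent class) with companions.

    ``counts`` includes every classified allele. Restored alleles sit in
    the parent-"0" column and LPR alleles in the parent-"1" column; their
    per-child-class counts are carried separately so reports can print
    the "emerged + restored" style compound cells without conflating the
    categories.
    """

    counts: pd.DataFrame
    transition: str = ""
    restored_by_child_class: pd.Series = field(default=None)
    lpr_by_child_class: pd.Series = field(default=None)

    def __post_init__(self):
        if self.restored_by_child_class is None:
            self.restored_by_child_class = pd.Series(
                0, index=FREQ_CLASS_LABELS, dtype=int
            )
        if self.lpr_by_child_class is None:
            self.lpr_by_child_class = pd.Series(0, index=FREQ_CLASS_LABELS, dtype=int)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def excluded_total(self) -> int:
        """Alleles lost in the child: row "0" minus the (0,0) cell."""
        return int(self.counts.loc["0"].sum() - self.counts.loc["0", "0"])

    @property
    def absent_both_total(self) -> int:
        return int(self.counts.loc["0", "0"])

    @property
    def restored_total(self) -> int:
        return int(self.restored_by_child_class.sum())

    @property
    def emerged_total(self) -> int:
        """Column "0" minus (0,0) and the restored companion counts."""
        col = int(self.counts["0"].sum() - self.counts.loc["0", "0"])
        return col - self.restored_total

    @property
    def lpd_total(self) -> int:
        """Locus-fixing alleles: row "1" minus the (1,1) cell."""
        return int(self.counts.loc["1"].sum() - self.counts.loc["1", "1"])

    @property
    def lpr_total(self) -> int:
        return int(self.lpr_by_child_class.sum())

    @property
    def lpe_total(self) -> int:
        """Column "1" minus (1,1) and the LPR companion counts."""
        col = int(self.counts["1"].sum() - self.counts.loc["1", "1"])
        return col - self.lpr_total

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["row_total"] = self.row_margins
        out.loc["col_total"] = out.sum(axis=0)
        return out

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        transition: str = "",
        restored_by_child_class: pd.Series | None = None,
        lpr_by_child_class: pd.Series | None = None,
    ) -> "CrossTable":
        """Build from an explicit (possibly published) count grid."""
        counts = counts.reindex(
            index=FREQ_CLASS_LABELS, columns=FREQ_CLASS_LABELS, fill_value=0
        ).astype(int)
        rest = (
            restored_by_child_class.reindex(FREQ_CLASS_LABELS, fill_value=0).astype(int)
            if restored_by_child_class is not None
            else None
        )
        lpr = (
            lpr_by_child_class.reindex(FREQ_CLASS_LABELS, fill_value=0).astype(int)
            if lpr_by_child_class is not None
            else None
        )
        return cls(
            counts=counts,
            transition=transition,
            restored_by_child_class=rest,
            lpr_by_child_class=lpr,
        )


def cross_table(fates: pd.DataFrame, transition: str = "") -> CrossTable:
    """Bin classified alleles into the child-by-parent frequency grid.

    Unclassifiable alleles (undefined frequency) are left out; the grand
    total therefore equals the classified allele universe.
    """
    ok = fates["category"] != gc.UNCLASSIFIABLE
    sub = fates[ok]
    ci = bin_frequencies(sub["child_freq"].to_numpy())
    pi = bin_frequencies(sub["parent_freq"].to_numpy())
    grid = np.zeros((12, 12), dtype=int)
    np.add.at(grid, (ci, pi), 1)
    counts = pd.DataFrame(grid, index=FREQ_CLASS_LABELS, columns=FREQ_CLASS_LABELS)
    counts.index.name = "child_class"
    counts.columns.name = "parent_class"

    restored = pd.Series(0, index=FREQ_CLASS_LABELS, dtype=int)
    rmask = (sub["category"] == gc.RESTORED).to_numpy()
    for k in ci[rmask]:
        restored.iloc[k] += 1
    lpr = pd.Series(0, index=FREQ_CLASS_LABELS, dtype=int)
    lmask = (sub["category"] == gc.INHERITED_LPR).to_numpy()
    for k in ci[lmask]:
        lpr.iloc[k] += 1
    if not transition and len(sub):
        transition = str(sub["transition"].iloc[0])
    return CrossTable(
        counts=counts,
        transition=transition,
        restored_by_child_class=restored,
        lpr_by_child_class=lpr,
    )


# Table-1-style row layout: (row name, allele categories it tallies)
SUMMARY_ROWS = [
    ("inherited", gc.INHERITED_CATEGORIES),
    ("frequency_of_1", [gc.INHERITED_FIXED]),
    ("frequency_changes", [c for c in gc.INHERITED_CATEGORIES if c != gc.INHERITED_FIXED]),
    ("increase_to_1_LPD", [gc.INHERITED_LPD]),
    ("first_decrease_from_1_LPE", [gc.INHERITED_LPE]),
    ("restored_decrease_from_1_LPR", [gc.INHERITED_LPR]),
    ("ordinary_increase", [gc.INHERITED_INCREASE]),
    ("ordinary_decrease", [gc.INHERITED_DECREASE]),
    ("unchanged_tie", [gc.INHERITED_UNCHANGED]),
    ("excluded", [gc.EXCLUDED]),
    ("emerged", [gc.EMERGED]),
    ("restored_from_source", [gc.RESTORED]),
    ("frequency_of_0", [gc.ABSENT_BOTH]),
    ("unclassifiable", [gc.UNCLASSIFIABLE]),
]


@dataclass
class SummaryReport:
    """Per-transition allele/locus change summary with per-year rates."""

    transition: str
    allele_table: pd.DataFrame
    zero_one_table: pd.DataFrame
    fixed_locus_count: int
    fixed_replaced_count: int
    allele_universe: int
    locus_universe: int


def summarize_transition(
    fates: pd.DataFrame,
    locus_fates: pd.DataFrame,
    spec: TransitionSpec,
    allele_universe: int | None = None,
    locus_universe: int | None = None,
) -> SummaryReport:
    """Emit the standard summary for one transition.

    The allele table mirrors the inherited / excluded / emerged /
    restored / frequency-of-0 breakdown with percentages of the allele
    universe; the zero/one table carries exclusion, emergence, locus
    polymorphism loss and gain with per-year rates over ``spec.years``.
    Unclassifiable alleles are itemised but excluded from denominators.
    """
    counts = gc.category_counts(fates)
    n_unclass = counts.get(gc.UNCLASSIFIABLE, 0)
    if allele_universe is None:
        allele_universe = int(len(fates) - n_unclass)
    if locus_universe is None:
        locus_universe = int(locus_fates["locus_id"].nunique())

    rows = []
    for name, cats in SUMMARY_ROWS:
        n = sum(counts.get(c, 0) for c in cats)
        denom = allele_universe if name != "unclassifiable" else max(len(fates), 1)
        rows.append({"row": name, "count": n, "pct": 100.0 * n / denom})
    allele_table = pd.DataFrame(rows).set_index("row")

    lcounts = locus_fates["category"].value_counts().to_dict()
    zero_one_rows = []
    for name, n, denom in [
        ("allele_exclusion", counts.get(gc.EXCLUDED, 0), allele_universe),
        ("allele_emergence", counts.get(gc.EMERGED, 0), allele_universe),
        ("locus_polymorphism_disappeared", lcounts.get(gc.LOCUS_DISAPPEARED, 0),
         locus_universe),
        ("locus_polymorphism_emerged", lcounts.get(gc.LOCUS_EMERGED, 0),
         locus_universe),
    ]:
        rate = per_year_rates(n, spec.years, denom)
        zero_one_rows.append(
            {
                "row": name,
                "count": n,
                "pct": 100.0 * n / denom,
                "per_year": rate.per_year_rounded,
                "per_year_per_unit": rate.per_unit_3sig,
            }
        )
    zero_one = pd.DataFrame(zero_one_rows).set_index("row")

    fixed = sum(
        lcounts.get(c, 0)
        for c in (gc.LOCUS_FIXED_KEPT, gc.LOCUS_FIXED_REPLACED, gc.LOCUS_DISAPPEARED)
    )
    return SummaryReport(
        transition=spec.label,
        allele_table=allele_table,
        zero_one_table=zero_one,
        fixed_locus_count=int(fixed),
        fixed_replaced_count=int(lcounts.get(gc.LOCUS_FIXED_REPLACED, 0)),
        allele_universe=allele_universe,
        locus_universe=locus_universe,
    )


def window_density(
    fates: pd.DataFrame,
    loci: list[SnpldbLocus],
    window_bp: int,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-window locus density and fate-category counts.

    Windows of ``window_bp`` tile each chromosome from coordinate 0
    (emitted 0-based half-open, BED-compatible). A locus belongs to the
    window containing its start; allele fates are attributed to their
    locus's window. ``annotations`` (columns chrom, start, end; 0-based
    half-open) adds the fraction of each window covered by the intervals.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    locus_by_id = {l.locus_id: l for l in loci}
    cat_by_locus = (
        fates.groupby(["locus_id", "category"]).size().unstack(fill_value=0)
        if len(fates)
        else pd.DataFrame()
    )
    records: dict[tuple[str, int], dict] = {}
    for locus in loci:
        w = (locus.start - 1) // window_bp
        key = (locus.chrom, w)
        rec = records.setdefault(key, {"n_loci": 0})
        rec["n_loci"] += 1
        if locus.locus_id in cat_by_locus.index:
            for cat, n in cat_by_locus.loc[locus.locus_id].items():
                rec[cat] = rec.get(cat, 0) + int(n)
    rows = []
    for (chrom, w), rec in sorted(records.items()):
        row = {"chrom": chrom, "start": w * window_bp, "end": (w + 1) * window_bp}
        row.update(rec)
        rows.append(row)
    out = pd.DataFrame(rows).fillna(0)
    count_cols = [c for c in out.columns if c not in ("chrom", "start", "end")]
    out[count_cols] = out[count_cols].astype(int)

    if annotations is not None and len(out):
        cover = []
        for row in out.itertuples(index=False):
            sub = annotations[annotations["chrom"] == row.chrom]
            bp = 0
            for iv in sub.itertuples(index=False):
                bp += max(0, min(row.end, iv.end) - max(row.start, iv.start))
            cover.append(bp / window_bp)
        out["annotation_fraction"] = cover
    return out
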