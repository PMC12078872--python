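"""Worked example on the published soybean germplasm tallies.

The package ships the allele-change tallies of a 750-accession Chinese
soybean panel (wild accessions -> landraces -> released cultivars;
154,088 SNPLDB loci, 559,611 alleles) as plain-text data. Feeding these
printed counts through the summarisation, binning and rate operations
reproduces the panel's derived figures — per-year exclusion/emergence
rates, cross-table margins, chained-fate ratios and the composite
zero/one percentages — and serves as an end-to-end check of the
reporting arithmetic at full scale.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from glac import glac_core as gc
from glac.glac_core import motivator_from_counts, per_year_rates
from glac.tabulate import CrossTable

_DATA = resources.files("glac.data")


def load_panel_summary() -> dict:
    """Per-transition allele-category tallies and universe sizes."""
    with (_DATA / "panel_summary.json").open() as fh:
        return json.load(fh)


def load_cross_table(transition: str) -> CrossTable:
    """Published 12x12 child-by-parent frequency-class grid.

    ``transition`` is "WA->LR" or "LR->RC"; the latter carries the
    restored / LPR companion counts that the compound cells separate.
    """
    name = {"WA->LR": "wa_lr_freq_grid.tsv", "LR->RC": "lr_rc_freq_grid.tsv"}[
        transition
    ]
    with (_DATA / name).open() as fh:
        grid = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    grid = grid.astype(int)
    grid.index = grid.index.astype(str)
    grid.columns = grid.columns.astype(str)
    restored = lpr = None
    if transition == "LR->RC":
        with (_DATA / "lr_rc_companions.tsv").open() as fh:
            comp = pd.read_csv(fh, sep="\t", index_col=0)
        comp.index = comp.index.astype(str)
        restored = comp["restored"]
        lpr = comp["lpr"]
    return CrossTable.from_counts(
        grid, transition=transition,
        restored_by_child_class=restored, lpr_by_child_class=lpr,
    )


def zero_one_rates() -> pd.DataFrame:
    """Per-year allele/locus zero-one change rates for both stages.

    Allele rates are normalised by the allele universe, locus rates by
    the locus universe; per-year values are rounded to 2 decimals and
    per-unit values to 3 significant figures (the reporting convention).
    """
    s = load_panel_summary()
    rows = []
    for label, t in s["transitions"].items():
        counts, years = t["counts"], t["years"]
        for name, n, universe in [
            ("allele_exclusion", counts[gc.EXCLUDED], s["allele_universe"]),
            ("allele_emergence", counts[gc.EMERGED], s["allele_universe"]),
            ("locus_disappeared", counts[gc.INHERITED_LPD], s["locus_universe"]),
            ("locus_emerged", counts[gc.INHERITED_LPE], s["locus_universe"]),
        ]:
            rate = per_year_rates(n, years, universe)
            rows.append(
                {
                    "transition": label,
                    "change": name,
                    "count": n,
                    "per_year": rate.per_year_rounded,
                    "per_year_per_unit": rate.per_unit_3sig,
                }
            )
    return pd.DataFrame(rows).set_index(["transition", "change"])


def motivators(transition: str) -> pd.DataFrame:
    """Evolutionary-motivator grouping of the published tallies."""
    s = load_panel_summary()
    counts = s["transitions"][transition]["counts"]
    return motivator_from_counts(counts, s["allele_universe"])


def composite_zero_one_pct(transition: str) -> float:
    """Share of the allele universe touched by allele/locus zero-one
    change: excluded + emerged + locus-fixing (LPD) + first-decrease
    (LPE) alleles, as the sum of their percentages at printed precision
    (2 decimals each, the panel's reporting convention)."""
    s = load_panel_summary()
    counts = s["transitions"][transition]["counts"]
    universe = s["allele_universe"]
    parts = [
        counts[gc.EXCLUDED],
        counts[gc.EMERGED],
        counts[gc.INHERITED_LPD],
        counts[gc.INHERITED_LPE],
    ]
    return round(sum(round(100.0 * n / universe, 2) for n in parts), 2)


def chained_ratios() -> dict[str, float]:
    """Successive-change ratios across the two stages (percent).

    * permanent exclusion: domestication-excluded alleles still absent
      after modern breeding, as a share of the domestication exclusions;
    * emergence kept: domestication-emerged alleles inherited onward;
    * fixation pathway: final-stage fixed loci explained by loci fixed
      in both stages plus loci whose fixing allele was already rising.
    """
    s = load_panel_summary()
    ch = s["chained"]
    dom = s["transitions"]["WA->LR"]["counts"]
    return {
        "permanently_excluded_pct": round(
            100.0 * ch["excluded_then_absent"] / dom[gc.EXCLUDED], 2
        ),
        "emerged_then_inherited_pct": round(
            100.0 * ch["emerged_then_inherited"] / dom[gc.EMERGED], 2
        ),
        "fixation_pathway_pct": round(
            100.0
            * (ch["loci_fixed_both_stages"] + ch["loci_lpd_after_increase"])
            / ch["loci_fixed_in_final_stage"],
            2,
        ),
    }
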