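import numpy as np
import pandas as pd
import pytest

from glac import glac_core as gc
from glac.glac_core import TransitionSpec
from glac.snpldb import SnpldbLocus
from glac.tabulate import (
    FREQ_CLASS_LABELS,
    bin_frequencies,
    bin_frequency,
    cross_table,
    summarize_transition,
    window_density,
)


class TestBinning:
    @pytest.mark.parametrize(
        "f,label",
        [
            (0.0, "0"),
            (1.0, "1"),
            (0.95, "0.9-0.99"),
            (0.999, "0.9-0.99"),  # (0.9, 1) is open at 1
            (0.05, "0.0-0.1"),
            (0.1, "0.0-0.1"),  # boundary goes to the lower class
            (0.2, "0.1-0.2"),
            (3 / 10, "0.2-0.3"),
            (0.30001, "0.3-0.4"),
            (0.9, "0.8-0.9"),
        ],
    )
    def test_class_limits(self, f, label):
        assert bin_frequency(f) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_frequency(1.2)
        with pytest.raises(ValueError):
            bin_frequencies(np.array([0.5, -0.1]))

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(2)
        f = np.concatenate([rng.uniform(0, 1, 200), [0, 1, 0.1, 0.9, 0.95]])
        idx = bin_frequencies(f)
        for fi, ki in zip(f, idx):
            assert FREQ_CLASS_LABELS[ki] == bin_frequency(fi)

    def test_count_ratios_bin_consistently(self):
        # frequencies arising as count/n must respect the class limits
        for n in range(2, 60):
            for k in range(n + 1):
                lab = bin_frequency(k / n)
                if k == 0:
                    assert lab == "0"
                elif k == n:
                    assert lab == "1"
                else:
                    assert lab not in ("0", "1")


def _fates(rows):
    return pd.DataFrame(
        rows,
        columns=["locus_id", "allele_id", "transition", "category",
                 "parent_freq", "child_freq"],
    )


class TestCrossTable:
    def test_single_allele_placement(self):
        ct = cross_table(_fates([("L1", "A", "t", gc.EXCLUDED, 0.25, 0.0)]))
        assert ct.counts.loc["0", "0.2-0.3"] == 1
        assert ct.total == 1

    def test_toy_set_matches_hand_tally(self):
        rows = [
            ("L1", "A", "t", gc.EXCLUDED, 0.25, 0.0),
            ("L1", "B", "t", gc.INHERITED_INCREASE, 0.35, 0.55),
            ("L2", "A", "t", gc.EMERGED, 0.0, 0.15),
            ("L2", "B", "t", gc.INHERITED_LPD, 0.85, 1.0),
            ("L3", "A", "t", gc.ABSENT_BOTH, 0.0, 0.0),
            ("L3", "B", "t", gc.INHERITED_FIXED, 1.0, 1.0),
        ]
        ct = cross_table(_fates(rows))
        assert ct.total == 6
        assert ct.counts.loc["0", "0.2-0.3"] == 1
        assert ct.counts.loc["0.5-0.6", "0.3-0.4"] == 1
        assert ct.counts.loc["0.1-0.2", "0"] == 1
        assert ct.counts.loc["1", "0.8-0.9"] == 1
        assert ct.counts.loc["0", "0"] == 1
        assert ct.counts.loc["1", "1"] == 1
        assert ct.excluded_total == 1
        assert ct.emerged_total == 1
        assert ct.lpd_total == 1
        assert ct.absent_both_total == 1

    def test_restored_kept_as_companion_not_conflated(self):
        rows = [
            ("L1", "A", "t", gc.EMERGED, 0.0, 0.15),
            ("L2", "A", "t", gc.RESTORED, 0.0, 0.15),
            ("L3", "A", "t", gc.INHERITED_LPE, 1.0, 0.95),
            ("L4", "A", "t", gc.INHERITED_LPR, 1.0, 0.95),
        ]
        ct = cross_table(_fates(rows))
        assert ct.counts.loc["0.1-0.2", "0"] == 2  # both live in column "0"
        assert ct.emerged_total == 1
        assert ct.restored_total == 1
        assert ct.lpe_total == 1
        assert ct.lpr_total == 1

    def test_margin_identities_on_simulated_fates(self, sim_panel):
        fates = sim_panel["fates"]
        for label, grp in fates.groupby("transition"):
            ct = cross_table(grp, transition=label)
            counts = grp["category"].value_counts()
            n_unclass = counts.get(gc.UNCLASSIFIABLE, 0)
            assert ct.total == len(grp) - n_unclass
            assert ct.excluded_total == counts.get(gc.EXCLUDED, 0)
            assert ct.emerged_total == counts.get(gc.EMERGED, 0)
            assert ct.restored_total == counts.get(gc.RESTORED, 0)
            assert ct.lpd_total == counts.get(gc.INHERITED_LPD, 0)
            assert ct.lpe_total == counts.get(gc.INHERITED_LPE, 0)
            assert ct.lpr_total == counts.get(gc.INHERITED_LPR, 0)


class TestSummarize:
    def test_planted_percentages(self):
        rows = (
            [(f"L{i}", "A", "t", gc.EXCLUDED, 0.5, 0.0) for i in range(3)]
            + [("L3", "B", "t", gc.EMERGED, 0.0, 0.5)]
            + [(f"L{i+4}", "A", "t", gc.INHERITED_INCREASE, 0.3, 0.6)
               for i in range(6)]
        )
        fates = _fates(rows)
        locus_fates = pd.DataFrame(
            {"locus_id": [f"L{i}" for i in range(10)], "transition": "t",
             "category": gc.LOCUS_POLY_KEPT}
        )
        rep = summarize_transition(
            fates, locus_fates, TransitionSpec("P", "C", years=10)
        )
        at = rep.allele_table
        assert at.loc["excluded", "count"] == 3
        assert at.loc["excluded", "pct"] == pytest.approx(30.0)
        assert at.loc["emerged", "pct"] == pytest.approx(10.0)
        assert at.loc["inherited", "pct"] == pytest.approx(60.0)

    def test_per_year_block_consistent_with_rate_helper(self, sim_panel):
        from glac.glac_core import per_year_rates

        fates, locus_fates = sim_panel["fates"], sim_panel["locus_fates"]
        spec = sim_panel["specs"][0]
        grp = fates[fates["transition"] == spec.label]
        lf = locus_fates[locus_fates["transition"] == spec.label]
        rep = summarize_transition(grp, lf, spec)
        n_excl = int(rep.zero_one_table.loc["allele_exclusion", "count"])
        rate = per_year_rates(n_excl, spec.years, rep.allele_universe)
        assert rep.zero_one_table.loc["allele_exclusion", "per_year"] == \
            rate.per_year_rounded
        assert rep.zero_one_table.loc["allele_exclusion", "per_year_per_unit"] == \
            rate.per_unit_3sig

    def test_table_identity_counts_sum_to_universe(self, sim_panel):
        fates, locus_fates = sim_panel["fates"], sim_panel["locus_fates"]
        spec = sim_panel["specs"][1]
        grp = fates[fates["transition"] == spec.label]
        lf = locus_fates[locus_fates["transition"] == spec.label]
        rep = summarize_transition(grp, lf, spec)
        at = rep.allele_table
        total = (
            at.loc["inherited", "count"]
            + at.loc["excluded", "count"]
            + at.loc["emerged", "count"]
            + at.loc["restored_from_source", "count"]
            + at.loc["frequency_of_0", "count"]
        )
        assert total == rep.allele_universe


def _locus(lid, chrom, start, end):
    return SnpldbLocus(lid, chrom, start, end, [], [], {}, [])


class TestWindowDensity:
    def test_all_loci_in_one_window(self):
        loci = [_locus(f"L{i}", "c1", 1000 + i, 1100 + i) for i in range(10)]
        fates = _fates([(f"L{i}", "A", "t", gc.EXCLUDED, 0.5, 0.0)
                        for i in range(10)])
        wd = window_density(fates, loci, window_bp=100_000)
        assert len(wd) == 1
        assert wd.iloc[0]["n_loci"] == 10
        assert wd.iloc[0][gc.EXCLUDED] == 10

    def test_split_across_windows(self):
        loci = [_locus(f"L{i}", "c1", 500 + i, 600) for i in range(7)] + [
            _locus(f"L{i+7}", "c1", 1500 + i, 1600) for i in range(3)
        ]
        wd = window_density(_fates([]), loci, window_bp=1000)
        assert list(wd["n_loci"]) == [7, 3]
        assert list(wd["start"]) == [0, 1000]

    def test_annotation_overlap_matches_brute_force(self):
        rng = np.random.default_rng(4)
        loci = [_locus(f"L{i}", "c1", int(p), int(p) + 50)
                for i, p in enumerate(rng.integers(1, 50_000, 40))]
        ann = pd.DataFrame(
            {"chrom": ["c1", "c1"], "start": [0, 20_000], "end": [5_000, 30_000]}
        )
        wd = window_density(_fates([]), loci, window_bp=10_000, annotations=ann)
        for row in wd.itertuples(index=False):
            expected = sum(
                max(0, min(row.end, e) - max(row.start, s))
                for s, e in zip(ann["start"], ann["end"])
            ) / 10_000
            assert row.annotation_fraction == pytest.approx(expected)

    def test_window_counts_conserve_chromosome_totals(self, sim_panel):
        fates = sim_panel["fates"]
        loci = sim_panel["panel"].loci
        label = sim_panel["specs"][0].label
        grp = fates[fates["transition"] == label]
        wd = window_density(grp, loci, window_bp=500_000)
        assert wd["n_loci"].sum() == len(loci)
        if gc.EXCLUDED in wd.columns:
            assert wd[gc.EXCLUDED].sum() == (grp["category"] == gc.EXCLUDED).sum()
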