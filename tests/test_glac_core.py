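import math

import numpy as np
import pandas as pd
import pytest

from glac import glac_core as gc
from glac.glac_core import (
    ConfigError,
    TransitionSpec,
    chain_fates,
    classify_allele,
    classify_transition,
    derive_locus_fates,
    motivator_from_counts,
    per_year_rates,
)

from conftest import make_freq_table


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "p,c,sources,expected",
        [
            (0.4, 0.0, (), gc.EXCLUDED),
            (1.0, 0.0, (), gc.EXCLUDED),
            (0.0, 0.2, (), gc.EMERGED),
            (0.0, 0.2, (0.0,), gc.EMERGED),
            (0.0, 0.2, (0.9,), gc.RESTORED),
            (0.0, 0.0, (), gc.ABSENT_BOTH),
            (1.0, 1.0, (), gc.INHERITED_FIXED),
            (0.6, 1.0, (), gc.INHERITED_LPD),  # frequency increased to 1
            (1.0, 0.95, (), gc.INHERITED_LPE),  # first decrease from 1
            (1.0, 0.95, (1.0,), gc.INHERITED_LPE),
            (1.0, 0.95, (0.9,), gc.INHERITED_LPR),  # polymorphic in a source
            (0.3, 0.7, (), gc.INHERITED_INCREASE),
            (0.7, 0.3, (), gc.INHERITED_DECREASE),
            (0.5, 0.5, (), gc.INHERITED_UNCHANGED),
            (float("nan"), 0.5, (), gc.UNCLASSIFIABLE),
        ],
    )
    def test_predicate_table(self, p, c, sources, expected):
        assert classify_allele(p, c, sources) == expected

    def test_zero_to_positive_never_excluded(self):
        """Raising child frequency from 0 can only leave the excluded class."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(0.01, 1.0)
            assert classify_allele(p, 0.0, ()) == gc.EXCLUDED
            c = rng.uniform(0.01, 1.0)
            assert classify_allele(p, c, ()) != gc.EXCLUDED


class TestClassifyTransition:
    def _freqs(self):
        rows = [
            ("L1", "A", {"WA": 0.4, "LR": 0.0}),
            ("L1", "B", {"WA": 0.6, "LR": 1.0}),
            ("L2", "A", {"WA": 1.0, "LR": 0.95}),
            ("L2", "B", {"WA": 0.0, "LR": 0.05}),
            ("L3", "A", {"WA": 0.5, "LR": 0.7}),
            ("L3", "B", {"WA": 0.5, "LR": 0.3}),
        ]
        return make_freq_table(rows, ["WA", "LR"])

    def test_categories_and_frame_shape(self):
        fates = classify_transition(
            self._freqs(), TransitionSpec("WA", "LR", years=5000)
        )
        by_key = fates.set_index(["locus_id", "allele_id"])["category"]
        assert by_key[("L1", "A")] == gc.EXCLUDED
        assert by_key[("L1", "B")] == gc.INHERITED_LPD
        assert by_key[("L2", "A")] == gc.INHERITED_LPE
        assert by_key[("L2", "B")] == gc.EMERGED
        assert by_key[("L3", "A")] == gc.INHERITED_INCREASE
        assert by_key[("L3", "B")] == gc.INHERITED_DECREASE

    def test_missing_population_raises(self):
        with pytest.raises(KeyError):
            classify_transition(self._freqs(), TransitionSpec("WA", "RC"))

    def test_unclassifiable_propagates_per_locus(self):
        rows = [
            ("L1", "A", {"WA": 0.4, "LR": float("nan"), "ALL": 0.2}),
            ("L1", "B", {"WA": 0.6, "LR": float("nan"), "ALL": 0.8}),
        ]
        ft = make_freq_table(rows, ["WA", "LR"])
        fates = classify_transition(ft, TransitionSpec("WA", "LR"))
        assert (fates["category"] == gc.UNCLASSIFIABLE).all()


class TestLocusFates:
    def _fates(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "locus_id", "allele_id", "transition", "category",
                "parent_freq", "child_freq",
            ],
        )

    def test_exclusion_fixing_partner_disappears_polymorphism(self):
        fates = self._fates([
            ("L1", "A", "t", gc.EXCLUDED, 0.4, 0.0),
            ("L1", "B", "t", gc.INHERITED_LPD, 0.6, 1.0),
        ])
        lf = derive_locus_fates(fates).set_index("locus_id")["category"]
        assert lf["L1"] == gc.LOCUS_DISAPPEARED

    def test_monomorphic_parent_gaining_allele_emerges(self):
        fates = self._fates([
            ("L1", "A", "t", gc.INHERITED_LPE, 1.0, 0.8),
            ("L1", "B", "t", gc.EMERGED, 0.0, 0.2),
        ])
        lf = derive_locus_fates(fates).set_index("locus_id")["category"]
        assert lf["L1"] == gc.LOCUS_EMERGED

    def test_three_allele_locus_losing_one_stays_polymorphic(self):
        fates = self._fates([
            ("L1", "A", "t", gc.INHERITED_INCREASE, 0.5, 0.6),
            ("L1", "B", "t", gc.INHERITED_INCREASE, 0.3, 0.4),
            ("L1", "C", "t", gc.EXCLUDED, 0.2, 0.0),
        ])
        lf = derive_locus_fates(fates).set_index("locus_id")["category"]
        assert lf["L1"] == gc.LOCUS_POLY_KEPT

    def test_fixed_replaced_corner_case(self):
        fates = self._fates([
            ("L1", "A", "t", gc.EXCLUDED, 1.0, 0.0),
            ("L1", "B", "t", gc.EMERGED, 0.0, 1.0),
        ])
        lf = derive_locus_fates(fates).set_index("locus_id")["category"]
        assert lf["L1"] == gc.LOCUS_FIXED_REPLACED

    def test_fixed_kept(self):
        fates = self._fates([
            ("L1", "A", "t", gc.INHERITED_FIXED, 1.0, 1.0),
            ("L1", "B", "t", gc.ABSENT_BOTH, 0.0, 0.0),
        ])
        lf = derive_locus_fates(fates).set_index("locus_id")["category"]
        assert lf["L1"] == gc.LOCUS_FIXED_KEPT


class TestChainFates:
    def _freqs(self, wa, lr, rc):
        rows = [("L1", "A", {"WA": wa, "LR": lr, "RC": rc, "ALL": 0.5}),
                ("L1", "B", {"WA": 1 - wa if wa < 1 else 0.0,
                             "LR": 1 - lr if lr > 0 else 1.0,
                             "RC": 1 - rc if rc > 0 else 1.0,
                             "ALL": 0.5})]
        return make_freq_table(rows, ["WA", "LR", "RC"])

    def _specs(self, sources_rc=()):
        return [
            TransitionSpec("WA", "LR", years=5000),
            TransitionSpec("LR", "RC", years=100,
                           restoration_sources=sources_rc),
        ]

    def test_permanent_exclusion(self):
        # present in the wild stage only: excluded and never seen again
        chains = chain_fates(self._freqs(0.3, 0.0, 0.0), self._specs())
        row = chains.set_index("allele_id").loc["A"]
        assert row["categories"][0] == gc.EXCLUDED
        assert row["permanently_excluded"]

    def test_emerged_then_inherited(self):
        chains = chain_fates(self._freqs(0.0, 0.1, 0.2), self._specs())
        row = chains.set_index("allele_id").loc["A"]
        assert row["categories"] == (gc.EMERGED, gc.INHERITED_INCREASE)
        assert row["emerged_then_inherited"]
        assert not row["permanently_excluded"]

    def test_restoration_from_direct_parent_source(self):
        chains = chain_fates(
            self._freqs(0.5, 0.0, 0.3), self._specs(sources_rc=("WA",))
        )
        row = chains.set_index("allele_id").loc["A"]
        assert row["categories"] == (gc.EXCLUDED, gc.RESTORED)

    def test_exclusion_after_decrease_flag(self):
        chains = chain_fates(self._freqs(0.6, 0.3, 0.0), self._specs())
        row = chains.set_index("allele_id").loc["A"]
        assert row["categories"] == (gc.INHERITED_DECREASE, gc.EXCLUDED)
        assert row["exclusion_after_decrease"]

    def test_non_contiguous_specs_rejected(self):
        specs = [TransitionSpec("WA", "LR"), TransitionSpec("RC", "XX")]
        with pytest.raises(ConfigError, match="contiguous"):
            chain_fates(self._freqs(0.3, 0.0, 0.0), specs)


class TestPerYearRates:
    def test_domestication_exclusion_rate(self):
        rate = per_year_rates(76_866, 5000, 559_611)
        assert rate.per_year_rounded == 15.37
        assert rate.per_unit_3sig == pytest.approx(2.75e-5)

    def test_modern_breeding_exclusion_rate(self):
        rate = per_year_rates(79_573, 100, 559_611)
        assert rate.per_year_rounded == 795.73
        assert rate.per_unit_3sig == pytest.approx(1.42e-3)

    def test_zero_count(self):
        rate = per_year_rates(0, 100, 10)
        assert (rate.per_year, rate.per_year_per_unit) == (0.0, 0.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            per_year_rates(-1, 100, 10)


class TestMotivators:
    def test_exclusion_group_combines_alleles_and_fixing_loci(self):
        m = motivator_from_counts(
            {gc.EXCLUDED: 76_866, gc.INHERITED_LPD: 23_670}, 559_611
        )
        assert round(m.loc["exclusion", "pct"], 2) == 17.97
        assert round(m.loc["exclusion", "pct_allele"], 2) == 13.74
        assert round(m.loc["exclusion", "pct_star"], 2) == 4.23

    def test_all_fixed_is_pure_no_change(self):
        m = motivator_from_counts({gc.INHERITED_FIXED: 50}, 50)
        assert m.loc["no_change", "pct"] == 100.0
        assert m.drop("no_change")["count"].sum() == 0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        cats = rng.choice(gc.ALLELE_CATEGORIES, size=500)
        counts = pd.Series(cats).value_counts().to_dict()
        m = motivator_from_counts(counts, 500)
        for group, plain, star in gc.MOTIVATOR_GROUPS:
            expected = sum(1 for c in cats if c in (plain, star))
            assert m.loc[group, "count"] == expected
        assert m["count"].sum() == 500


class TestPartitionIdentities:
    """Bookkeeping identities on the simulated panel (every transition)."""

    def test_fate_counts_sum_to_universe(self, sim_panel):
        fates = sim_panel["fates"]
        universe = sim_panel["panel"].freqs.freq.shape[0]
        for _, grp in fates.groupby("transition"):
            assert len(grp) == universe

    def test_child_allele_count_identity(self, sim_panel):
        fates = sim_panel["fates"]
        for _, grp in fates.groupby("transition"):
            present_child = int((grp["child_freq"] > 0).sum())
            counts = grp["category"].value_counts()
            inherited = sum(counts.get(c, 0) for c in gc.INHERITED_CATEGORIES)
            assert present_child == inherited + counts.get(gc.EMERGED, 0) + \
                counts.get(gc.RESTORED, 0)

    def test_locus_zero_one_matches_allele_counts(self, sim_panel):
        fates, locus_fates = sim_panel["fates"], sim_panel["locus_fates"]
        for label, grp in fates.groupby("transition"):
            lf = locus_fates[locus_fates["transition"] == label]
            lcounts = lf["category"].value_counts()
            acounts = grp["category"].value_counts()
            assert lcounts.get(gc.LOCUS_DISAPPEARED, 0) == acounts.get(
                gc.INHERITED_LPD, 0
            )
            assert lcounts.get(gc.LOCUS_EMERGED, 0) == acounts.get(
                gc.INHERITED_LPE, 0
            )
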