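"""Allele-fate classification across ordered population stages.

Every allele of the whole-sample universe is classified at each
ancestor->descendant transition by its parent frequency p and child
frequency c:

* ``excluded``        p > 0, c = 0 (allele zero/one change, loss)
* ``emerged``         p = 0, c > 0, and absent from every restoration source
* ``restored``        p = 0, c > 0, present in >= 1 restoration source
* ``absent_both``     p = 0, c = 0 (frequency kept at 0)
* inherited (p > 0, c > 0), subdivided:
  - ``inherited_fixed``      p = 1, c = 1 (locus fixation kept)
  - ``inherited_LPD``        p < 1, c = 1 (locus polymorphism disappeared)
  - ``inherited_LPE``        p = 1, c < 1, fixed in all restoration sources
                             (first decrease from 1: polymorphism emerged)
  - ``inherited_LPR``        p = 1, c < 1, polymorphic in some source
                             (polymorphism restored, not new)
  - ``inherited_increase``   p < c < 1 (ordinary frequency increase)
  - ``inherited_decrease``   c < p, c < 1 (ordinary frequency decrease)
  - ``inherited_unchanged``  0 < p = c < 1 (tie, surfaced separately)

Loci where either population has only missing calls are flagged
``unclassifiable`` and excluded from percentage denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glac.snpldb import WHOLE_SAMPLE, AlleleFrequencyTable

EXCLUDED = "excluded"
EMERGED = "emerged"
RESTORED = "restored"
ABSENT_BOTH = "absent_both"
INHERITED_FIXED = "inherited_fixed"
INHERITED_LPD = "inherited_LPD"
INHERITED_LPE = "inherited_LPE"
INHERITED_LPR = "inherited_LPR"
INHERITED_INCREASE = "inherited_increase"
INHERITED_DECREASE = "inherited_decrease"
INHERITED_UNCHANGED = "inherited_unchanged"
UNCLASSIFIABLE = "unclassifiable"

ALLELE_CATEGORIES = [
    EXCLUDED,
    EMERGED,
    RESTORED,
    ABSENT_BOTH,
    INHERITED_FIXED,
    INHERITED_LPD,
    INHERITED_LPE,
    INHERITED_LPR,
    INHERITED_INCREASE,
    INHERITED_DECREASE,
    INHERITED_UNCHANGED,
]
INHERITED_CATEGORIES = [
    INHERITED_FIXED,
    INHERITED_LPD,
    INHERITED_LPE,
    INHERITED_LPR,
    INHERITED_INCREASE,
    INHERITED_DECREASE,
    INHERITED_UNCHANGED,
]

# locus-level categories
LOCUS_DISAPPEARED = "polymorphism_disappeared"
LOCUS_EMERGED = "polymorphism_emerged"
LOCUS_RESTORED = "polymorphism_restored"
LOCUS_FIXED_KEPT = "fixed_kept"
LOCUS_POLY_KEPT = "polymorphic_kept"
LOCUS_ABSENT = "absent"
LOCUS_FIXED_REPLACED = "fixed_replaced"


class ConfigError(ValueError):
    """Inconsistent stage-graph configuration."""


@dataclass
class TransitionSpec:
    """One ancestor->descendant comparison.

    ``restoration_sources`` lists earlier stage labels whose alleles can
    re-enter the child (e.g. wild accessions used as direct breeding
    parents); for a first-stage transition it is empty. ``years`` is the
    calendar span of the transition, used for per-year rates.
    """

    parent: str
    child: str
    years: float = 1.0
    restoration_sources: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.parent == self.child:
            raise ConfigError(f"parent == child ({self.parent!r})")
        if self.years <= 0:
            raise ConfigError(f"years must be > 0, got {self.years}")
        self.restoration_sources = tuple(self.restoration_sources)
        if not self.label:
            self.label = f"{self.parent}->{self.child}"


def classify_allele(p: float, c: float, source_freqs: tuple[float, ...]) -> str:
    """Fate of one allele from its parent/child/source frequencies."""
    if math.isnan(p) or math.isnan(c) or any(math.isnan(s) for s in source_freqs):
        return UNCLASSIFIABLE
    if p > 0 and c == 0:
        return EXCLUDED
    if p == 0 and c > 0:
        return RESTORED if any(s > 0 for s in source_freqs) else EMERGED
    if p == 0 and c == 0:
        return ABSENT_BOTH
    # inherited: p > 0 and c > 0
    if p == 1 and c == 1:
        return INHERITED_FIXED
    if p < 1 and c == 1:
        return INHERITED_LPD
    if p == 1 and c < 1:
        if all(s == 1 for s in source_freqs):
            return INHERITED_LPE
        return INHERITED_LPR
    if p < c:
        return INHERITED_INCREASE
    if c < p:
        return INHERITED_DECREASE
    return INHERITED_UNCHANGED


def classify_transition(
    freqs: AlleleFrequencyTable, spec: TransitionSpec
) -> pd.DataFrame:
    """Classify every universe allele for one transition.

    Returns a frame with columns locus_id, allele_id, transition,
    category, parent_freq, child_freq. The universe is every allele with
    whole-sample frequency > 0.
    """
    for pop in (spec.parent, spec.child, *spec.restoration_sources):
        if pop not in freqs.freq.columns:
            raise KeyError(f"population {pop!r} absent from frequency table")
    table = freqs.freq[freqs.freq[WHOLE_SAMPLE] > 0]
    p = table[spec.parent].to_numpy(float)
    c = table[spec.child].to_numpy(float)
    sources = [table[s].to_numpy(float) for s in spec.restoration_sources]
    cats = [
        classify_allele(pi, ci, tuple(col[i] for col in sources))
        for i, (pi, ci) in enumerate(zip(p, c))
    ]
    out = pd.DataFrame(
        {
            "locus_id": table.index.get_level_values("locus_id"),
            "allele_id": table.index.get_level_values("allele_id"),
            "transition": spec.label,
            "category": cats,
            "parent_freq": p,
            "child_freq": c,
        }
    )
    return out


def derive_locus_fates(fates: pd.DataFrame) -> pd.DataFrame:
    """Locus-level fate from the complete allele fates of one transition.

    A locus polymorphism disappears iff one of its inherited alleles
    reached frequency 1 (inherited_LPD); it emerges iff an inherited
    allele first decreased from 1 (inherited_LPE); LPR likewise. A locus
    monomorphic on both sides keeps (or replaces) its fixed allele.
    """
    records = []
    for (locus_id, transition), grp in fates.groupby(
        ["locus_id", "transition"], sort=False
    ):
        cats = set(grp["category"])
        if cats == {UNCLASSIFIABLE}:
            cat = LOCUS_ABSENT
        elif INHERITED_LPD in cats:
            cat = LOCUS_DISAPPEARED
        elif INHERITED_LPE in cats:
            cat = LOCUS_EMERGED
        elif INHERITED_LPR in cats:
            cat = LOCUS_RESTORED
        else:
            present_parent = grp.loc[grp["parent_freq"] > 0, "allele_id"]
            present_child = grp.loc[grp["child_freq"] > 0, "allele_id"]
            if len(present_parent) <= 1 and len(present_child) <= 1:
                same = set(present_parent) == set(present_child)
                cat = LOCUS_FIXED_KEPT if same else LOCUS_FIXED_REPLACED
            elif len(present_child) == 1:
                # child fixed at an allele absent from the parent
                cat = LOCUS_FIXED_REPLACED
            else:
                cat = LOCUS_POLY_KEPT
        records.append((locus_id, transition, cat))
    return pd.DataFrame(records, columns=["locus_id", "transition", "category"])


def chain_fates(
    freqs: AlleleFrequencyTable, specs: list[TransitionSpec]
) -> pd.DataFrame:
    """Join per-transition fates along a stage path and derive flags.

    ``specs`` must form a contiguous path (child of one = parent of the
    next). Returns one row per (locus, allele) with a ``categories``
    tuple in path order and boolean flags:

    * ``permanently_excluded``: excluded at some step and frequency 0 at
      every later stage;
    * ``emerged_then_inherited``: emerged at some step and inherited
      (p>0, c>0) at every later step;
    * ``exclusion_after_decrease``: excluded at step k with an ordinary
      decrease at step k-1;
    * ``fixation_after_increase``: locus-fixing increase (LPD) at step k
      with an ordinary increase at step k-1.
    """
    for a, b in zip(specs, specs[1:]):
        if a.child != b.parent:
            raise ConfigError(
                f"transitions not contiguous: {a.label!r} then {b.label!r}"
            )
    per_step = [classify_transition(freqs, s) for s in specs]
    n_steps = len(specs)
    cats_by_key: dict[tuple[str, str], list[str]] = {}
    child_freqs: dict[tuple[str, str], list[float]] = {}
    for step, df in enumerate(per_step):
        for row in df.itertuples(index=False):
            key = (row.locus_id, row.allele_id)
            cats_by_key.setdefault(key, [None] * n_steps)[step] = row.category
            child_freqs.setdefault(key, [np.nan] * n_steps)[step] = row.child_freq

    inherited = set(INHERITED_CATEGORIES)
    records = []
    for key, cats in cats_by_key.items():
        cf = child_freqs[key]
        perm_excl = any(
            cats[k] == EXCLUDED and all(f == 0 for f in cf[k:] if not math.isnan(f))
            for k in range(n_steps)
        )
        emerged_inh = any(
            cats[k] == EMERGED
            and all(c in inherited for c in cats[k + 1:])
            for k in range(n_steps)
        )
        excl_after_dec = any(
            cats[k] == EXCLUDED and cats[k - 1] == INHERITED_DECREASE
            for k in range(1, n_steps)
        )
        fix_after_inc = any(
            cats[k] == INHERITED_LPD and cats[k - 1] == INHERITED_INCREASE
            for k in range(1, n_steps)
        )
        records.append(
            (
                key[0],
                key[1],
                tuple(cats),
                perm_excl,
                emerged_inh,
                excl_after_dec,
                fix_after_inc,
            )
        )
    return pd.DataFrame(
        records,
        columns=[
            "locus_id",
            "allele_id",
            "categories",
            "permanently_excluded",
            "emerged_then_inherited",
            "exclusion_after_decrease",
            "fixation_after_increase",
        ],
    )


@dataclass
class PerYearRate:
    """A count expressed per year and per year per universe unit."""

    per_year: float
    per_year_per_unit: float

    @property
    def per_year_rounded(self) -> float:
        return round(self.per_year, 2)

    @property
    def per_unit_3sig(self) -> float:
        x = self.per_year_per_unit
        if x == 0:
            return 0.0
        return round(x, -int(math.floor(math.log10(abs(x)))) + 2)

    def __iter__(self):
        return iter((self.per_year, self.per_year_per_unit))


def per_year_rates(count: int, years: float, universe: int) -> PerYearRate:
    """Per-year change rate and its per-universe-unit normalisation.

    Reporting convention: the per-year rate is printed to 2 decimals and
    the per-unit rate to 3 significant figures.
    """
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if years <= 0 or universe <= 0:
        raise ValueError("years and universe must be positive")
    per_year = count / years
    return PerYearRate(per_year=per_year, per_year_per_unit=per_year / universe)


# evolutionary-motivator groups: (group, plain-allele member, starred member)
MOTIVATOR_GROUPS = [
    ("exclusion", EXCLUDED, INHERITED_LPD),
    ("emergence", EMERGED, INHERITED_LPE),
    ("restoration", RESTORED, INHERITED_LPR),
    ("ordinary", INHERITED_INCREASE, INHERITED_DECREASE),
    ("no_change", ABSENT_BOTH, INHERITED_FIXED),
]


def motivator_from_counts(counts: dict[str, int], universe: int) -> pd.DataFrame:
    """Group per-category allele counts into evolutionary motivators.

    Exclusion = excluded alleles + inherited alleles fixing their locus
    (LPD); emergence = emerged + first-decrease-from-1 (LPE);
    restoration = directly restored + LPR; ordinary = frequency increase
    + decrease; no-change = frequency kept at 0 + kept at 1. Percentages
    are of the allele universe; components are reported separately
    ("allele + allele*"). Unchanged ties, if any, appear as their own row.
    """
    rows = []
    for group, plain, star in MOTIVATOR_GROUPS:
        n_plain = counts.get(plain, 0)
        n_star = counts.get(star, 0)
        rows.append(
            {
                "group": group,
                "count": n_plain + n_star,
                "pct": 100.0 * (n_plain + n_star) / universe,
                "count_allele": n_plain,
                "pct_allele": 100.0 * n_plain / universe,
                "count_star": n_star,
                "pct_star": 100.0 * n_star / universe,
            }
        )
    n_tie = counts.get(INHERITED_UNCHANGED, 0)
    if n_tie:
        rows.append(
            {
                "group": "unchanged_tie",
                "count": n_tie,
                "pct": 100.0 * n_tie / universe,
                "count_allele": n_tie,
                "pct_allele": 100.0 * n_tie / universe,
                "count_star": 0,
                "pct_star": 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def motivator_summary(fates: pd.DataFrame, universe: int | None = None) -> pd.DataFrame:
    """Motivator grouping from a classified fate table (one transition)."""
    counts = fates["category"].value_counts().to_dict()
    if universe is None:
        universe = int(sum(v for k, v in counts.items() if k != UNCLASSIFIABLE))
    return motivator_from_counts(counts, universe)


def category_counts(fates: pd.DataFrame) -> dict[str, int]:
    """Tally of allele categories (including unclassifiable)."""
    return fates["category"].value_counts().to_dict()
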