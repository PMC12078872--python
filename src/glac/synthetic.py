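"""Multi-stage population simulator with planted allele fates.

Generates an inbred panel across an ordered path of population stages
(e.g. wild accessions -> landraces -> released cultivars) with exact,
planted allele-fate events per transition — exclusions, emergences,
restorations from earlier stages, locus polymorphism loss/gain/restore,
and ordinary frequency shifts — plus background loci with optional
drift, heterozygous-call noise and missingness. Output is a VCF, a
sample manifest and a ground-truth fate table, so the whole pipeline is
testable without any external data.

Design notes
------------
* Planted frequencies are realised as exact accession counts, so the
  noiseless pipeline recovers every planted category deterministically.
* Each locus's allele catalogue is a "staircase" of haplotypes
  ``h_m = '1'*m + '0'*(k-m)`` over its k constituent SNPs. Any subset of
  staircase haplotypes gives |D'| = 1 for every SNP pair, so the LD
  partition recovers the planted loci exactly, and adjacent staircase
  levels differ at exactly one SNP, which is how emerged alleles are
  created (a one-SNP mutation of an existing haplotype).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glac.glac_core import (
    ABSENT_BOTH,
    EMERGED,
    EXCLUDED,
    INHERITED_DECREASE,
    INHERITED_FIXED,
    INHERITED_INCREASE,
    INHERITED_LPD,
    INHERITED_LPE,
    INHERITED_LPR,
    INHERITED_UNCHANGED,
    RESTORED,
    ConfigError,
    TransitionSpec,
    UNCLASSIFIABLE,
)

PLANT_CATEGORIES = ("excluded", "emerged", "restored", "lpd", "lpe", "lpr", "ordinary")


@dataclass
class StageSpec:
    label: str
    n_accessions: int


@dataclass
class SimConfig:
    """Simulation plan for an ordered stage path.

    ``planted`` holds one dict per transition mapping a plant kind
    (excluded, emerged, restored, lpd, lpe, lpr, ordinary) to the number
    of dedicated loci carrying that event. ``restoration_sources`` maps
    a transition index to the earlier stage labels that can donate
    alleles back (required for restored / lpr plants). Background loci
    are polymorphic everywhere; with ``drift`` > 0 their frequencies
    random-walk between stages (planted loci never drift).
    """

    stages: list[StageSpec]
    planted: list[dict[str, int]]
    years: list[float]
    restoration_sources: dict[int, list[str]] = field(default_factory=dict)
    n_background: int = 100
    missing_rate: float = 0.0
    het_rate: float = 0.0
    drift: float = 0.0
    seed: int = 0
    n_chromosomes: int = 5
    locus_spacing_bp: int = 200_000
    snp_spacing_bp: int = 50

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ConfigError("need at least two stages")
        if len(self.planted) != len(self.stages) - 1:
            raise ConfigError(
                f"planted has {len(self.planted)} entries for "
                f"{len(self.stages) - 1} transitions"
            )
        if len(self.years) != len(self.stages) - 1:
            raise ConfigError("years must have one entry per transition")
        labels = [s.label for s in self.stages]
        if len(set(labels)) != len(labels):
            raise ConfigError("stage labels must be unique")
        for t, plan in enumerate(self.planted):
            for kind, n in plan.items():
                if kind not in PLANT_CATEGORIES:
                    raise ConfigError(f"unknown plant kind {kind!r}")
                if n < 0:
                    raise ConfigError(f"negative plant count for {kind!r}")
            needs_source = plan.get("restored", 0) or plan.get("lpr", 0)
            if needs_source:
                sources = self.restoration_sources.get(t, [])
                earlier = labels[: t + 1]
                if not sources:
                    raise ConfigError(
                        f"transition {t} ({labels[t]}->{labels[t + 1]}) plants "
                        "restored/lpr loci but has no restoration source"
                    )
                bad = [s for s in sources if s not in earlier]
                if bad:
                    raise ConfigError(
                        f"restoration sources {bad} are not earlier stages of "
                        f"transition {t}"
                    )
                if t == 0:
                    raise ConfigError(
                        "restored/lpr cannot be planted on the first transition: "
                        "no earlier stage exists to restore from"
                    )

    @property
    def n_loci(self) -> int:
        return self.n_background + sum(
            sum(plan.values()) for plan in self.planted
        )

    def transition_specs(self) -> list[TransitionSpec]:
        """Classification specs matching the simulated stage graph."""
        labels = [s.label for s in self.stages]
        return [
            TransitionSpec(
                parent=labels[t],
                child=labels[t + 1],
                years=self.years[t],
                restoration_sources=tuple(self.restoration_sources.get(t, [])),
            )
            for t in range(len(labels) - 1)
        ]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a simulation plan from a YAML file."""
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        stages = [StageSpec(s["label"], int(s["n"])) for s in doc["stages"]]
        kwargs = {
            k: doc[k]
            for k in (
                "n_background", "missing_rate", "het_rate", "drift", "seed",
                "n_chromosomes", "locus_spacing_bp", "snp_spacing_bp",
            )
            if k in doc
        }
        return cls(
            stages=stages,
            planted=[dict(p) for p in doc["planted"]],
            years=[float(y) for y in doc["years"]],
            restoration_sources={
                int(k): list(v)
                for k, v in (doc.get("restoration_sources") or {}).items()
            },
            **kwargs,
        )

    @classmethod
    def default(cls, seed: int = 0) -> "SimConfig":
        """Three-stage plan mirroring a wild -> landrace -> cultivar panel
        (127/424/199 accessions; 5000- and 100-year transitions)."""
        return cls(
            stages=[StageSpec("WA", 127), StageSpec("LR", 424), StageSpec("RC", 199)],
            planted=[
                {"excluded": 30, "emerged": 20, "lpd": 15, "lpe": 5, "ordinary": 40},
                {"excluded": 30, "emerged": 5, "restored": 10, "lpr": 8, "lpd": 15,
                 "ordinary": 40},
            ],
            years=[5000.0, 100.0],
            restoration_sources={1: ["WA"]},
            n_background=100,
            seed=seed,
        )


@dataclass
class SimResult:
    vcf_path: Path
    manifest_path: Path
    truth_path: Path
    truth: pd.DataFrame
    config: SimConfig


def _exact_counts(fractions: dict[int, float], n: int) -> dict[int, int]:
    """Integer allele counts summing to n, largest-remainder rounding."""
    items = sorted(fractions.items())
    raw = [(a, f * n) for a, f in items]
    counts = {a: int(math.floor(x)) for a, x in raw}
    rem = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda t: (-(t[1] - math.floor(t[1])), t[0]))
    for a, _ in by_frac[:rem]:
        counts[a] += 1
    return {a: c for a, c in counts.items() if c > 0}


def _locus_plan(kind: str, t: int, n_stages: int) -> list[dict[int, float]]:
    """Per-stage allele-frequency plan for one planted locus.

    Alleles are staircase levels (ints). Transition t runs from stage t
    to stage t+1.
    """
    before_t = lambda plan: [plan] * (t + 1)  # stages 0..t (parent side)
    after_t = lambda plan: [plan] * (n_stages - t - 1)  # stages t+1..

    if kind == "excluded":
        return before_t({0: 0.5, 1: 0.3, 2: 0.2}) + after_t({0: 0.6, 1: 0.4})
    if kind == "emerged":
        return before_t({0: 0.6, 1: 0.4}) + after_t({0: 0.5, 1: 0.3, 2: 0.2})
    if kind == "restored":
        return (
            [{0: 0.4, 1: 0.3, 2: 0.3}]
            + [{0: 0.6, 1: 0.4}] * t
            + after_t({0: 0.5, 1: 0.3, 2: 0.2})
        )
    if kind == "lpd":
        return before_t({0: 0.7, 1: 0.3}) + after_t({0: 1.0})
    if kind == "lpe":
        return before_t({0: 1.0}) + after_t({0: 0.8, 1: 0.2})
    if kind == "lpr":
        return (
            [{0: 0.7, 1: 0.3}]
            + [{0: 1.0}] * t
            + after_t({0: 0.8, 1: 0.2})
        )
    if kind == "ordinary":
        return before_t({0: 0.4, 1: 0.6}) + after_t({0: 0.6, 1: 0.4})
    raise ConfigError(f"unknown plant kind {kind!r}")


def _background_plan(rng: np.random.Generator, n_stages: int,
                     drift: float, sizes: list[int]) -> list[dict[int, float]]:
    """A 3-allele locus, stable or drifting between stages."""
    base = {0: 0.5, 1: 0.3, 2: 0.2}
    if drift <= 0:
        return [dict(base)] * n_stages
    plans = [dict(base)]
    for s in range(1, n_stages):
        prev = plans[-1]
        n = sizes[s]
        new = {}
        for a, p in prev.items():
            sd = drift * math.sqrt(max(p * (1 - p), 1e-6) / n)
            new[a] = min(max(p + rng.normal(0, sd), 0.02), 0.95)
        tot = sum(new.values())
        plans.append({a: v / tot for a, v in new.items()})
    return plans


def _categorize(p: float, c: float, sources: list[float]) -> str:
    """Planted-truth fate from planned frequencies (definitional rules,
    kept local so the truth table does not depend on the pipeline)."""
    if p > 0 and c == 0:
        return EXCLUDED
    if p == 0 and c > 0:
        return RESTORED if any(s > 0 for s in sources) else EMERGED
    if p == 0 and c == 0:
        return ABSENT_BOTH
    if p == 1 and c == 1:
        return INHERITED_FIXED
    if p < 1 and c == 1:
        return INHERITED_LPD
    if p == 1 and c < 1:
        return INHERITED_LPE if all(s == 1 for s in sources) else INHERITED_LPR
    if p < c:
        return INHERITED_INCREASE
    if c < p:
        return INHERITED_DECREASE
    return INHERITED_UNCHANGED


_BASES = ("A", "C", "G", "T")


def simulate_history(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Simulate the panel and write VCF + manifest + truth table.

    Deterministic for a fixed seed; the emitted VCF round-trips through
    ``glac.genotype_io.read_vcf`` and the planted loci through the
    SNPLDB partition (use ``min_maf=0`` and ``rare_threshold=0`` for
    exact noiseless recovery of low-frequency planted alleles).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_stages = len(config.stages)
    sizes = [s.n_accessions for s in config.stages]
    labels = [s.label for s in config.stages]

    # build the locus roster: (kind, transition index or None)
    roster: list[tuple[str, int | None]] = []
    for t, plan in enumerate(config.planted):
        for kind in PLANT_CATEGORIES:
            roster.extend([(kind, t)] * plan.get(kind, 0))
    roster.extend([("background", None)] * config.n_background)
    order = rng.permutation(len(roster))
    roster = [roster[i] for i in order]

    # per-locus stage plans (allele level -> frequency)
    plans: list[list[dict[int, float]]] = []
    for kind, t in roster:
        if kind == "background":
            plans.append(_background_plan(rng, n_stages, config.drift, sizes))
        else:
            plans.append(_locus_plan(kind, t, n_stages))

    # realised per-stage counts and frequencies
    stage_counts = [
        [_exact_counts(plan[s], sizes[s]) for s in range(n_stages)] for plan in plans
    ]
    stage_freqs = [
        [
            {a: cnt / sizes[s] for a, cnt in stage_counts[i][s].items()}
            for s in range(n_stages)
        ]
        for i in range(len(plans))
    ]

    # geometry: loci laid out round-robin on chromosomes, spaced so that
    # the LD partition can never bridge adjacent loci
    geom = []  # (chrom, [snp positions], k)
    per_chrom_count: dict[str, int] = {}
    for i in range(len(plans)):
        levels = sorted({a for s in range(n_stages) for a in stage_counts[i][s]})
        k = max(1, max(levels))  # staircase level m needs m SNPs set
        chrom = f"Chr{(i % config.n_chromosomes) + 1:02d}"
        j = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = j + 1
        start = 10_000 + j * config.locus_spacing_bp
        positions = [start + m * config.snp_spacing_bp for m in range(k)]
        geom.append((chrom, positions, k))

    # accession roster
    samples: list[str] = []
    sample_stage: list[int] = []
    for s, stage in enumerate(config.stages):
        for a in range(stage.n_accessions):
            samples.append(f"{stage.label}_{a + 1:03d}")
            sample_stage.append(s)
    n_samples = len(samples)

    def hap_string(level: int, k: int) -> str:
        return "1" * level + "0" * (k - level)

    # assign alleles to accessions (exact counts, seeded shuffle per locus)
    locus_alleles = np.empty((len(plans), n_samples), dtype=np.int16)
    for i in range(len(plans)):
        for s in range(n_stages):
            members = [j for j in range(n_samples) if sample_stage[j] == s]
            pool: list[int] = []
            for a, cnt in sorted(stage_counts[i][s].items()):
                pool.extend([a] * cnt)
            pool = list(rng.permutation(pool))
            for j, a in zip(members, pool):
                locus_alleles[i, j] = a

    # noise masks per (locus, accession)
    miss_mask = (
        rng.random((len(plans), n_samples)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((len(plans), n_samples), dtype=bool)
    )
    het_mask = (
        (rng.random((len(plans), n_samples)) < config.het_rate) & ~miss_mask
        if config.het_rate > 0
        else np.zeros((len(plans), n_samples), dtype=bool)
    )

    # emit VCF
    vcf_path = out_dir / "panel.vcf"
    chrom_order = [f"Chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_order}
    for i, (chrom, positions, k) in enumerate(geom):
        for m, posn in enumerate(positions):
            by_chrom[chrom].append((posn, i, m))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom in chrom_order:
            for posn, i, m in sorted(by_chrom[chrom]):
                k = geom[i][2]
                ref = _BASES[(i + m) % 4]
                alt = _BASES[(i + m + 1) % 4]
                het_snp = int(rng.integers(k)) if het_mask[i].any() else 0
                gts = []
                for j in range(n_samples):
                    if miss_mask[i, j]:
                        gts.append("./.")
                    elif het_mask[i, j] and m == het_snp:
                        gts.append("0/1")
                    else:
                        bit = hap_string(int(locus_alleles[i, j]), k)[m]
                        gts.append("1/1" if bit == "1" else "0/0")
                fh.write(
                    f"{chrom}\t{posn}\t{chrom}_{posn}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )

    # manifest
    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        for j, name in enumerate(samples):
            fh.write(f"{name}\t{labels[sample_stage[j]]}\n")

    # ground truth over the full allele universe
    stage_index = {lab: s for s, lab in enumerate(labels)}
    truth_rows = []
    specs = config.transition_specs()
    for i, (chrom, positions, k) in enumerate(geom):
        locus_id = f"{chrom}:{positions[0]}-{positions[-1]}"
        universe = sorted({a for s in range(n_stages) for a in stage_counts[i][s]})
        for t, spec in enumerate(specs):
            srcs = [stage_index[lab] for lab in spec.restoration_sources]
            for a in universe:
                p = stage_freqs[i][t].get(a, 0.0)
                c = stage_freqs[i][t + 1].get(a, 0.0)
                cat = _categorize(p, c, [stage_freqs[i][s].get(a, 0.0) for s in srcs])
                truth_rows.append(
                    (
                        locus_id,
                        hap_string(a, k),
                        spec.label,
                        cat,
                        p,
                        c,
                        roster[i][0] if roster[i][1] == t else "",
                    )
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "locus_id",
            "allele_id",
            "transition",
            "category",
            "parent_freq",
            "child_freq",
            "planted_kind",
        ],
    )
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(
        vcf_path=vcf_path,
        manifest_path=manifest_path,
        truth_path=truth_path,
        truth=truth,
        config=config,
    )


class IdentifierMismatchError(ValueError):
    """Truth and called fate tables disagree on locus/allele identifiers."""


@dataclass
class RecoveryReport:
    """Planted-vs-called confusion matrix and bookkeeping."""

    confusion: pd.DataFrame  # rows: planted category, cols: called
    n_total: int
    n_unclassifiable: int
    unclassifiable: pd.DataFrame

    @property
    def n_mismatch(self) -> int:
        """Off-diagonal count, the unclassifiable column excluded."""
        off = 0
        for planted in self.confusion.index:
            for called in self.confusion.columns:
                if called == UNCLASSIFIABLE or called == planted:
                    continue
                off += int(self.confusion.loc[planted, called])
        return off

    @property
    def recovery_rate(self) -> float:
        classified = self.n_total - self.n_unclassifiable
        if classified == 0:
            return float("nan")
        return 1.0 - self.n_mismatch / classified


def verify_recovery(truth: pd.DataFrame, fates: pd.DataFrame) -> RecoveryReport:
    """Compare planted truth with pipeline-called fates.

    Raises ``IdentifierMismatchError`` when the (locus, allele,
    transition) keys differ. Alleles the pipeline could not classify
    (all-missing subpopulation calls) are itemised separately and do not
    count as mismatches.
    """
    key = ["locus_id", "allele_id", "transition"]
    t_keys = set(map(tuple, truth[key].itertuples(index=False)))
    f_keys = set(map(tuple, fates[key].itertuples(index=False)))
    if t_keys != f_keys:
        missing = list(t_keys - f_keys)[:5]
        extra = list(f_keys - t_keys)[:5]
        raise IdentifierMismatchError(
            f"keys differ: {len(t_keys - f_keys)} missing from calls "
            f"(e.g. {missing}), {len(f_keys - t_keys)} unexpected (e.g. {extra})"
        )
    merged = truth.merge(
        fates[key + ["category"]].rename(columns={"category": "called"}),
        on=key,
        validate="one_to_one",
    )
    confusion = (
        merged.groupby(["category", "called"]).size().unstack(fill_value=0)
    )
    unclass = merged[merged["called"] == UNCLASSIFIABLE]
    return RecoveryReport(
        confusion=confusion,
        n_total=len(merged),
        n_unclassifiable=len(unclass),
        unclassifiable=unclass[key + ["category"]].reset_index(drop=True),
    )
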