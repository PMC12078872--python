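# glac — genome-wide locus–allele comparison

`glac` characterises how the allele content of a genome changes across
ordered ancestor→descendant population stages — for example from annual
wild soybean accessions (WA) through farmers' landraces (LR) to modern
released cultivars (RC). Classical scans (π, F<sub>ST</sub>, XP-CLR
selective sweeps) summarise *frequency shifts*; they are blind to the
qualitative events that restructure a population's gene–allele
constitution: alleles disappearing outright, novel alleles arising,
whole loci losing or regaining polymorphism. `glac` counts exactly those
events, genome-wide, for every allele of a shared universe. It is aimed
at population and crop geneticists working with resequenced inbred
panels (selfing species, homozygous genotypes).

## The method

**Markers.** Biallelic SNPs are grouped into SNPLDB loci: maximal
contiguous runs of tightly linked SNPs (pairwise |D′| ≥ 0.70 for at
least 95% of informative pairs, span ≤ 100 kb); observed haplotypes are
the locus's multiple alleles, and unblocked SNPs remain biallelic loci.
This gives one uniform multi-allelic marker system for gene and
inter-gene regions.

**Classification.** For each transition with parent frequency *p* and
child frequency *c*, every universe allele receives exactly one fate:

| fate | predicate |
|---|---|
| excluded | *p* > 0, *c* = 0 (allele zero/one change) |
| emerged | *p* = 0, *c* > 0, absent from every restoration source |
| restored | *p* = 0, *c* > 0, present in an earlier source population |
| inherited, fixed | *p* = *c* = 1 |
| inherited, LPD | *p* < 1, *c* = 1 — locus polymorphism disappeared |
| inherited, LPE | *p* = 1, *c* < 1, fixed in all sources — polymorphism emerged |
| inherited, LPR | *p* = 1, *c* < 1, polymorphic in a source — polymorphism restored |
| inherited, ordinary | 0 < *p*, *c* < 1, *p* ≠ *c* (increase / decrease) |
| frequency of 0 | *p* = *c* = 0 |

Locus-level fates follow (a locus loses polymorphism iff one of its
alleles is LPD), fates are chained along the stage path (permanent
exclusion, emergence kept, …), counts become per-year rates
(count/years, and per universe unit), frequencies are cross-tabulated in
12 classes {0}, (0,0.1], …, (0.9,1), {1}, and fates are intersected with
top-5% sweep regions called from an external per-window statistic.

## Worked example

The package ships the printed allele-change tallies of a 750-accession
Chinese soybean germplasm panel (127 WA / 424 LR / 199 RC; 154,088
SNPLDB loci, 559,611 alleles). `python examples/02_published_panel_figures.py`
prints, among other lines:

```
per-year zero/one change rates:
                              count  per_year  per_year_per_unit
transition change
WA->LR     allele_exclusion   76866     15.37           0.000028
           allele_emergence   37543      7.51           0.000013
           locus_disappeared  23670      4.73           0.000031
           locus_emerged       2351      0.47           0.000003
LR->RC     allele_exclusion   79573    795.73           0.001420
...
WA->LR cross-table margins: total=559,611 excluded=76,866 emerged=37,543 ...
  composite zero/one share: 25.10% of all alleles
chained fates across both stages:
  permanently_excluded_pct: 91.88%
  emerged_then_inherited_pct: 95.06%
  fixation_pathway_pct: 99.13%
```

Read: during ~5000 years of domestication alleles were excluded at
15.37/year (2.75·10⁻⁵ per allele per year) but during ~100 years of
modern breeding at 795.73/year — a ~50-fold acceleration of selection —
while emergence stayed near 7 alleles/year in both stages (mutation
supply is stable). A quarter (25.10%) of all alleles underwent zero/one
change during domestication; 91.88% of the excluded alleles never
reappeared.

`examples/01_simulate_and_classify.py` runs the full pipeline on a
simulated panel with planted fates (it recovers 100% of them), and
`examples/03_diversity_sweeps_overlap.py` shows π/F<sub>ST</sub>, sweep
calling and fate–sweep overlap.

A thin CLI wraps the same library:

```bash
glac simulate --seed 5 --out sim/
glac classify --vcf sim/panel.vcf --manifest sim/manifest.tsv \
     --stage-graph stages.yaml --out run/
glac verify --truth sim/truth.tsv --fates run/fates.tsv --out check/
```

## Layout

- `src/glac/genotype_io.py` — VCF/manifest input, MAF filter
- `src/glac/snpldb.py` — D′, LD-block partition, haplotype alleles, frequencies
- `src/glac/glac_core.py` — fate taxonomy, chaining, rates, motivator groups
- `src/glac/tabulate.py` — summaries, 12×12 cross-tables, window densities
- `src/glac/popgen_stats.py` — π, Weir–Cockerham F<sub>ST</sub>, sweep regions, overlap
- `src/glac/synthetic.py` — multi-stage simulator with planted ground truth
- `src/glac/worked.py`, `src/glac/data/` — published panel tallies and derived figures
- `src/glac/cli.py` — `glac` subcommands
- `docs/methods.md` — models, conventions, numerical choices, limitations
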