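# Methods

## Scope and model

`glac` operates on a panel of inbred accessions genotyped at biallelic
SNPs, partitioned into ordered population stages with ancestor→descendant
relationships (a path, optionally with "restoration sources": earlier
stages whose material re-enters a later one, e.g. wild accessions used
as direct breeding parents). The quantity of interest is the fate of
every allele of the whole-sample universe at every transition, with
special attention to zero/one changes — transitions between absence
(frequency 0) and presence — at both the allele and the locus level.

Genotypes are treated as haploid-equivalent throughout: the panel is
assumed highly homozygous (selfing species), heterozygous calls are
treated as missing rather than phased, and frequencies are carrier
counts over non-missing accessions. This one assumption propagates
consistently through the MAF filter (a het contributes half a dose of
each allele), haplotype calling, π and F_ST.

## SNPLDB construction

**Pairwise LD.** |D′| = |D|/D_max with D = p(AB) − p(A)p(B) and D_max
the usual bound given the marginals, computed from joint homozygous
calls; pairs with a het or missing call at either site are skipped. A
pair is *informative* when ≥ `min_informative` (default 4) usable joint
calls exist and both sites are polymorphic in the usable subset; a
monomorphic subset yields an undefined value, never a silent 0.

**Partition.** Blocks are grown greedily left to right along each
chromosome: a SNP joins the current run while the block span stays
≤ `max_span_bp` (default 100 kb) and the proportion of informative
pairwise |D′| ≥ `strong_ld` (default 0.70) remains ≥ `strong_pair_prop`
(default 0.95). Runs that never reach two SNPs are singleton loci. This
is a deliberately simple, fully documented Gabriel-style rule: the
original block-finding software's internals are not printed anywhere we
could mirror, so the package's own rule is the contract — it reproduces
"tightly linked SNPs grouped at D′ ≥ 0.70" and is exactly testable. The
partition is exhaustive and disjoint by construction.

**Alleles.** Per block and accession, the haplotype string over the
constituent SNPs is the allele; any het/missing constituent call makes
the locus call missing. Haplotypes with whole-sample frequency below
`rare_threshold` (default 0.01, mirroring the SNP MAF floor; 0 disables)
are merged into the nearest frequent haplotype by Hamming distance,
ties resolved toward the more frequent target and then the
lexicographically smallest. Merging relabels calls only — it never
changes which calls are non-missing. Allele ids are the representative
haplotype strings. Loci whose calls are all missing are dropped with a
warning.

## Fate taxonomy

For parent frequency p, child frequency c and restoration-source
frequencies s₁…s_k (empty for a first transition):

- excluded: p > 0, c = 0; emerged: p = 0, c > 0 and all sᵢ = 0;
  restored: p = 0, c > 0, some sᵢ > 0; absent_both: p = c = 0.
- inherited (p, c > 0): fixed (p = c = 1); LPD (p < 1, c = 1); LPE
  (p = 1, c < 1, all sᵢ = 1 — a *first* decrease from 1); LPR (p = 1,
  c < 1, some sᵢ < 1 — the locus was polymorphic earlier, so its
  polymorphism is restored, not new); ordinary increase (p < c < 1) and
  decrease (c < p, c < 1).
- inherited_unchanged (0 < p = c < 1) is surfaced as its own category
  rather than silently binned into increase or decrease: the published
  four-way frequency-change breakdown has no tie class, and at desk
  scale ties are common, so hiding them would silently break the
  partition identity. Summaries print it as a separate row.
- unclassifiable: a population with zero non-missing calls at the locus
  leaves its frequency undefined; all alleles of that locus are itemised
  and excluded from percentage denominators.

Locus fates derive from allele fates: polymorphism_disappeared iff some
allele is LPD, polymorphism_emerged iff some is LPE, likewise LPR;
otherwise fixed_kept / polymorphic_kept by presence counts, with a
fixed_replaced corner case (parent and child each monomorphic for
different alleles) counted among fixed loci but flagged separately.
These definitions make the bookkeeping identities exact on any input:
fates partition the universe; child-present alleles = inherited +
emerged + restored; #LPD alleles = #disappeared loci; #LPE = #emerged
loci.

Per-year rates are count/years and count/years/universe; reports print
the former to 2 decimals and the latter to 3 significant figures.
Motivator groups combine allele and locus zero/one changes on the
allele scale: exclusion = excluded + LPD, emergence = emerged + LPE,
restoration = restored + LPR, ordinary = increase + decrease, no-change
= kept-at-0 + kept-at-1, components always reported separately.

## Binning and cross-tables

Frequency classes partition [0,1] as {0}, (0,0.1], (0.1,0.2], …,
(0.8,0.9], (0.9,1), {1}. Interior bins are right-closed (0.1 belongs to
"0.0–0.1"); any consistent convention preserves the margin identities,
and this one keeps count/n ratios stable under float rounding (a 1e-9
guard absorbs representation error, far below any attainable frequency
gap at realistic n). The "0.9–0.99" label denotes the open interval
(0.9, 1): with finite samples below n = 100 no frequency strictly
between 0.99 and 1 exists, so small synthetic panels bin identically to
large ones. Cross-tables count alleles by (child class, parent class);
restored and LPR alleles are carried as per-class companion counts so
the "emerged + restored" style compound cells never conflate categories.
Margins recover the zero/one tallies exactly (row "0" minus (0,0) =
excluded, etc.).

The composite zero/one share of a transition is reported as the sum of
its four component percentages *at printed precision* (2 decimals
each), matching how such tables are customarily totalled; summing raw
counts first can differ in the last digit (25.10 vs 25.09 on the
shipped panel tallies).

## Diversity, differentiation, sweeps

π at a site is the unbiased mean pairwise difference
n/(n−1)·(1 − Σpᵢ²) over haploid-equivalent calls; a locus is the mean
over constituent SNPs and the genome value the mean over loci. F_ST is
the Weir–Cockerham (1984) variance-component estimator on
haploid-equivalent counts, summed over alleles; locus values are
ratio-of-summed-components, negative estimates are reported as computed
(an optional clamp floors them at 0), and the same-allele-fixed-in-both
case is undefined rather than 0. Both have independent test oracles
(exhaustive pairwise enumeration; an ANOVA-on-indicators evaluation).

Sweep calling consumes an external per-window score (e.g. XP-CLR; the
statistic itself is out of scope). The threshold is the k-th largest
score with k = ⌈top_fraction·N⌉; all windows at or above it are selected
(ties included, so "top 5%" is reproducible bit-exactly), and selected
windows that overlap or are book-ended merge into regions — with the
standard 100 kb/10 kb sliding windows, adjacency implies overlap, so
this reproduces grouping adjacent high-scoring windows. Fate–sweep
overlap uses interval intersection of the locus span with any region
(containment is configurable in principle but intersection is the
default and what the tests pin down).

## Synthetic panels

The simulator emits VCF + manifest + ground truth for an ordered stage
path with *planted*, exactly-realised fate events. Defaults mirror the
three-stage soybean setting: 127/424/199 accessions, 5000- and 100-year
transitions, wild accessions as the restoration source of the cultivar
stage, and a mix of planted exclusions, emergences, restorations, locus
zero/one events and ordinary shifts over a few hundred loci.

Choices that make recovery exact and deterministic:

- Planted frequencies are realised as integer accession counts
  (largest-remainder rounding), not sampled; drift, when enabled,
  perturbs only background loci.
- Each locus's catalogue is a *staircase* of haplotypes
  h_m = 1^m 0^(k−m): any subset gives |D′| = 1 for every SNP pair, so
  the LD partition recovers the planted loci exactly; adjacent levels
  differ at one SNP, so emerged alleles are one-SNP mutations of an
  existing haplotype; every constituent SNP is polymorphic in the whole
  sample, so nothing is lost to the MAF filter.
- Loci are spaced 200 kb apart (twice the maximum block span), so
  blocks can never bridge loci.
- Missingness and het noise are applied per (locus, accession) after
  frequency realisation; the truth table records the planned (pre-noise)
  frequencies.

What the simulator does *not* emulate: linkage between loci,
recombination within blocks, coalescent genealogy, genotyping-error
structure, or realistic allele-frequency spectra. Passing recovery
tests therefore demonstrate the correctness of the marker construction
and fate accounting, not robustness to the messiness of real
resequencing data; the noisy-mode tests only check that the pipeline
degrades gracefully (planted exclusions stay excluded; loci with an
all-missing subpopulation are flagged, not misclassified).

Noiseless recovery on a 1,110-locus, five-stage plan (40 accessions per
stage, all planted categories represented, restoration sources at three
transitions) is the package's primary parameter-recovery property; it
also keeps the default test suite and the acceptance run in seconds on
one CPU, which is why those are the shipped problem sizes.

## Numerical conventions and degenerate inputs

Frequencies compare exactly against 0 and 1 — both arise as integer
count ratios, so no tolerance is needed or wanted (a tolerance would
misclassify genuine near-fixation). Undefined quantities are NaN plus an
explicit flag, never 0. Multi-allelic VCF records are dropped, not
split, to avoid phantom loci. Locus coordinates are 1-based inclusive
in TSV outputs and 0-based half-open in BED exports. Empty chromosomes
partition to nothing; an empty window set is a hard error for sweep
calling; zero surviving SNPs after the MAF filter is a hard error
naming the cause.

## Known limitations

- The block partition is greedy and order-dependent; it does not
  implement the original Gabriel confidence-interval machinery nor
  EM-based haplotype estimation for outbred data.
- Whether published "% in each type" denominators under missing data
  match this package's (unclassifiable alleles excluded) cannot be
  decided from printed tables alone; the identity checks are the
  testable surface.
- The XP-CLR statistic, upstream read mapping and variant calling, and
  phenotype-weighted fate analyses are out of scope; the VCF and the
  per-window score table are the input boundaries.
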