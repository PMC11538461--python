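# Methods

This note documents the models and procedures implemented in `holocentro`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical choices that matter.

## Coordinate model

All genomic spans are 0-based half-open (`[start, end)`), the BED
convention; GFF3 input (1-based inclusive) is converted at the parsing
boundary only. Strand is parsed and preserved as an attribute but ignored
by the interval algebra — every set operation here (consensus, merging,
intersection, windowing) is strand-agnostic. Terminal short windows are
kept when tiling a genome so that window sets always cover 100 % of each
chromosome; dropping them would bias coverage proportions near chromosome
ends.

## Centromeric units

CENH3 occupancy defines functional centromere chromatin. Peak calls from
two callers in two replicates are combined by **base-level four-way
intersection**: a genomic position enters the consensus only if all four
peak sets cover it. The alternative — peak-level reciprocal-overlap
voting — depends on pairing order and an arbitrary overlap threshold; the
base-level rule is symmetric, deterministic, and any fragmentation it
introduces is healed by the subsequent merge. Consensus peaks separated by
at most `merge_gap` (default **150 kb**, configurable) are merged into
centromeric units; the threshold is a parameter of the analysis, not a
quantity the pipeline derives. Unit statistics report per-chromosome and
genome-wide count, density in units/Mb and length summaries; chromosomes
without units carry NaN length statistics rather than zeros.

No minimum unit length is imposed by default. A single-set false-positive
peak contributes zero consensus bases, so caller- or replicate-specific
artifacts are eliminated by construction.

## Satellite array detection

A satellite family is represented by its consensus monomer (the default
synthetic families use 124-bp and 174-bp monomers, the sizes typical of
the two dominant woodrush centromeric satellites). Detection is
seed-and-extend: exact k-mers (k = 11 by default) of the doubled monomer —
doubling covers the copy junction, so a seed fixes the repeat phase for
any rotation — anchor a monomer-phased grid on both strands; every grid
copy is scored by ungapped per-base identity against the consensus. Copies
with identity ≥ `min_identity` (default **0.95**) are merged into an array
when separated by at most two monomer lengths, and arrays spanning fewer
than two monomer lengths are discarded: this separates genuine tandem
arrays from isolated monomer hits. `mean_identity` averages member-copy
identities, so it converges on 1 − μ for copies diverged at per-base rate
μ. Seed segments are split where the observed repeat phase shifts, which
keeps arrays intact across small insertions between copies.

The model is substitution-only within a copy (no indel alignment); on real
assemblies indel-rich arrays would fragment at phase breaks and be
re-joined by the merge step, at some cost in boundary precision.

### Interstitial telomeric sites

The same scanner with the 7-bp plant telomere monomer (TTTAGGG) feeds a
three-stage rule per stringency level s ∈ {0.75, 0.90}:

1. copies with per-copy identity ≥ s join into candidates when separated
   by ≤ 50 bp (tight, so chance isolated heptamer matches stay isolated);
2. a candidate qualifies if it is strictly longer than 200 bp **and** its
   aggregate similarity — the mean identity over all phased copies it
   spans, including sub-threshold ones — reaches s;
3. qualifying arrays closer than 10 kb are merged.

The aggregate-similarity filter is what distinguishes the two stringency
levels: a 20 %-diverged array has region similarity ≈ 0.80, passing 75 %
but never 90 %. Arrays farther than `terminal_margin` (default 10 kb) from
both chromosome ends are flagged interstitial — candidate fusion
footprints.

## Classification and contrasts

An array is functional iff it overlaps the centromeric units by at least
`min_overlap` bases (default 1 bp — any CENH3 contact counts; the
threshold is configurable). Functional array *fragments* are the exact
base-level intersections. Unit family labels are non-exclusive (a unit may
contain both families); satellite-free units overlap no satellite of any
family by even one base. Satellite-free unit composition over annotation
tracks is reported as per-class base fractions; classes may overlap, so
fractions need not sum to 1.

Size contrasts use a two-sided Mann–Whitney U on array lengths; dyad
abundance uses a one-tailed U (functional > nonfunctional) on per-array
dyad density.

## Dyad symmetries

A dyad symmetry is an exact inverted repeat: left arm, loop, right arm
with reverse-complement arm identity, stem ∈ [`min_stem`, `max_stem`]
(default 10–100 bp) and loop ≤ `max_loop` (default 100 bp); N never pairs.
All *maximal* hits are reported — a hit extendable by one more
complementary base pair outward, or inward into the loop, without
violating a constraint is suppressed in favour of its extension.
Overlapping hits are allowed; stricter non-overlap policies can filter the
superset downstream. The finder scans anti-diagonals of the implicit
self-comparison matrix (complementary base codes sum to 3), restricted to
the band the stem/loop limits allow, giving O(n·(max_stem + max_loop))
time; its hit sets are verified against an exhaustive per-position oracle
in the test suite. Abundance is normalized to hits per kb of array length
because functional arrays are roughly ten times longer than nonfunctional
ones — raw counts would confound length with abundance. Arrays are scanned
on the forward strand only: a dyad is its own reverse complement, so
scanning both strands would double-count every hit.

## Array homogeneity

Group sequences (functional fragments, or whole nonfunctional arrays) are
concatenated in genome order; 5-kb windows never span a source boundary,
and a terminal window shorter than half the window width is dropped. Each
window pair is compared by the Jaccard index J of exact canonical 21-mer
sets, converted to an ANI estimate with the Mash-distance formula
`identity = 1 + ln(2J/(1+J))/k` (0 when J = 0). Exact k-mer sets replace
sketching deliberately: at the scale of satellite array groups sketching
saves nothing and introduces a stochastic approximation. Canonical k-mers
make the comparison strand-independent. The estimator recovers planted
divergence to within a few tenths of a percentage point for μ ≤ 0.10
(verified in the acceptance tests at ±2 points). Summaries report the mean
of the off-diagonal upper triangle and a histogram in 1-point bins — the
histogram is where mixtures of divergence levels show up as bimodality.

## Windowed features, correlograms, profiles

Feature matrices over 100-kb windows hold covered-base proportions (for
interval tracks) or coverage-weighted means (for signal tracks; spans
missing from a bedGraph count as 0). Correlograms are pairwise Spearman
correlations with Benjamini–Hochberg adjustment across all feature pairs
at α = 0.05; the diagonal, non-significant pairs and constant columns are
masked. ChIP normalization is log2((RPKM_chip + ε)/(RPKM_input + ε)) with
ε defaulting to the RPKM of one read in one full-size bin — small enough
to preserve signal, large enough to keep empty bins finite. Metaprofiles
follow scale-regions semantics: the feature body is split into 100 equal
sub-spans plus 50 fixed-width bins per 5-kb flank, minus-strand features
are flipped, features shorter than the body bin count are skipped and
counted. Outputs are TSV/JSON; plotting is left to the caller's tooling.

## Statistical primitives

Mann–Whitney U uses midranks; the exact null distribution is enumerated by
the standard count recursion when n·m ≤ 100 and the pooled sample is
tie-free, otherwise a normal approximation with tie and continuity
corrections — the exact branch doubles as an oracle surface for the
approximation and is itself validated against full enumeration for all
n, m ≤ 7. Spearman's ρ is the Pearson correlation of midranks with a
t-approximation p-value; constant vectors raise rather than return NaN.
Multiple testing uses Benjamini–Hochberg step-up (the standard choice for
correlogram-scale testing), configurable at the call site. Empirical
percentiles use the midrank tie convention,
`100·(#below + ½·#equal)/n` — symmetric and degenerate-safe.

## Shuffle colocalization test

Query regions are re-placed with lengths preserved; the chromosome is
drawn with probability proportional to its length (a per-chromosome-
preserving mode is available), and the start is drawn **uniformly among
all placements** that avoid the exclusion mask and previously placed
regions — computed exactly from the gap structure rather than by
rejection, so a single remaining slot is always found and placement is
uniform conditional on validity. The statistic is the proportion of
feature-covered bases overlapped by the regions. The real statistic's
midrank percentile among `n_rounds` (default 1000) simulated statistics is
reported together with permutation p-values using the +1 correction; low
percentiles indicate depletion. Calibration (percentile uniform under an
independent null) and power (5× planted enrichment ⇒ percentile ≥ 99) are
asserted in the acceptance tests; the calibration check draws its "real"
regions from the same non-overlapping placement process as the null,
since overlap among query regions would otherwise shift the statistic.

## Ancestral centromere projection

A reference-genome centromere fully inside one synteny block maps by
linear interpolation through that block (orientation-aware). Otherwise the
nearest flanking blocks on each side bound the projection as the span
between their target-genome images; projections exceeding five times the
source centromere length are flagged oversized, and centromeres without a
flanking block on either side (or with flanks on different target
chromosomes) are reported unprojectable rather than guessed.

## Synthetic data generator

The generator emulates the data shapes of a holocentromere study at desk
scale. Defaults (the study conditions for all tests):

| parameter | default | note |
|---|---|---|
| genome | 3 chromosomes × 2 Mb | a `paper-shaped` preset gives 6 × 5 Mb at 0.6–0.9 units/Mb |
| GC | 0.33 | typical for the clade |
| families | 124-bp (20 arrays, 35 % functional), 174-bp (16 arrays, 12.5 % functional) | |
| array lengths | log-normal; functional mean 18.9 kb / 9.4 kb, nonfunctional 2 kb | the ~10× functional/nonfunctional length contrast, scaled down 10× |
| divergence μ | 0.02 per copy | homogeneous satellite; keeps arrays contiguous at the 95 % scan threshold |
| dyad planting | 1.2 /kb functional vs 0.2 /kb nonfunctional | inserted *between* monomer copies so copy integrity is preserved; the contrast is strong enough to be detectable at toy-scale group sizes (n ≈ 7–13 per group) |
| satellite-free domains | 3, ~15 kb | annotated 54 % low-complexity / 26 % TE |
| peak noise | jitter 200 bp/boundary/set; 5 unique false positives per set | false positives never shared between sets |
| domain separation | ≥ 165 kb | keeps planted domains distinct under the 150-kb merge |
| ChIP model | Poisson reads per 100-bp bin, 4× enrichment over domains, depth 10 | |
| methylation | beta noise around CpG 30/80, CHG 20/55, CHH 5/10 (background/array) with border gradients CHG +15, CHH +8 | reproduces border-elevated non-CpG methylation over arrays |
| telomeres / ITS | 50 perfect copies per end; two 300-bp interstitial plantings | |
| synteny | 3 blocks per chromosome, one >100-kb fusion gap each | optional gene enrichment inside gaps |

One master seed drives `SeedSequence`-spawned per-stage generators, so
identical specs give byte-identical outputs and each stage is
independently reproducible. Everything planted is recorded in
`truth.json`.

What the generator does **not** emulate: indels and higher-order repeat
structure inside arrays, realistic TE sequence (TE/gene/low-complexity
tracks are coordinate annotations, not sequence models), read-level noise
(tracks are drawn at the bin level), chromatin-state heterogeneity, and
genome rearrangements other than the block/gap synteny layout. Passing
tests therefore demonstrate correctness of the algorithms under a clean
substitution-and-placement model — not robustness to assembly error or
alignment artifacts.

## Problem sizes and determinism

The default test and acceptance runs use the 6-Mb toy genome; the full
pipeline is a pure function of (inputs, config, seed), reruns are
byte-identical, and the report deliberately contains no timestamps or
absolute paths. Timing and record counts go to the log instead.

## Known limitations

- The monomer scanner's identity model is per-copy Hamming identity;
  heavily indel-diverged arrays are under-merged.
- ITS "similarity" is defined against the phased copy grid; other
  definitions (global alignment to a telomeric reference) would shift
  absolute values, which is why absolute homogeneity/similarity numbers
  are parameter-dependent summaries rather than portable constants.
- The dyad finder reports all maximal hits; in low-complexity or
  AT-alternating contexts the overlap-permissive policy can yield many
  hits per locus, as EMBOSS-style overlap reporting does.
- `compare_*` tests require both groups non-empty and raise informative
  errors otherwise; families whose functional group is empty are excluded
  from contrasts rather than imputed.
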