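# Methods

This note documents the models and procedures implemented in `ladkit`, the
parameters that matter, the design choices made where the underlying
protocol left the procedure open, and what the synthetic data does and does
not establish.

## DamID scoring

DamID quantification is per DpnI fragment: the interval between consecutive
GATC cut sites. The digest convention is GA^TC (the enzyme's blunt cut), so
a motif at position *p* cuts at *p* + 2; any consistent offset shifts all
bin edges by ≤ 2 bp and no downstream statistic depends on it. Matching is
case-insensitive and literal: `N` never matches and no IUPAC expansion is
applied. Terminal sub-fragments at chromosome ends are retained as bins.

Reads are assigned to every fragment they overlap by at least 1 bp, so a
read straddling a cut site counts toward both neighbours; the library size
is the number of reads, not the column sum. Scoring is

    score_i = log2( fusion_i / control_i )

with three rules:

* fragments with zero reads in **both** samples are *missing*, never 0 — a
  log-ratio is only defined for bins with signal;
* a zero in exactly **one** sample takes the pseudocount 0.5 before the
  ratio (default pseudocount 0.5, configurable);
* with reads-per-million normalisation on (the default), counts are scaled
  by library size before the ratio and the pseudocount substitutes on the
  raw-zero side after scaling, preserving its role as a detection floor.
  Normalisation is a flag because unequal sequencing depth otherwise shifts
  every score by a constant; turning it off reproduces the literal
  unnormalised ratio.

An optional mask (BED intervals) removes fragments in unalignable regions
before analysis; no mask is applied by default.

The 5′ quality trimming (3-base sliding window, mean ≥ Q30) and
adaptor-splitting (split at every exact adaptor occurrence, keep pieces
> 20 bp) operations are provided for completeness; the standard entry point
is aligned reads as BED intervals, since alignment is outside this
package's scope. A read shorter than the trim window is kept when its
full-length mean passes the cutoff, else emptied.

## Segmentation and LAD classification

Score tracks are partitioned per chromosome by recursive binary
segmentation (the CBS procedure): at each step the candidate split
maximises the two-sample statistic

    T(i) = |mean_left − mean_right| / sqrt(1/n_l + 1/n_r)

over all split points (ties leftmost) and is accepted iff its permutation
p-value, (1 + exceedances) / (1 + n_perm), is below `alpha`. Defaults:
`alpha = 0.01`, `n_perm = 10 000`, seeded. The common variance term is
permutation-invariant and is omitted from the statistic. Missing fragments
are skipped in the statistics but inherit the enclosing segment (interior
missing runs attach to the segment on their right), so segments tile the
chromosome. The permutation loop is a compiled kernel with an inline
xorshift64* generator; the permutation stream is reproducible for a given
seed and stops early once the exceedance count already implies rejection.

Greedy recursion estimates each boundary on whatever segment the recursion
is currently testing, which can strand a few bins on the wrong side when
the local shift is marginal. A refinement pass therefore re-estimates every
interior changepoint at the SSE-optimal position within its two flanking
segments (segment count fixed), iterated to a fixpoint. The pass is
deterministic and typically moves boundaries by 0–3 bins.

LAD classification follows the positive-signal rule: segments with strictly
positive mean are mapped to genomic intervals at their fragment edges;
consecutive positive intervals separated by negative spans shorter than
`max_gap` (default 10 kb) merge across the gap; merged regions of length
≥ `min_lad` (default 100 kb, inclusive — the length rule is stated both
exclusively and inclusively in common usage, so the inclusive form is the
default and both are configurable) are emitted. Boundaries always lie at
outermost positive-segment edges, never inside a gap. One left-to-right
merge pass suffices because gap-merging on sorted disjoint intervals is
associative (tested).

A chromosome partitioned into a single segment yields **no** LADs. DamID
log-ratios are relative quantities: with no significant changepoint there
is no within-chromosome contrast between lamina-proximal and -distal
regions, and the sign of the chromosome-wide mean is a noise-level coin
flip (of order 1/sqrt(n_fragments)), not evidence of domain structure. The
corollary — a chromosome that is entirely one LAD would be missed — is a
documented limitation.

## Biotinylation-site analysis

Site records (protein, 1-based lysine position, condition, replicate, MS1
abundance) aggregate to proteins as *ratio of sums then mean of ratios*:
per replicate, site abundances are summed per protein and condition; one
numerator/denominator ratio is formed per replicate; the arithmetic mean of
replicate ratios is compared with the fold threshold. This matches the
replicate-averaged-ratio convention; a geometric mean is available via
`ratio_mean="geometric"`. Default thresholds are 2.0 for the
bait-vs-tracer comparison and 1.6 for the +shield/−shield LAD-directed
comparison.

Choices where the protocol is open:

* a zero denominator in a replicate is imputed as the smallest positive
  abundance observed in that replicate of the denominator condition (a
  detection floor); the result is flagged `imputed` rather than producing
  an infinite ratio;
* proteins observed in only some replicates are averaged over the
  replicates they have, with `n_replicates` reported; nothing is filtered
  by default;
* site identity is (protein, position): peptides sharing a modified lysine
  collapse to one site.

Degree of biotinylation is distinct biotinylated positions divided by the
count of K in the protein sequence, ranked descending with ties broken by
protein ID. Lysine-free sequences, sites beyond the sequence, non-K
residues at a claimed site, and proteins missing from the FASTA each
produce an explicit error record while the rest proceed. Topology mapping
labels each site by the annotated domain (1-based inclusive ranges)
containing it; overlapping annotation ranges are rejected.

## Protein-set integration

Symbols are uppercased and trimmed, with an optional alias→canonical
synonym table (source lists mix species casing and aliases; conflicting
alias rows are an error). The consensus laminome keeps proteins observed in
≥ `min_studies` (default 3) of the published lamina-interactome datasets.
Zones partition the universe (default: union of the inputs):

* zone 1 = (laminome ∪ bait interactome) \ LAD proteome
* zone 2 = LAD proteome ∩ (laminome ∪ bait interactome)
* zone 3 = LAD proteome \ (laminome ∪ bait interactome)
* none   = universe minus all three

The partition invariant (disjoint, exhaustive) is asserted on every run.
Venn accounting supports up to 4 sets (beyond that a membership table is
the sane output). Published overlap counts depend on the original deposited
lists and are reproduced only when those lists are supplied; the package
ships a 12-protein worked micro-fixture of well-known periphery proteins
instead.

## Interval statistics

Interval sets are merged on construction, so self-overlapping inputs cannot
inflate coverage; all features are unstranded. Base-coverage overlap is
100·|A∩B|/|A| (NA for an empty set). Peak containment uses the midpoint
rule by default (a peak "resides within" a region iff its centre base
does); any-overlap is a flag.

Profiles average a binned signal in half-open offset bins [o, o + step)
around anchors. Boundary profiles use both edges of every region ≥
`min_region` (default 100 kb) and mirror right-hand boundaries so positive
offsets always point into the region, with the anchor at offset 0 on the
inside edge; windows beyond chromosome bounds contribute only in-bounds
bins, and bin means are coverage-weighted over the track bins they
intersect. Defaults flank = 100 kb, step = 10 kb match the ±100 kb axes of
typical boundary plots. Anchor profiles are the unoriented special case.

## Synthetic data

The generators are pure functions of (config, seed) and emit truth
alongside data. Defaults are the scaled-down study conditions: one 10 Mb
chromosome; GATC density 4/kb (mean fragment ≈ 250 bp, the genome-wide
average); 15 planted LADs of 100–500 kb with ≥ 50 kb spacing (spacing is
kept above the 10 kb merge gap so planted domains are never merged by
construction); Dam-only depth 10 reads/fragment with 4-fold fusion
enrichment inside LADs under Poisson noise (negative binomial with
mean·dispersion variance available, as real DamID is overdispersed);
fragment membership by midpoint. The background sequence would contribute
accidental GATCs at ~1/256 per bp, so background motifs are ablated (A→C,
which cannot create a new motif) before insertion and the truth is defined
by an exact rescan. The biotinylation generator plants 50 of 500 proteins
at 3-fold enrichment under multiplicative log-normal noise (σ = 0.2 in ln
space) across 2 replicates on synthetic lysine-bearing sequences; the peak
generator places 500 peak midpoints inside a region set with probability
0.8 and reports the achieved fraction (post-merge).

What the generators do **not** emulate: mappability structure and masked
regions, PCR amplification and Dam-expression artifacts, read-level
base-call errors, GATC density variation along the genome, peptide-level
missingness patterns and ionisation bias, or correlated replicates.
Recovery results on synthetic data therefore demonstrate the correctness
and calibration of the procedures under their stated noise models, not
performance on real libraries.

## Problem sizes and numerics

The test suite and acceptance script run the full DamID pipeline at the
10 Mb / ~40 000-fragment scale (about 30 s of segmentation) and use 1 Mb
genomes or toy fragment maps for distributional and oracle checks.
Tolerances on stochastic checks are 3-sigma bands from the configured
distributions; deterministic oracle comparisons are exact. Degenerate
inputs (empty sequences, all-missing chromosomes, empty interval sets,
lysine-free proteins, zero library sizes) raise explicit errors or warnings
rather than propagating NaNs silently.
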