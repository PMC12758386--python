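# Methods

`stcap` models the subterminal heterochromatic caps found at the chromosome
ends of African great apes: long tandem arrays of a 32 bp satellite unit
(pCht/StSat) interleaved with 32–34 kbp segmental-duplication "spacer"
copies, bounded proximally by euchromatin.  The package provides the full
analysis chain for such regions — satellite annotation, higher-order
structure, spacer phylogenetics, recombination tests, and boundary
epigenomics — together with a generator of synthetic cap genomes that
supplies exact ground truth for every stage.  This note records the models,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Satellite unit detection

A unit is an alignment of the full consensus (default the 32-mer
`GATATTTCCATGTTTATACAGATAGCGGTGTA`) to a substring of the arm, on either
strand.  A hit must retain strictly more than `min_match_fraction` (default
0.90) of the consensus positions; since substitutions and deletions each
remove one retained position, a hit may carry at most
`L - (floor(0.90 L) + 1)` Levenshtein edits — 3 edits for the 32-mer, i.e.
at least 29 of 32 positions matched.

Detection is seed-and-extend: by pigeonhole, any hit with ≤3 edits contains
an exact 7-mer of the consensus, so exact 7-mer seeds (both strands)
generate candidate end positions, each evaluated by bounded edit-distance
alignment over the seven window lengths L±3.  Overlapping hits are resolved
greedily: best identity first, then leftmost start, then plus strand.  For
ties on the edit count at one end position the shortest window (largest
start) is taken.  This definition is deliberately simple enough to be
checked exactly: the test suite contains an exhaustive sliding-window
dynamic-programming oracle and asserts set equality of detected units on
random sequences with planted, mutated units.  `N` bases match nothing and
hits with >10% `N` are rejected.

Each unit carries a canonical variant signature — the ordered list of
differences from the consensus (`SUB12T>C`, `DEL3A>-`, `INS7->G`), in
ascending consensus coordinate.  Signatures are the atoms of all
composition analyses.  Arrays are maximal runs of units separated by at
most `max_gap` (default 5 bp, the merging distance being an implementation
choice); spacers are the cap span minus the arrays, so arrays and spacers
tile the cap exactly.

## Composition matrix and clustering

The composition matrix holds, per arm, the count of each variant signature
divided by the arm's total unit count.  Following the filtering used for
real cap data, arms with fewer than 2000 units are dropped and only
signatures with genome-wide count strictly greater than 100 are kept as
columns (both configurable).

Arms are clustered on correlation distance (1 − Pearson r between rows)
with average linkage.  Support values are plain nonparametric bootstrap
over variant columns (percentage of replicates containing each cluster),
a deliberate simplification of multiscale-bootstrap AU values: the support
semantics are the same, the numerical values are not comparable to AU
p-values.

Higher-order block types come from two-step k-means.  Step 1 clusters
variant signatures by their across-arm frequency vectors (the matrix
columns, used as-is).  Step 2 tiles each cap into fixed-width blocks
(20 kbp for real data, 2048 bp for synthetic genomes — exactly 64 units),
represents each block by its unit-composition over the step-1 clusters
(fractions summing to 1), and clusters the blocks.  Both k are chosen by
maximal mean silhouette (Euclidean) over a searched range; k-means uses
k-means++ with `n_init=10` and a fixed seed, so results are deterministic.
Trailing partial blocks under half the width are merged into their
neighbour.  Blocks containing no retained unit (pure spacer) are reported
as untyped (−1).  The library default k-range is 5–20; the synthetic
pipeline searches 2–10 because its generator plants 4 types.

## Spacer phylogeny

Spacer copies shorter than 90% of the modal length are discarded.  The
multiple alignment is center-star progressive: the copy with maximal mean
pairwise identity is the center, every other copy is pairwise-aligned to
it, and gap patterns are merged.  Pairwise alignment uses an affine-gap
Gotoh scheme (match 0, mismatch 1, gap open 4, extend 1): for >90%-identical
paralogs a stiff gap penalty keeps the alignment column-to-column instead
of absorbing substitution clusters into spurious indels, and substitution-
only input provably aligns without gaps.  The classical center-star
sum-of-pairs bound (≤2× optimal) is checked against an exhaustive three-way
alignment oracle in the tests.

Trees are neighbor-joining on Jukes–Cantor-corrected p-distances
(`d = -3/4 ln(1 - 4p/3)`, gap-free column pairs only; pairs at p ≥ 0.75 are
reported as saturated).  Negative NJ branch lengths are clamped to zero
with the deficit moved to the sibling branch.  Support comes from
site-resampled bootstrap replicates (default 1000).

Time calibration assumes a strict clock.  After outgroup rooting, the
depth of a node is the mean path length to its descendant tips; the global
rate is the least-squares fit through the origin of calibrated node depths
against their set ages, and every node age is depth/rate.  The packaged
calibration table uses the human-vs-chimpanzee/gorilla/orangutan/siamang
divergence ages 6.4/8.6/15.2/19.5 million years.  Ages are forced monotone
root-to-tip (a parent is at least as old as its children); confidence
intervals are 2.5/97.5 percentiles of ages over bootstrap trees.  This
replaces maximum-likelihood inference with least-squares dating; on
clock-like data the two agree closely, and at desk scale (2 kbp spacers)
the dominant error is sampling noise in the distances, roughly
`1/sqrt(d·L)` relative — the reason the acceptance study uses 20 kbp
alignments for age recovery (relative error ≈ 4% at the shallowest nodes)
but 2 kbp for topology recovery.

## Ectopic exchange

Pairwise arm alignment is anchor-based: k-mers (default k=21) occurring at
most `max_occ=5` times in each arm are matched, chained by diagonal
consistency (±100 bp) and proximity (≤20 kbp), and each chain's identity is
recomputed exactly by global alignment of the chained substrings.  The
occurrence cap suppresses satellite-internal matches; chains bridge
anchor-free arrays through flanking unique sequence.

Exchange candidates come from diagonal-consistent clusters of blocks
(blocks shorter than 1 kbp are treated as repeat noise).  Because a chain
can extend past the true exchange boundary through sub-threshold satellite
paralogy, the candidate is not the chain but the maximal run of 1 kbp
windows along the chain diagonal whose identity clears the threshold
(default >99.5%, with a >99.8% "recent" class; single failing windows are
bridged since near-threshold identity makes individual windows fluctuate).
Run edges are refined at 250 bp resolution to the identity transition, the
exact identity of the final region is recomputed by global alignment, and
a minimum span applies (scaled default 10 kbp standing in for the >1 Mbp
used at genome scale).  On synthetic genomes with planted events the
refined breakpoints land within a few tens of bp of the truth.

A note on what is detectable: a strictly reciprocal swap of divergent tails
leaves no high-identity sequence shared by the two product arms, so the
simulator's exchange event defaults to a conversion-like, non-reciprocal
copy (arm A's tail replaced by a copy of arm B's tail).  That is the event
class that produces the "virtually identical caps on nonhomologous
chromosomes" signature the detector targets; the reciprocal swap mode is
retained for completeness.

Two statistics probe spacer involvement:

* **Breakpoint–spacer proximity.**  The statistic is the mean distance from
  each breakpoint to the nearest spacer bp (0 inside).  The null re-places
  each breakpoint uniformly within its own cap span (the shuffle domain is
  an implementation choice; per-arm placement keeps arm composition fixed);
  1000 shuffles by default, one-sided with smaller distances more extreme,
  and add-one correction `p = (1+r)/(1+N)` so p is never 0.  A one-sided
  rank-sum comparison of observed vs pooled null distances is reported
  alongside.  Under a uniform null the test is close to nominal (measured
  type-I ≈ 0.05–0.09 at α=0.05); with five planted in-spacer breakpoints at
  10% spacer occupancy power exceeds 90%.

* **RF-shift.**  The alignment is split at column ⌈L/2⌉; NJ trees are built
  for the full alignment and both halves, and the observed statistics are
  the Robinson–Foulds distances RF(full, half).  The null is the RF
  distance between each full-alignment bootstrap tree and the majority-rule
  consensus of all bootstrap trees; `p_i = (1 + #{null ≥ RF_i})/(1 + N)`.
  When the phylogenetic signal saturates, half-trees equal the full tree
  and p is maximal — the test is conservative by construction in that
  regime (measured rejection ≈ 0.8% at 1 kbp, 8 taxa).  With realistic
  topology uncertainty (400 bp, 8 taxa) it is approximately calibrated
  (measured ≈ 2.5%), and with random coalescent trees carrying near-zero
  internal branches it can be mildly anti-conservative (≈ 11%); the
  acceptance study therefore evaluates calibration in the moderate-signal
  regime.  On chimeric alignments of two maximally different 8-taxon trees
  it rejects at p<0.01 in >90% of runs.

Allelic-vs-nonallelic identity is summarised per non-overlapping window
(50 kbp default, scaled in synthetic mode) as the coverage-weighted mean of
block identities; unaligned windows are NA and excluded.  The two-sided
test permutes allelic/nonallelic labels over pair-level mean identities.

## Boundary epigenomics

CpG methylation is symmetric, so strand-specific modified/total counts are
summed per CpG dinucleotide (minus-strand records belong to the CpG whose
plus-strand C is one bp upstream); sites with fewer than 5 merged reads
are dropped, and read counts are conserved up to that filter.  Boundary
windows extend a fixed width (2 Mbp real, 20 kbp synthetic) proximally from
the first cap satellite unit.  Profiles are binned means ± SD by distance
to the cap; feature-class comparisons use two-sided rank-sum tests, and
spacer length vs mean methylation uses Spearman correlation.

Insertions relative to a syntenic reference arm are internal gaps (≥50 bp)
between alignment chains (chains shorter than 1 kbp or under 90% identity
do not count as coverage); sequence distal to the outermost chain is never
called, since anchor-free terminal satellite would otherwise produce
spurious calls even for identical arms.  Each insertion is re-aligned
against all reference arms and attributed to the best source ≥90%
identity, else "unplaced".

Boundary enrichment of SDs/genes uses feature-bp density inside the
windows as the statistic, with a null that re-places each feature interval
uniformly (length preserved, overlaps allowed) within the euchromatic
spans, one-sided.  The fold difference is window density over span-wide
density; the null's expected fold is 1 by construction, which the tests
verify within Monte-Carlo error.

## The synthetic generator

Each arm is `euchromatic flank | (array spacer)* array`, cap to the arm
end (q-arm orientation).  Defaults (all configurable): 6 arms; 12–16
arrays per cap of 2–5 blocks each; blocks of 64 units (2048 bp); spacers of
2048 bp evolved from one random root along a random ultrametric coalescent
tree (root depth 0.05 subs/site) by Jukes–Cantor events (per-site Poisson;
every event redraws the base uniformly, so a branch of length b flips a
site with probability (3/4)(1−e^(−4b/3))); flanks of 120 kbp with a 20 kbp
boundary window.  All structural sizes are multiples of the 32 bp unit so
the 2048 bp block grid tiles caps exactly and planted block labels can be
compared one-to-one with classified blocks.

Variant structure: 4 block types, each drawing 85% of its units from its
own group of 3 single-substitution signatures (distinct consensus
positions) and 15% from the others; per-arm block-type propensities are
Dirichlet-distributed so arm compositions differ.  Methylation is
beta-binomial per CpG (satellite mean 0.80, spacer 0.40, flank 0.70,
concentration 50, Poisson coverage of mean 30 split over both strands);
real methylation pileups dictate no particular generative model, so
beta-binomial is the package's own choice of an overdispersed count model.  Boundary SD/gene
features are placed so that window density over flank density equals the
configured fold (default 5).

What the generator does not emulate: indels and structural mutation inside
spacers (substitution-only, by design, so MSA columns are true positions
and the RF-shift ground truth is exact), unit turnover processes
(units are drawn i.i.d. from profiles rather than evolved along the array),
read-level noise, assembly error, and the LINE/transposon content of real
spacers.  Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated model, not robustness to every
property of real assemblies.

## Numerical choices and degenerate inputs

Empirical p-values always use the add-one correction and are never 0.
Correlation distance is undefined for constant rows: the error names the
offending arm.  Silhouette selection skips k values where k-means collapses
to one cluster and errors if none remain.  JC69 errors on saturated pairs
(p ≥ 0.75), naming the pair.  NJ requires ≥3 taxa, trees for testing ≥4.
Ties in k selection prefer the smaller k.  The calibration fit errors on a
non-positive rate.  Degenerate exchange breakpoints outside cap spans are
rejected.

## Problem sizes

Default study sizes were chosen as the smallest at which each recovery is
statistically comfortable: ~1.5 Mbp six-arm genomes for the end-to-end run;
10 seeds for clustering recovery (ARI vs planted types); 2 kbp × 10 seeds
for NJ topology and 20 kbp for node ages; 200 null runs / 50 power runs for
the permutation tests with 199 shuffles (p resolution 0.005) or 150–200
bootstraps.

## Known limitations

Bootstrap support from plain resampling is not an AU p-value.  Strict-clock
dating is biased when lineage rates vary.  The anchor-chain aligner is
tuned for collinear, high-identity comparisons; it does not model large
rearrangements other than whole-segment orientation flips, and its identity
estimates inside anchor deserts rely on the banded realignment of chained
spans.  The center-star MSA is adequate for >90%-identical copies but not a
general-purpose aligner.  Real 32 kbp spacers and 2 Mbp windows are scaled
down ~16× and ~100×; absolute quantities that depend on genome scale
(counts of candidates, Mbp of insertions) are not comparable to full-genome
values.
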