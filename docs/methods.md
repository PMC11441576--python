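# Methods

This note documents the models, algorithms and numerical choices behind
`barcodelim`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the field's tool descriptions are
under-specified.

## Quality control

Sequences pass four rules in fixed order — *short* → *ambiguous* →
*stop_codon* → *duplicate* — and an excluded record carries only its first
failing rule. Length is counted over non-gap characters; "shorter than
600 bp" excludes 599 and retains exactly 600. The ambiguity screen caps
non-ACGT characters (default 0). The translation check translates the
ungapped sequence in all three forward frames under the invertebrate
mitochondrial code (NCBI table 5, configurable), skips codons containing
ambiguity characters, and fails a sequence whose *best* frame (fewest
stops, ties to the lowest frame index) still contains a stop — the
standard screen against NUMTs/pseudogenes. Reverse-complement frames are
not searched: amplicon-based barcodes arrive oriented. Duplicates are
exact ungapped string matches within one morphospecies, keeping the first
by input order. `apply_qc` is idempotent and never raises; malformed input
is rejected earlier, at I/O.

## K2P distances

For an aligned pair, sites where either sequence has a non-ACGT character
(gap, `?`, `N`, any IUPAC ambiguity) are excluded pairwise; ambiguity
codes never count as matches or mismatches. With transition proportion
`P` and transversion proportion `Q` over the `n_valid` remaining sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

If either log argument is non-positive the pair is **saturated**: it is
reported as a sentinel, excluded from means/minima/maxima (and counted),
and treated as infinitely distant by every clustering method (no edge,
never merged). Pairs overlapping at fewer than `min_valid_sites` sites
(default 300) are a hard error naming the pair — half a barcode of shared
signal is the floor below which K2P on ~658-bp COI fragments becomes
noise. Distances are stored as proportions and printed ×100 with 2
decimals, rounding half away from zero (rates print with 1 decimal).

Level summaries pool intraspecific pairs, different-species pairs sharing
a genus, and different-genus pairs sharing a subfamily; the remainder is
reported as "between subfamily". Per-species summaries report max/mean
intraspecific distance (undefined for singletons), the nearest-neighbour
species (minimum between-species distance, ties broken lexicographically)
and the barcode gap `min_inter_nn − max_intra`. A species is "accurately
defined" at threshold `t` iff `max_intra < t` (vacuously true for
singletons) **and** `min_inter_nn > t`; this operationalisation is a
package choice — published threshold statements rarely define the
predicate — and a flag excludes singletons entirely for sensitivity
analysis. `threshold_curve` exposes the maximising `t` over a grid.

## Haplotypes

Default condensation is strict aligned-string equality. The alternative
"ambiguity-compatible" mode treats `N`, `-`, `?` as wildcards and any
IUPAC set overlap as a site match, merging greedily in input order (order
dependence is inherent to greedy merging and documented rather than
hidden). Representative = first member; ids `H0001…` in appearance order.

## Distance-based delimitation

**Single-linkage threshold.** MOTUs are connected components of the graph
with edges where `d ≤ cutoff`. Components are labelled by their smallest
member id, making partitions order-invariant.

**Base-cutoff sweep (jMOTU-style).** Cutoffs of 1–50 bases are applied as
the transition-only K2P equivalent `-1/2·ln(1 − 2c/L)` rather than the
raw proportion `c/L`: K2P distances sit strictly above raw difference
proportions, so the raw threshold would fail to merge pairs differing at
exactly `c` sites. Sequences whose ungapped length is below 95% of the
alignment length are excluded first and reported. MOTU counts are
monotone non-increasing across the sweep.

**Recursive barcode-gap partitioning (ABGD-style).** For each prior `P`
on a log-spaced ladder (default 10 values in [0.005, 0.1]): sort all
finite pairwise distances; find the first gap `(d_i, d_{i+1})` whose upper
end exceeds `P` and whose width exceeds `X` (default 1.0) times the local
mean gap over a window of `n_bins` (default 20) neighbouring ranks
(excluding the candidate gap itself); split by single linkage at the gap
midpoint; recurse within each group with the same prior. No significant
gap → one MOTU. Two deliberate choices: distances *below* the prior stay
in the list (only the gap's location is constrained — dropping them would
erase the barcode gap whenever it spans the prior), and the
moving-average slope is a documented surrogate for the original
published heuristic, parameter-compatible with `X` and the prior ladder.
Low priors over-split and the top of the ladder collapses everything, so
the pipeline's single representative answer is the **modal set-partition
across the ladder** (the stable plateau; ties prefer the coarser one).

**Ranked-score selection (ASAP-style).** Build the single-linkage
dendrogram (saturated pairs pushed beyond all finite heights). Every
distinct merge height `h` defines a candidate partition (clusters after
all merges at height ≤ `h`), scored by two ranked metrics:

* *group-homogeneity probability*: for the first merge **above** `h`, a
  one-sided rank-permutation test (999 permutations, seeded) of whether
  the between-subgroup distances exceed the pooled within-subgroup
  distances; Fisher-combined over simultaneous merges. A low probability
  is evidence the next merge would cross the barcode gap, i.e. stopping
  at `h` is right. Evaluating the merge above the cut (rather than the
  one forming it) makes this metric point at the same candidate as the
  gap metric on clean data.
* *relative gap width* `W = (next height − h)/h`, larger is better.

P-values are floored at `3/(1+n_perm)`, the Monte-Carlo resolution of a
999-permutation test: below it, estimates are statistically
indistinguishable, and without the floor permutation-draw jitter (0.001
vs 0.002) perturbs the ranking. The score is the mean of the two ranks
(rank 1 best, ties `min`); the winner is the lowest score, ties broken by
gap rank, then fewer MOTUs, then lower threshold.

## Tree-based delimitation (PTP)

The PTP model classes every edge of a rooted gene tree as *speciation* or
*coalescent*, each class with i.i.d. exponential lengths at its own rate.
A delimitation is an antichain of "species crown" nodes covering every
leaf; edges strictly below a crown are coalescent, the rest speciation,
so every root-to-leaf path crosses the transition at most once. Rates are
profiled at their MLEs (`λ = class size / class length sum`), giving

    logL = Σ_classes n_c·ln(n_c/B_c) − n_c ,

with an empty class simply omitted (single-class model). The search
criterion subtracts an AIC penalty of 2 when both classes are occupied,
so a tree with no real rate structure collapses to one MOTU.

The ML search is greedy hill climbing (moves: split one crown into its
children, or merge a full sibling set into its parent), taking the best
improving move until none exists, from the all-one-species start, the
all-singletons start, and 10 seeded random descents of varying depth. The
two fixed extremes matter: the likelihood surface between them is
valley-shaped and climbing from the root alone can stall. On trees with
≤ 7 leaves the search provably matches exhaustive enumeration in the test
suite.

The Bayesian variant runs Metropolis–Hastings over valid delimitations
(uniform proposal among legal split/merge moves with the exact Hastings
correction, flat prior, profile likelihood), discards a burn-in fraction
(default 20% of 500,000 generations), thins, and reports per-node support
(posterior frequency of being a crown) plus the modal sampled partition.
Zero-length branches are perturbed to 1e-9 with a warning; trees whose
root has more than two children are rejected as unrooted.

## Consensus layer

For every morphospecies and method: the number of distinct MOTUs touching
the species' sequences, and whether any of those MOTUs also contains
another species' sequence. Status rules, in precedence order:
**warning_split** if ≥ `split_quorum` (4) methods report ≥ 2 MOTUs;
**warning_merge** if ≥ `merge_quorum` (4) methods report a shared MOTU
(the published convention states the 4-method quorum only for splits; the
symmetric reading is applied to merges and is configurable);
**congruent** if ≥ `single_quorum` (3) methods report exactly one
unshared MOTU; otherwise **ambiguous** (rows meeting no quorum — e.g. 3
splits against 3 merged singles — need a residual category). Both warning
flags are recorded even though only one becomes the status. The match
rate is the congruent fraction, printed ×100 with 1 decimal.

A bundled reference table (`data/molytinae_warning_table.tsv`) carries
the published six-method MOTU counts for the 28 weevil morphospecies
flagged in a large COI survey of Molytinae; classifying it reproduces the
28 split warnings and anchors the worked-example tests.

## Synthetic data generator

`generate_dataset` emulates the statistical structure of a large COI
barcode survey of a diverse beetle group: per-species sampling is a
two-point mixture (44% singletons; the rest draw `1 + Geometric(p=0.14)`
capped at 55, mean ≈ 8), within-species divergence targets 2.9%,
between-species 22%, at 658 sites. Mutation is the K2P process itself — a
Poisson number of substitution events per branch, site-uniform, with
transition probability `κ/(κ+2)` (default κ = 2) — so the distance
estimator is exactly matched to the generator. Species ancestors sit at
`(inter − intra)/2` events/site from a common root (star phylogeny):
between-species *leaf* pairs then expect `inter` events/site once their
two `intra/2` tip branches are counted. Multiple hits occur, so realized
K2P sits slightly below the event count, with a Jensen-gap bias in the
other direction at high divergence; both shrink as the sequence length
grows, which the tests verify at 300 vs 3000 sites. Deep-split species
carry a second ancestor at inter-level divergence under one species label
(the truth partition splits them); merge pairs are two species labels
whose ancestors differ at intra level (the truth partition joins them).
Everything is byte-reproducible from the seed.

What the generator does **not** emulate: codon structure (so the
stop-codon screen must be disabled for synthetic runs and is tested on
constructed coding sequences), indels and length variation, NUMTs,
rate variation among lineages, and geographic signal. Passing recovery
tests therefore demonstrate algorithmic correctness under the assumed
divergence structure, not robustness to every artefact of real barcode
data.

`generate_ptp_tree` builds a rooted binary species backbone by random
sequential joining with Exponential(mean 1.0) edges and hangs a random
coalescent-shaped subtree with Exponential(mean 0.02) edges under each
species — exactly the two-class PTP generating model.

## Problem sizes and test design

The recovery experiments use 10 species × 3 sequences × 658 sites at
intra 1% / inter 10% over 20 seeded replicates (every distance method
must recover the truth exactly, ARI = 1), 5 species × 4 leaves two-rate
trees for PTP recovery (ARI = 1 in ≥ 16/20; the misses are genuine ML
optima that differ from the generating partition, not search failures),
and 51 species × 2 leaves (~100 edges per class) for rate recovery
(fitted means within 25% of truth in ≥ 90% of replicates, evaluated at
the true delimitation — the estimator property, uncontaminated by search
error). These sizes were chosen as the smallest at which the sampling
noise of each statistic is comfortably inside its acceptance band.

## Known limitations

* The ABGD and ASAP implementations are documented surrogates sharing the
  published methods' decision structure and parameters, not ports; on
  borderline datasets their MOTU counts can differ from the web services.
* Single-linkage chaining can bridge clusters through intermediate
  sequences at high cutoffs; this is inherent to the method family.
* PTP assumes the input tree is correctly rooted and its branch lengths
  are in substitutions/site; tree inference is out of scope.
* The consensus quorums assume roughly six methods; with many more
  methods the fixed quorums of 3/4 would need rescaling.
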