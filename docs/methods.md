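# Methods

## Genome model and the synteny index

A genome is an ordered sequence of gene-family tokens with strands;
nucleotide coordinates are never used, so "position" always means rank in
the gene order. Prokaryotic chromosomes are circular by default (an
explicit per-genome flag), and neighborhoods wrap around the origin;
linear genomes truncate at the termini.

The per-gene synteny index divides the overlap of the two
*k*-neighborhoods by min(|N₁|, |N₂|) with a floor of 1. The choice of
denominator matters only in edge cases: for circular genomes of length
≥ 2k + 1 both neighborhoods have exactly 2k members and the min-size
denominator coincides with the natural 2k. Taking the minimum (rather
than 2k, the maximum, or the union size) is what makes the identity
invariant SI(G, G) = 1 hold exactly for linear genomes, for genomes
shorter than 2k + 1, and at chromosome ends. At k = 0 a shared family
scores 1 by convention, which reduces 1 − SI₀ to the gene-content
distance exactly — the GC baseline is the k = 0 special case, and the
test suite asserts the reduction on random inputs.

Paralogs: when a family occurs multiple times in a genome, its per-gene
SI is the maximum over occurrence pairs (any conserved context counts),
and the union set J counts each family once. This is the conservative
choice; gene-order data with heavy, divergent paralogy is outside what
the index is designed to discriminate.

Directed-pairs (DP) baseline: an adjacency (x→y with strand signs) is
identified with its reverse-complement reading (y′→x′); similarity is the
number of shared canonical adjacencies divided by the number of
adjacencies whose two families are present in the other genome, averaged
over the two directions so the measure is symmetric. Unknown strands are
treated as +. A side with no comparable adjacency contributes 0.

Default neighborhood radius: k = 10. Smaller k maximizes separability
between differently diverged genome pairs but amplifies annotation noise;
the `si_vs_k_curve` calibration (SI of a genome against a
rate-P-relocated copy, swept over k) shows SI falling in P at fixed k and
rising in k toward 1 at the genome scale, with good separation around
k ≈ 10 for 500-gene genomes.

## Neighbor joining

Classic Saitou–Nei agglomeration, reimplemented for determinism: ties in
the Q criterion are broken by the lexicographic order of each cluster's
smallest leaf label, and negative branch lengths are clamped to zero with
the clamped mass logged. On additive matrices the implementation recovers
the generating topology and all path lengths to 1e-9 (property-tested
against randomly generated additive matrices up to 30 taxa, and
cross-checked against dendropy's independent NJ). Tie-heavy degenerate
matrices are resolved reproducibly but the particular resolution is a
convention, not an inference.

## Distribution bootstrap

For each genome pair the histogram f(SI) of per-gene SI values over J is
resampled with replacement — |J| draws per pair per replicate, mirroring
the resample-n-of-n convention on the units the average is taken over
(configurable via `--boot-samples`). Each replicate's matrix feeds NJ,
and each internal edge of the point-estimate tree is labeled with the
percentage of replicates containing its bipartition. Supports are
attached to the point tree; no consensus tree is computed. RNG streams
are derived per (master seed, replicate, pair), so replicates are
independent and the whole procedure is reproducible from one seed.
Collapsing contracts internal edges with support below a threshold (80 by
convention) into polytomies; unlabeled edges count as support 0 with a
warning.

Degenerate pairs behave as expected: identical genomes have all histogram
mass at SI = 1, so their bootstrap distance is 0 in every replicate, and
disjoint pairs are likewise pinned at 1.

## Simulator

Species trees follow the Yule pure-birth process: a uniformly chosen
extant lineage splits until the target leaf count. Edge lengths are
i.i.d. Exponential(edge_rate) by default — lengths represent waiting
times of the event process, not a clock. A strict molecular-clock variant
(`ultrametric=True`), with node heights from the Yule waiting times
themselves, is available but off by default; the two readings are both
defensible and the default is the one under which event counts on an edge
are proportional to its drawn length.

Genome evolution: the root genome is `root_size` fresh families in order
(default 500, a realistic small prokaryotic gene count). On each edge the
number of events is Poisson(event_rate × length × genome size at the top
of the edge) — the rate is per gene, so bigger genomes experience more
events. Each event is a gain with probability p_hgt, inserting a
brand-new family at a uniform position (horizontal acquisition from
outside the sampled taxa), otherwise a loss of a uniform gene. Gains
never copy between contemporaneous lineages; with gains modelled as novel
families, leaf genome pairs show intersection fractions in the observed
0.2–0.4 range at moderate rates, which is the regime the distances are
meant to operate in. A genome shrinking to zero genes is a hard error
asking for rate recalibration rather than a silent degenerate output.

The pairwise perturbation operator used for calibration relocates each
gene independently with probability P (excise + uniform reinsertion),
preserving gene content exactly so that only the synteny signal degrades.
At P = 1 on a circular n-gene genome the expected per-gene SI approaches
the chance-overlap baseline 2k/(n − 1), which the tests verify by Monte
Carlo.

What the simulator does not emulate: inversions and block rearrangements,
operon-scale co-transfer, replacement-style gains, donor-recipient
transfer within the sampled set (a `--donor-pool` mode was considered and
dropped as unspecifiable without further assumptions), annotation error,
or paralogy. Passing benchmarks therefore demonstrate correctness of the
method under gain/loss/relocation dynamics, not performance on real
annotation pipelines.

## Tree comparison

RF similarity counts shared informative bipartitions divided by n − 3,
the maximum attainable by a binary tree — partially resolved trees can
never score 1 against a binary tree, deliberately avoiding the known bias
of RF variants that flatter unresolved consensus trees. Induced quartet
topologies are read off topological (unit-weight) leaf distances via the
four-point condition; the test suite checks this route against an
independent split-membership oracle. Quartet fit is exhaustive when
C(n, 4) is small and seed-deterministic sampling with replacement
otherwise; quartets left unresolved by polytomies count as disagreement
unless compatibility counting is requested. The significance of a quartet
fit a over m quartets uses the Chernoff bound exp(−m·D(a‖1/3)) with D the
Kullback–Leibler divergence in nats; for a < 1/3 the one-sided bound is
reported as 1. MAST is computed exactly: both trees are rerooted at each
shared leaf and the classic quadratic agreement-subtree recursion for
rooted binary trees is run on the remainder; the overall cost is cubic,
fine for the tens-of-taxa trees compared here. Polytomous inputs are
refused rather than silently resolved.

## Random-tree nulls and the attachment rule

"Random binary tree" here means the sequential attachment process: start
from the 3-leaf star and attach each next taxon to a uniformly chosen
edge. Uniform choice over *all* 2m − 3 edges makes every unrooted binary
topology equiprobable, and under that distribution a fixed quartet
topology is induced with probability exactly 1/3 (verified by enumerating
all 15 five-leaf topologies: each quartet resolution appears in 5).

The zero-overlap mass of the RF null is sensitive to the attachment rule.
For 89-leaf trees, uniform-attachment pairs share no informative split in
about 87–88% of cases (the expected number of shared splits is
Σ_A P(A)² ≈ 0.13, dominated by cherries, giving e^−0.13 ≈ 0.88);
restricting attachment to pendant edges — which is exactly Yule lineage
splitting and produces cherry-richer trees — lowers the zero-shared
fraction to about 80%. Published figures for this experiment vary with
that (often unstated) choice; `random_rf_null` defaults to the uniform
rule and exposes `attachment="leaf"` for the Yule variant, and both
variants agree that observed RF similarities above ~12% of splits
essentially never occur by chance at this tree size. The null experiment
runs on a bitmask split representation without building tree objects
(~0.4 ms per pair), so the full 100,000-pair experiment takes well under
a minute.

## Numerical conventions and scales

Distance matrices are validated on construction (symmetry to 1e-9, zero
diagonal, non-negativity). Phylip square output carries 6 decimals;
round-trips are exact to that precision. Bipartitions are canonicalized
as the side not containing the lexicographically smallest leaf label.

Problem sizes used by the shipped checks: reconstruction benchmarks run
at 20 taxa × 200-gene genomes × 10 replicates with rates spanning the
informative regime (0.1–0.3 events per gene per unit length); calibration
curves use 120–200-gene genomes with 30 replicates per rate; the RF null
ships as a 10,000-pair check alongside the full 100,000-pair experiment
in `scripts/acceptance.py`. These sizes give stable orderings (Monte
Carlo error well below the effects asserted) while keeping a full run in
tens of seconds.

## Known limitations

- Orthology assignment is assumed given and correct; the package never
  touches sequences. Family vocabulary mismatches between annotation
  sources will read as spurious distance.
- The SI distance is not additive; NJ on it is a heuristic (as for most
  genome-scale distances), and branch lengths should be read
  comparatively, not as time.
- Genomes dominated by repeats/paralogs weaken the index (the max-over-
  occurrences rule can only soften, not fix, this).
- MAST and exhaustive quartet fit are exact but polynomial; they are
  meant for the tens-to-low-hundreds of taxa this tool targets.
- Tie-breaking in NJ and the arbitrary chromosome break point of circular
  genomes are conventions; both are deterministic and documented, but
  alternative conventions can change degenerate-case outputs.
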