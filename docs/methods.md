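# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `phyloaudit`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Substitution model

The engine and the simulator share one model: general time-reversible (GTR)
with six symmetric exchangeabilities and four equilibrium frequencies. The
rate matrix is normalized so that −Σᵢ πᵢ qᵢᵢ = 1, i.e. one expected
substitution per site per unit branch length; branch lengths and the
campaign's α scale factor are therefore directly interpretable as expected
substitutions per site. Transition matrices come from the eigendecomposition
of the reversibly-symmetrized matrix D^{1/2} Q D^{−1/2} (symmetric, so
`numpy.linalg.eigh` applies); tiny negative entries from roundoff are
clipped at zero, and rows are renormalized in the simulator's sampling path.

Among-site rate variation is the discrete-Gamma approximation: k equal
probability categories (default k = 4, shape default 1.0) whose rates are
the conditional means of Gamma(shape, rate = shape) on the category
intervals, computed from regularized incomplete-gamma differences and
renormalized to mean exactly 1. A median-based discretization is available
behind a flag (`median_rates`). An optional invariant-site proportion adds a
zero-rate category with the Gamma rates rescaled so the mixture mean stays
1; the campaign uses 0.

Defaults (equal exchangeabilities, equal frequencies, shape 1, k = 4, no
invariant sites) are the campaign's simulation conditions. `+F`-style
empirical frequencies can be counted from an alignment via
`GTRModel.with_empirical_freqs`.

## Simulation campaign

Reference trees are fully balanced rooted binary trees: every external
branch α, every internal branch α/2. The star variant zeroes the six
internal branches nearest the root (the two root-child edges and four
grandchild edges), so contracting the zero branches leaves a root polytomy
of eight 8-leaf subtrees. Note that in the *unrooted* view the two α/2
branches at the root merge into a single branch of length α; all topology
and branch-length comparisons in this package act on that unrooted view.

The default design is 15 α values × 2 shapes × 500 alignments per tree
= 15 000 alignments of 64 taxa, lengths drawn as uniform integers on
[300, 1000] inclusive (the simplest distribution consistent with a stated
range). Sequences evolve by drawing each site's rate category once, root
states from the equilibrium frequencies, and child states from the
categorical rows of P(rate · branch length) down the tree.

Every alignment has a counter-derived seed,
`SeedSequence([master_seed, tree_index, alignment_index])`, which drives
first the length draw and then the simulation; a single file is therefore
regenerable in isolation, and two campaign runs with the same master seed
are byte-identical. `run_campaign(..., limit=k)` caps the per-tree count for
smoke-scale runs without changing any seed.

## Likelihood engine

Alignment columns are compressed to unique site patterns (lexicographically
sorted — the canonical order) with multiplicities. Conditional likelihoods
are computed by Felsenstein pruning over patterns with per-pattern
log-scaling against underflow; leaves use IUPAC ambiguity masks (gaps and
`N` are fully ambiguous).

**Summation modes.** Per-site log-likelihoods are combined into a tree score
under an explicit mode: `exact` (compensated Kahan summation over the
canonical pattern order; permutation-invariant, and exactly additive under
alignment duplication), `sequential`, `reversed`, `blocked:K` (K contiguous
blocks summed independently then combined, modeling a K-thread partial-sum
reduction), and `shuffled:S` (a pseudorandom site order with order seed S,
modeling a different processor kernel's operation order). The modes agree to
far below any scientifically meaningful difference (≪ 10⁻⁶ per site) yet
generally differ in the last few bits — which is the audited mechanism. The
mode applies where tree scores are *compared* (move acceptance during the
search, selection across starts); branch-length optimization always uses
pattern-level compensated summation internally so the optimizer itself is
stable and mode-independent.

**Branch lengths.** Each branch is optimized by safeguarded Newton-Raphson
on the per-edge likelihood, using analytic first and second derivatives from
the eigendecomposition (multiplicative fallback steps when the curvature is
unusable, bounds [10⁻⁸, 10], absolute step tolerance 10⁻⁶ by default; the
returned length is the best point visited, so the per-edge likelihood never
decreases). Sweeps over all edges are true coordinate ascent: after each
edge update the edge's contribution and all ancestor partials are refreshed,
which matters on degenerate directions such as the two root-adjacent
branches of a two-taxon tree, where stale-cache updates oscillate.
Optimization terminates when a full sweep improves the log-likelihood by
less than epsilon (default 10⁻⁴, the audited protocol's value) or at a sweep
cap (default 100, with a warning).

**Search.** Starting trees are built by sequential taxon addition in a
seed-shuffled order: `random` attaches each taxon to a uniformly random
edge; `parsimony` attaches it to the edge minimizing the weighted Fitch
score. The multi-start search (default 20 starts: half parsimony, half
random) hill-climbs over NNI (default) or SPR, first-improvement in a
deterministic enumeration order, accepting strictly improving moves only.
Candidate moves are scored after re-optimizing just the edge(s) the move
touched; a move that gains more than epsilon triggers a one-sweep length
refit, and a full re-optimization runs at the end of each climb. Because
acceptance is strict and near-tied candidates differ only in the last bits
of the score, the summation mode decides these ties — by design. A round cap
(default 50) bounds plateau wandering. Across starts, the best score wins;
starts within epsilon of the maximum are tie-broken by the lexicographically
smallest canonical topology key (the sorted tuple of nontrivial
bipartitions), so the engine is a pure function of (alignment, model,
config). Every result logs the full configuration — seeds, mode, epsilon,
search counts — implementing the recommendation that analyses disclose the
parameters that actually determine their output.

**Bootstrap.** Standard nonparametric column resampling; each replicate is
re-searched by NNI starting from the ML tree, and supports are the
percentage of replicate trees containing each bipartition.

**AU test.** Per-site log-likelihood vectors (after per-topology
branch-length optimization) are resampled at scales r ∈ {0.5, …, 1.4}
(default 1000 multinomial resamples per scale). Resample wins are shared
equally across exact ties. Each topology's acceptance probability curve is
fit by weighted least squares on the probit scale against √r and 1/√r to
estimate the signed distance d and curvature c, giving p = 1 − Φ(d − c);
the flag marks p ≤ 0.05. The scale set, resample count, and fitting method
are exposed in the call signature.

## Tree distances and classification

nRFD divides the Robinson–Foulds count by 2(n−3) — the maximum between two
binary unrooted n-leaf trees — even for multifurcating (collapsed) inputs,
so collapsed and uncollapsed analyses remain comparable. KF is reported as
the plain sum of squared branch-length differences over matched bipartitions
(external edges matched by leaf, internal edges by canonical split, an
unmatched edge contributing its squared length); a square-rooted accessor
exists because some packages report that convention, and the package does
not guess which convention produced any external table. The percentage of
shared bipartitions with different support is defined only when the
topologies are identical, and counts strict numeric inequality on a common
support scale (percent and probability scales are never silently mixed).
Support-threshold collapsing is inclusive (support ≤ threshold contracts the
edge) and never touches edges without a support value.

Replicate outcomes are classified exactly by (nRFD, KF): identical /
same-topology-different-lengths / irreproducible-topology. |ΔlogL| between
the two final trees is always computed in exact summation mode so that it
reflects topology and length differences, not summation noise. KF is
compared against exactly zero: under the identical scenario the engine is
bitwise deterministic, so "identical" means identical, and any nonzero KF is
a real (if tiny) length difference.

## Audit scenarios

`identical` runs the same configuration twice (verified equal before
execution). `order` gives Run1 sequential summation and Run2 a shuffled
order seeded per gene — the single-machine emulation of executing replicates
on nodes with different kernels or thread counts. `seed` changes only the
search's starting seed. Per-gene seeds derive from the audit seed and the
manifest's (tree, alignment) counters, so reports are byte-identical across
re-runs; per-gene results can be cached by configuration fingerprint and
audits resumed. Stratified summaries report category percentages (summing to
100 per stratum), mean nRFD among irreproducible genes, mean |ΔlogL|, and
class means of informativeness and gene-tree error; AU screening of
irreproducible pairs is optional because it multiplies runtime.

## Species stage

Concatenation builds a supermatrix over the union of taxa (gaps for missing
blocks). The coalescent-style stage is a deliberately small stand-in:
the species topology maximizes the number of induced quartet topologies
shared with the gene trees, exhaustively over all (2n−5)!! topologies up to
8 taxa (deterministic lexicographic tie-break), and by greedy consensus +
NNI hill-climbing above that (with a warning). Edge support is gene-tree
concordance — the fraction of gene trees containing the bipartition — which
is clearly labeled and deliberately simpler than a local posterior
probability. Species-level replicate comparisons report tree distance (%),
branch distance (None when either tree lacks lengths, as quartet trees do),
and the support-difference percentage (None when the topologies differ).

## Problem sizes used by the tests

The packaged test suite runs the audits at desk scale, as the package's own
choice of problem size: 16-taxon reductions of the campaign trees, 2 tree
searches per run (one parsimony, one random start), a 12-round NNI cap, 100
genes for the identical-scenario determinism check, and 100 genes per α at
α ∈ {0.001, 0.1} for the summation-order mechanism. The mechanism is not
delicate at this scale — at α = 0.001 a majority of genes flip topology
under an order change while at α = 0.1 essentially none do — but the
*percentages* produced at 16 taxa with 2 starts are not calibrated to any
external study and should be read qualitatively.

## What the simulations do and do not show

The generator reproduces the campaign's stated conditions: known reference
topologies, GTR+Γ₄ with equal frequencies, no indels, no alignment error, no
model misspecification, equal rates across lineages, and complete taxon
sampling. Passing audits therefore demonstrate the mechanism — summation
order flips effectively tied searches, preferentially for low-information
genes, and those genes carry larger estimation error — under clean
conditions. Real data add alignment uncertainty, heterotachy, and model
misfit, all of which plausibly increase the pool of near-tied topologies;
the simulated irreproducibility rates are not predictions of empirical
rates.

## Known limitations

- DNA only in the engine (alignment statistics accept amino acids).
- NNI/SPR hill-climbing is a compact stand-in for production search
  schedules (no lazy SPR radii, no stochastic perturbation phases); the
  engine audits reproducibility mechanisms, it does not race external tools.
- The blocked/shuffled summation modes are an explicit abstraction of
  kernel- and thread-order effects, not a bit-accurate emulation of any
  particular SIMD kernel.
- The quartet species-tree optimizer is exhaustive only to 8 taxa and its
  greedy fallback carries no optimality guarantee.
- KF values near the bottom of double precision (≲10⁻¹⁵) are reported raw;
  callers decide what to treat as zero when supports or lengths come from
  external tools.
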