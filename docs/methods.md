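# Methods

## Substitution model and likelihood

The engine implements GTR+I+G on nucleotide alignments.  The rate matrix
is Q with q_ij = s_ij·π_j for i ≠ j, GT exchangeability fixed at 1,
rows summing to zero, scaled so the mean rate −Σ π_i q_ii equals 1:
branch lengths are expected substitutions per site.  Transition matrices
come from the symmetric eigendecomposition of D^{1/2} Q D^{−1/2}
(D = diag π), with eigenvalues clamped at zero — exact for a CTMC
generator and immune to overflow at extreme trial parameters.  A direct
`expm`-based `transition_matrix` is also exposed; a test cross-checks the
two paths on 200 random parameter draws.

Per-site likelihoods follow the pruning algorithm over compressed site
patterns, with per-node rescaling to prevent underflow.  Rate variation
mixes a proportion p_inv of invariant sites with m equal-probability
discrete-gamma categories (category means, m = 4 by default):

    L_site = p_inv · [site can be constant in x] · π_x
             + (1 − p_inv) · (1/m) · Σ_c L(site | r_c)

The gamma category rates are normalized to mean 1 on their own (they are
not rescaled by 1/(1 − p_inv)); branch lengths are therefore in expected
substitutions per *variable* site when p_inv > 0.  This is one of the two
standard conventions; it is applied consistently in simulation and
inference, so round-trip parameter recovery is exact.  Gaps and ambiguity
codes are marginalized — a tip contributes partial likelihood 1 over
each state its character allows — never treated as a fifth state.

Optimization is coordinate ascent: each branch length by bounded Brent
search on [1e−8, 10], substitution parameters jointly by L-BFGS-B on
unconstrained transforms (log exchangeabilities, frequency logits,
log α, logit p_inv), repeated until the lnL gain drops below 1e−4 (at
most 100 rounds; non-convergence flags the result rather than raising).
A trial point whose lnL evaluates positive — impossible for probabilities,
so necessarily numerical breakdown — is rejected, and the optimizer
never returns a point worse than its start, which makes warm-started
nested fits monotone by construction.

Topology search is greedy nearest-neighbor interchange from a
neighbor-joining start tree (Jukes–Cantor distances).  Candidate moves
are scored with a single cheap branch-length sweep; the accepted move is
refined before the next round, and accepted lnL values increase
strictly.  Bootstrap supports are plain nonparametric bootstraps (sites
resampled with replacement, branch lengths refit, optional NNI), written
as percent of replicates containing each bipartition.  UFBoot is not
reimplemented: the analysis consumes supports only through thresholds.

## Partition linking and combinability

Five linking schemes are fitted, nested in this order: unpartitioned,
edge-equal, edge-proportional, edge-unlinked, separate trees.
Edge-proportional gives each partition a rate multiplier constrained to
site-count-weighted mean 1, contributing p − 1 free parameters; this is
the unique convention under which the free-parameter count for two
edge-proportional organellar gene sets (79 + 39 partitions, 226 taxa,
10 substitution parameters each) is 790 + 390 + 449 + 449 + 78 + 38 =
2194, and under which the BIC−AICc gaps of the proportional fits match
their published counterparts.  AICc uses n = total aligned sites.

Separate-trees candidates are scored by summing lnL, n and k across the
per-dataset fits before computing the criteria; candidates in one
ranking must agree on total n (enforced).  Within a fitting chain, each
scheme warm-starts from the previous one's optimum (equal from
unpartitioned, proportional from equal with multipliers 1, unlinked from
the proportional per-partition trees), so maximized lnL is non-decreasing
along the nesting order up to optimizer tolerance.

Greedy partition merging works under the edge-proportional model on a
fixed topology: branch lengths are re-optimized once per round (not per
candidate pair), each pair merge is scored by refitting the merged
cluster's substitution parameters and rate multiplier on the fixed tree,
and the best strictly-improving merge (BIC by default) is applied until
none improves.  Ties break on the lexicographically smallest pair of
cluster names; merged clusters are named by joining their members with
`+`, which is also how the cluster-composition summary recovers
memberships.

## Tree comparison and conflict

Robinson–Foulds distances are unweighted symmetric differences of
canonical non-trivial splits; trees on unequal leaf sets are pruned to
the intersection first, and with a support threshold both trees are
collapsed before comparison (edges lacking supports collapse — the
conservative reading).  The tree network merges topologies at RF 0 into
one node and weights edges 1/RF; the undefined inverse at RF 0 never
arises because such pairs share a node.  The Fruchterman–Reingold layout
is implemented natively without post-scaling, so its coordinates satisfy
force balance: attraction w·d²/k against repulsion k²/d puts an isolated
edge's endpoints at distance k·w^(−1/3), which the tests verify against
that closed form.

Conflict mapping classifies each gene tree against each internal
reference split after restricting the split to the gene's taxa:
concordant if the restricted split occurs in the gene tree, conflicting
if any gene split is incompatible with it (witnessed by the
most-supported incompatible split), uninformative if the restriction is
trivial or the gene tree is unresolved there.  "Strong" requires the
witnessing split's support to reach the threshold (default 95%).
Unresolved-but-compatible gene trees count as uninformative, not
concordant; reference edges whose restrictions coincide are tallied
independently.

## Clock metrics

Midpoint rooting places the root halfway along the longest tip-to-tip
path; diameter ties break on the lexicographically smallest tip pair.
Root-to-tip variance is the sample variance (n − 1 denominator) of
root-to-tip path lengths — zero for an ultrametric gene, growing with
lineage rate heterogeneity.  Tree trimming to a gene's taxon set sums
branch lengths through suppressed degree-2 nodes and keeps the maximum
support along a suppressed path.

## Composition-shift detection

Shifts in compositional heterogeneity are modeled deliberately simply:
each tip's unambiguous base counts are a multinomial draw from the
equilibrium frequencies of the regime painted on its subtending edge.
Regime paintings start at the root (regime 0); each added regime begins
at one shift edge subtending at least `min_clade` = 4 tips and is
inherited by the whole clade until overridden by a nested shift.
Maximum-likelihood regime frequencies are pooled count proportions
(additive smoothing of 0.5 per cell if any pooled count is zero); the
greedy search adds the candidate edge with the best BIC improvement
(3 free frequencies per regime, n = total counted bases) until nothing
improves or `max_shifts` = 10 is reached.  This implements shift
detection on a fixed topology with a fully testable likelihood; it is
not claimed to reproduce any particular external tool numerically.

A painting is identifiable from tip counts only if each regime is
*expressed* at its tips.  The planted-truth validation therefore plants
ancient shifts — the shift edge stretched to 1.0 substitutions per
site, so the new equilibrium is reached by the clade ancestor.  Shifts
on short stems leave tip compositions in transit between regimes (a real
within-clade gradient), and no tip-multinomial method can recover the
painting exactly there; at intermediate depths the same gradient makes
the BIC search split genuine sub-structure.  This is the method's main
limitation on real data: recent shifts and gradual compositional drift
are reported as approximate or multiple paintings.

## Synthetic data

The generators emulate the two-organelle study design: one taxon set;
a gene-rich, faster-evolving "plast" set (default 8 genes, rate 2.0,
per-gene log-normal rate multipliers with σ = 0.3) and a smaller, slower
"mito" set with broader rate spread (5 genes, rate 1.0, σ = 0.8);
500–2000 sites per gene; uniform taxon dropout to 90% occupancy;
optional distinct true topologies at a requested minimum RF; optional
clade-restricted composition shifts (instantaneous π change at the shift
edge).  Defaults are desk-scale — 16 taxa rather than hundreds — chosen
so model selection is decisive while full studies run in minutes.  Every
generator is a pure function of its seed.

What the generators do *not* emulate, and hence what passing tests do
not establish about real data: indels and alignment error, codon
structure and selection, structured (non-uniform) taxon occupancy,
RNA editing, horizontal transfer, and gradual compositional drift.  The
validation shows the estimators recover the truth of this generating
process, not that organellar data satisfy it.

## Numerical and design choices

- Branch-length bounds [1e−8, 10]; optimizer tolerance 1e−4 lnL units.
- Gamma discretization by category means over equal-probability bins.
- Base frequencies start at empirical counts and are ML-optimized when
  free; plain-GTR fits (exchangeabilities + frequencies, 8 parameters)
  are the default for per-partition likelihood contributions.
- Support values are percentages; an all-fractional Newick file is
  auto-rescaled to percent with a warning.
- Supermatrix cells for taxa missing a gene are gaps (full-ambiguity
  states), not N — both are uninformative to the likelihood.
- Internal coordinates are 0-based half-open; 1-based inclusive only in
  partition files.
- All randomness takes explicit integer seeds; there is no global RNG
  state anywhere in the package.

Validation problem sizes: likelihood oracles use ≤ 5 taxa × ≤ 50 sites
against exhaustive state enumeration (agreement to 1e−9); combinability
uses 8 taxa × 3000 sites per dataset over 20 replicates per condition;
merging uses 6 taxa × 4 × 300 sites; shift recovery uses 16 taxa × 2000
sites.  These are the package's desk-scale study conditions; the same
code paths scale to organellar supermatrices.
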