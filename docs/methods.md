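# Methods

This note records the models, algorithms and numerical choices behind
`treelen`, in enough detail that every reported number can be traced to a
decision made here.

## Edit costs

A cost scheme is `(match, transition, transversion, gap_open, gap_extend)`.
Substitutions split purine↔purine / pyrimidine↔pyrimidine exchanges
(transitions: A↔G, C↔T) from the rest (transversions).  A maximal gap of
`l ≥ 1` columns in one alignment row costs `f(l) = gap_open + gap_extend·l`,
charged once per maximal run; `f(0) = 0`.  `gap_open = 0` is a *simple*
(linear) gap cost, `gap_open > 0` *affine*, `gap_open = ∞` forbids indels —
the maximum-parsimony limit, in which treelength equals the parsimony score
(verified against an independent per-site Sankoff dynamic program in the
tests).

Costs are `fractions.Fraction` values; before any dynamic program they are
rescaled by the least common multiple of their denominators to integers, so
all scores, comparisons and tie-breaks are exact.  Reported scores are
rendered with 6 decimals alongside the exact fraction.

Terminal gaps are charged exactly like internal gaps: nothing in the
criterion's definition exempts sequence ends, and exempting them would make
treelength non-additive over edges.

The preset constants (`simple1`: all events 1; `simple2`: indel =
transversion = 2, transition = 1; `affine`: gap_open 2, gap_extend ½,
transition 1, transversion 2) follow the prior studies this family of
criteria comes from and are deliberately config-overridable — the package
fixes the structure of the three criteria, not the numbers.

Ambiguity handling is an extension: by default only `{A,C,G,T}` are
accepted; a permissive parsing flag collapses IUPAC codes to `N`, and `N`
matches any base at cost 0.

## Pairwise alignment

Three-state Gotoh dynamic programming (match / gap-in-a / gap-in-b), integer
costs, full `O(nm)` tables.  Opening a run charges `gap_open + gap_extend`;
extending charges `gap_extend`.  Traceback is deterministic with tie order
*diagonal, gap in sequence b's row, gap in sequence a's row* — determinism
here is load-bearing, because the implied alignment downstream is defined in
terms of these tracebacks.  A brute-force oracle that enumerates every
monotone alignment of short sequences (including never-optimal
insert-then-delete adjacencies) is kept in the public API for testing.

## Fixed-tree treelength

Finding optimal ancestral sequences is NP-hard even for a known tree, so
three solvers with different cost/guarantee trade-offs are provided.  All
traversal roots at the internal node adjacent to the lexicographically
smallest leaf label (determinism); polytomies are scored as-is, never
resolved first.

* **lifted** — every internal node receives some leaf's sequence; the
  optimal such labeling is found by dynamic programming over the all-pairs
  leaf distance matrix (`cost(v,c) = Σ_w min_{c'} cost(w,c') + D[c][c']`).
  Under a metric edit distance the optimal lifted labeling is within a
  factor 2 of the true fixed-tree optimum; the tests assert this bound
  against the exact solver.  The distance matrix can be shared across many
  trees on the same sequences, which is what makes pool scoring cheap.
* **do** — a direct-optimization-style pass: post-order, each internal node
  takes the column consensus of the optimal pairwise alignment of its
  children's sequences (base/base ties → alphabetically first base;
  base/gap → keep the base, so ancestors stay gap-free).  A hill-climbing
  pass then repeatedly replaces a node's sequence by a neighbor's sequence
  or by a freshly folded consensus of its neighbors whenever that lowers the
  node's incident edge-cost sum, iterating to a fixed point (at most 20
  sweeps).  The keep-the-base consensus rule makes ancestors drift toward
  the union of descendant sites, so `do` is not dominant over `lifted`;
  paired comparisons on simulated data (reported by the test suite) show it
  wins or ties in a clear majority of instances with a median ratio of 1.0.
* **exact** — Sankoff-style dynamic programming over the space of *all*
  strings up to a length bound (default 4, alphabet restrictable), giving
  the global optimum over that enumerated space.  Feasible only for ≤ 5–8
  taxa and very short sequences; it is the oracle the heuristics are tested
  against.  The candidate space and its distance matrix are cached per
  (alphabet, bound, scheme).

The treelength stored on an assignment is always recomputable from the node
sequences (edge-sum identity, asserted in tests with exact arithmetic).

## Implied alignment

Each edge's optimal pairwise alignment (parent row first) pairs sites of the
two endpoint sequences; the transitive closure of these pairings across all
edges partitions sites into homology classes — the alignment columns.
Column order is the delicate part: the package takes the precedence relation
"class A immediately precedes class B in some edge alignment" and
topologically sorts it (Kahn's algorithm, ties broken by each class's
smallest (node, site) member).  This subsumes within-sequence site order and
reproduces the edge alignment column-for-column on 2-leaf trees.  Closure
across different paths can in principle create precedence cycles; when the
sort stalls, a frontier sweep emits, among the remaining classes, whole
classes whose members are all next-in-order for their sequences, and
otherwise splits a class (emitting only its frontier members) chosen by
smallest member key.  Splitting preserves the two hard invariants — every
row reads out its sequence in order, and no emitted column is empty — at the
price of extra columns, and only triggers on genuinely conflicting
closures.  Rows are finally restricted to leaves and leaf-all-gap columns
dropped.

## p-ECR moves and the candidate-pool search

A p-ECR move contracts `p` internal edges chosen uniformly without
replacement (the move's definition says only "randomly selected"; uniform
without replacement is the natural reading) and then refines every polytomy
back to binary by repeatedly grouping a uniformly chosen pair of its
incident branches under a new node.  Consequences asserted in tests: output
is binary with the same leaf set, every input bipartition of the collapsed
tree survives, and the missing branch rate between input and output is at
most `p/(n−3)`.  `p` is clamped to the number of internal edges with a
warning on small trees.

The search scores a pool consisting of the starting trees — user-supplied,
and/or internal baselines: neighbor joining on the all-pairs edit-distance
matrix (via scikit-bio, labels sorted for determinism) and uniformly random
topologies — plus, per starting tree, 20 neighbors produced by independent
p-ECR moves with `p ~ Uniform{1..5}` (both counts configurable; draws are
not deduplicated).  Non-binary starting trees are randomly refined before
perturbation but scored as supplied.  Pool scoring defaults to `lifted`
(fast, shares one distance matrix); ties break by insertion order.  Because
every starting tree is in its own pool, the winner is never longer than any
of them — the "never worse than the baseline" guarantee, equivalently
normalized scores ≤ 1.  The first pool member is the normalization baseline
(override by flag); a zero-treelength baseline (identical sequences) yields
NaN with a warning.

The search is single-round by design: it samples neighborhoods once rather
than iterating hill-climbing over tree space.

## Error metrics

*Missing branch rate* = |bip(ref) \ bip(est)| / |bip(ref)| over non-trivial
bipartitions.  The denominator is deliberately the reference's internal
edge count: the symmetric Robinson–Foulds distance rewards unresolved
estimates, while the false-negative convention does not.  For binary pairs
the two agree up to the factor 2(n−3) (cross-checked against dendropy).
A reference with no internal edges gives NaN with a warning.

*SP-FN* = 1 − |H(est) ∩ H(ref)| / |H(ref)| where H(A) is the set of residue
pairs `((taxon_i, site_k), (taxon_j, site_l))` co-occurring in a column,
taxa ordered, sites indexed within degapped sequences.  It is 0 exactly when
the estimate's pair set contains the reference's.  Inputs must degap to the
same sequences; ambiguity codes are rejected.

*Majority consensus* keeps splits in strictly more than half of the input
trees (a split in exactly half is excluded) and assembles them rooted at an
anchor taxon, largest clade first — strict-majority splits are always
pairwise compatible.

## Simulator

The generator emulates indel-aware sequence evolution: i.i.d. uniform root
sequence (default 200 sites in library use; 120 in the acceptance pipeline,
80 in the README example — sizes chosen to exercise every code path at desk
scale); per branch of length `b`, each site receives
`Poisson(substitution_rate·b)` substitution events (transition with
probability `k/(k+1)`, `k` = ts/tv event ratio, default 2), and
`Poisson(indel_rate·b·L)` indel events are applied sequentially — insertion
with probability `insertion_fraction` (default ½) at a uniform position,
else a deletion at a uniform position, lengths drawn from the configured
gap-length model.  Insertions mint fresh homology columns spliced into a
global column order immediately after their anchor; deletions remove sites
from the lineage.  The true alignment is read directly off this bookkeeping,
so rows degap to the leaf sequences by construction.

Gap-length models: geometric(p) (mean 1/p), or a mixture of geometrics —
included because real reference alignments show heavy-tailed gap lengths
(median 1 with very long tails) that no single geometric reproduces.  The
preset bundles short/medium/long (p = 0.5, 0.25, 0.1) give stochastically
ordered mean gap lengths; they are qualitative axes, not replicas of any
particular published parameterization.  Every drawn indel length is recorded
on the simulation record; distribution-recovery tests use these draws
rather than maximal gap runs of the alignment matrix, because independent
events landing on adjacent columns merge into one run and bias the run mean
upward by more than the sampling error at any useful event density (the run
mean is separately sanity-checked from below).

The *reference tree* contracts every internal branch whose realized event
tally is (0 substitutions, 0 indels) — realized counts, not expectations —
since recovering a branch on which nothing happened is chance.  Branch
lengths of zero are legal (they generate no events and are then contracted);
only negative lengths are errors.  Empirical statistics (setwise/edgewise
p-distances excluding gap-paired sites, gap percentage, gap-run summaries,
column count, reference-tree resolution = internal edges / (n−3)) summarize
each dataset.

What the simulator does *not* model: rate heterogeneity across sites, codon
or amino-acid alphabets, selection, and realistic long-tailed biological gap
distributions beyond the mixture option.  Tests passing on this generator
therefore demonstrate correctness of the algorithms under the stated model,
not accuracy claims about any particular biological dataset.

## Randomness and determinism

All stochastic operations are pure functions of (input, seed), using numpy's
default generator; composite operations pass one generator through their
sub-steps, so a single seed reproduces an entire search or simulation.  The
CLI defaults and echoes seeds, and embeds scheme name, seed and version in
its reports.

## Problem sizes

The test suite and the acceptance pipeline run on deliberately small
instances — enumeration oracles at sequence length ≤ 6, exact fixed-tree
solving at ≤ 5–8 taxa and length ≤ 4, searches at 5–12 taxa with sequences
of 80–150 sites, p-ECR contracts checked up to 100 leaves.  These sizes are
the package's own choice of where exhaustive verification is feasible; the
library itself has no hard-coded size ceilings apart from the explicit
guards on the brute-force oracles.

## Known limitations

* The fixed-tree heuristics carry no optimality guarantee beyond the lifted
  2-approximation under metric costs; `do` can exceed `lifted` on adversarial
  instances (see above).
* The implied alignment depends on traceback tie-breaking; two
  cost-equivalent assignments can imply different alignments.
* Column-splitting on closure conflicts trades alignment compactness for
  correctness of the row read-out.
* Neighbor joining on edit distances is a coarse baseline; it stands in for
  externally estimated starting trees, which users can always supply as
  Newick.
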