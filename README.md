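# treelen

Treelength optimization for simultaneous phylogeny and alignment estimation
from unaligned nucleotide sequences.

## The problem

Given a set `S` of unaligned sequences over `{A,C,G,T}` and an edit-cost
function `c` (per-event substitution costs plus a gap penalty
`f(l) = gap_open + gap_extend·l` for a gap of `l` nucleotides), the
*treelength* of a tree `T` whose nodes all carry sequences is

    TL(T) = Σ_{(u,v) ∈ E(T)} c(s_u, s_v),

the sum over edges of the pairwise edit distance between the endpoint
sequences.  The generalized Sankoff problem asks for the tree, together with
ancestral sequences at its internal nodes, minimizing `TL` — a criterion
that generalizes maximum parsimony: setting `gap_open = ∞` forbids indels
and makes treelength equal the parsimony score.  The optimal pairwise
alignment of each edge's endpoint sequences, closed transitively across the
tree, yields an *implied multiple sequence alignment*, so a treelength
optimizer co-estimates a tree and an alignment at once.

The problem is NP-hard even on a fixed tree, so everything here is built
around inspectable heuristics plus brute-force oracles on tiny instances:

* **pairwise** — exact affine-gap (Gotoh) edit distance with deterministic
  traceback, in exact rational arithmetic;
* **treelength** — fixed-tree solvers: optimal *lifted* labeling (internal
  nodes take leaf sequences, chosen by dynamic programming; a
  2-approximation under metric costs), a *direct-optimization* style
  consensus heuristic with hill-climbing, and an *exact* enumerator for tiny
  instances; plus implied-alignment construction;
* **search** — the candidate-pool heuristic: score the supplied starting
  trees (or internal neighbor-joining / random baselines) and 20 random
  p-ECR perturbations of each (`p ~ Uniform{1..5}`), return the shortest.
  The winner is never longer than any supplied starting tree, so
  treelengths normalized by a baseline are ≤ 1;
* **tree_moves** — p-ECR moves (contract `p` internal edges, randomly
  refine back to binary) and random tree generation;
* **metrics** — missing branch rate (false-negative bipartition rate,
  robust to unresolved trees), symmetric Robinson–Foulds, SP-FN alignment
  error, strict-majority consensus;
* **simulator** — sequence evolution with K2P-style substitutions and a
  Poisson indel process (geometric or mixture gap lengths), exact homology
  bookkeeping (true alignment), per-branch event tallies, and reference
  trees obtained by contracting zero-event branches.

Three named cost criteria ship as presets — `simple1` (every event costs 1),
`simple2` (indels and transversions 2, transitions 1), `affine`
(gap_open 2, gap_extend ½, transition 1, transversion 2) — plus `mp`
(indels forbidden).  Every constant is overridable; the criteria's
structure, not the constants, is fixed.

## Worked example

Simulate an 8-taxon dataset, search for a short tree under the affine
criterion starting from a neighbor-joining tree, and measure errors against
the simulation truth:

```
$ treelen simulate --tree model.nwk --out-prefix sim --seed 4 --root-length 80
$ treelen search --seqs sim/leaves.fasta --scheme affine --nj-baseline \
      --seed 1 --out-tree best.nwk --out-alignment best.fasta --report pool.tsv
# scheme=affine seed=1 method=lifted version=0.1.0
best_treelength 247.000000      247
best_origin     neighbor-of:nj_baseline
normalized_score        0.976285
$ treelen treecmp --ref sim/reference_tree.nwk --est best.nwk
missing_branch_rate     rf
0.000000        0
$ treelen aligncmp --ref sim/true_alignment.fasta --est best.fasta
sp_fn
0.163489
```

Reading the output: the search's 21-tree pool (NJ baseline + 20 p-ECR
neighbors) contained a neighbor 2.4% shorter than the baseline
(normalized score 0.976 < 1).  That shortest tree recovers every reference
bipartition (missing branch rate 0), while its implied alignment misses
16.3% of the true alignment's homologous residue pairs — treelength optima
tend to be better trees than alignments, which is exactly the behavior this
toolkit exists to study.

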