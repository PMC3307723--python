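"""The BeeTLe candidate-pool search for short trees.

BeeTLe ("Better TreeLength") is deliberately simple: assemble a pool of
candidate topologies — user-supplied starting trees plus optional internal
baselines (neighbor joining on edit distances, random trees) and 20 random
p-ECR perturbations of each — score every candidate's treelength under one
criterion, and return the shortest.  Because every starting tree is itself in
the pool, the winner is guaranteed to be at least as short as any supplied
tree; treelengths normalized by a designated baseline are therefore <= 1
whenever the baseline is in the pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .cost_model import Cost, CostScheme
from .formats import PhyloTree, SequenceSet, parse_newick
from .pairwise import edit_distance
from .tree_moves import DEFAULT_NEIGHBORHOOD, DEFAULT_P_MAX, neighborhood, random_binary_tree
from .treelength import Method, TreeAssignment, _distance_matrix, score_fixed_tree


@dataclass
class ScoredTree:
    """A candidate tree with its sequence assignment and treelength."""

    tree: PhyloTree
    assignment: TreeAssignment
    origin: str

    @property
    def treelength(self) -> Cost:
        return self.assignment.treelength


@dataclass
class CandidatePool:
    """All scored candidates of one search, with the normalization baseline."""

    scored: list[ScoredTree]
    scheme: CostScheme
    baseline_index: int = 0

    def __post_init__(self):
        if not self.scored:
            raise ValueError("empty candidate pool")
        leaf_sets = {frozenset(s.tree.leaf_labels) for s in self.scored}
        if len(leaf_sets) != 1:
            raise ValueError("pool trees disagree on the leaf set")

    @property
    def baseline(self) -> ScoredTree:
        return self.scored[self.baseline_index]

    def __len__(self) -> int:
        return len(self.scored)


def nj_start_tree(seqs: SequenceSet, scheme: CostScheme) -> PhyloTree:
    """Neighbor joining on the all-pairs edit-distance matrix.

    Internal baseline standing in for an externally estimated starting tree;
    deterministic (labels are ordered before the NJ run).
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    labels = sorted(seqs.labels)
    by_label = seqs.as_dict()
    k = len(labels)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = edit_distance(by_label[labels[i]], by_label[labels[j]], scheme)
            mat[i, j] = mat[j, i] = float(d)
    tree = nj(DistanceMatrix(mat, labels))
    out = parse_newick(str(tree))
    out.splice_degree2()
    return out


def normalized_score(pool: CandidatePool, target: ScoredTree) -> float:
    """target treelength / baseline treelength (<= 1 for the pool winner)."""
    base = pool.baseline.treelength
    if base == 0:
        warnings.warn("baseline treelength is zero; normalized score undefined")
        return math.nan
    return float(target.treelength) / float(base)


def beetle_search(
    seqs: SequenceSet,
    scheme: CostScheme,
    starting_trees: list[PhyloTree],
    seed: int | None = None,
    method: Method = "lifted",
    neighbors: int = DEFAULT_NEIGHBORHOOD,
    p_max: int = DEFAULT_P_MAX,
    nj_baseline: bool = False,
    random_baselines: int = 0,
) -> tuple[ScoredTree, CandidatePool]:
    """Score starting trees and their p-ECR neighborhoods; return the shortest.

    The pool is: supplied trees (in order) + optional internal baselines +
    ``neighbors`` p-ECR perturbations of each, p ~ Uniform{1..p_max}.  Ties
    break by origin order, then insertion order.  The first pool member is
    the normalization baseline.  Pure function of (inputs, seed).
    """
    if not starting_trees and not nj_baseline and not random_baselines:
        raise ValueError("no starting trees supplied and no internal baselines requested")
    labels = set(seqs.labels)
    starts: list[tuple[PhyloTree, str]] = []
    for i, t in enumerate(starting_trees):
        if t.leaf_labels != labels:
            raise ValueError("starting tree leaf set does not match the sequences")
        starts.append((t, f"supplied:{i}"))
    if nj_baseline:
        starts.append((nj_start_tree(seqs, scheme), "nj_baseline"))
    rng = np.random.default_rng(seed)
    for i in range(random_baselines):
        starts.append((random_binary_tree(sorted(labels), rng), f"random_baseline:{i}"))

    pool_trees: list[tuple[PhyloTree, str]] = list(starts)
    for t, origin in starts:
        base = t if t.is_binary() else None
        if base is None:
            # p-ECR needs a binary tree; perturb a random refinement instead
            from .tree_moves import random_refine

            base = random_refine(t, rng)
        for nb in neighborhood(base, count=neighbors, p_max=p_max, seed=rng):
            pool_trees.append((nb, f"neighbor-of:{origin}"))

    D = _distance_matrix([s for _, s in seqs], scheme) if method == "lifted" else None
    scored = []
    for t, origin in pool_trees:
        asn = score_fixed_tree(t, seqs, scheme, method=method, distance_matrix=D)
        scored.append(ScoredTree(t, asn, origin))
    pool = CandidatePool(scored, scheme, baseline_index=0)
    best = min(range(len(scored)), key=lambda i: (scored[i].treelength, i))
    return scored[best], pool
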